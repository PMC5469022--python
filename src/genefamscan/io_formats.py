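"""Readers/writers for the standard formats the pipeline touches.

Internal coordinate convention is 1-based inclusive (GFF3 native).
``GeneModel.span_length`` is the inclusive length ``end - start + 1``;
``GeneModel.paper_gene_length`` is ``end - start``, the convention used by
the gene-length column of the family table this pipeline reproduces (on
its printed rows, e.g. 450,835 - 447,830 = 3005).  Both accessors are kept
so the printed convention can be reproduced without corrupting the
internal model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("genefamscan")

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def get_logger(name: str = "genefamscan") -> logging.Logger:
    return logging.getLogger(name)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: identifier, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A gene's chromosome, strand, coordinates and exon/CDS segments.

    ``exons`` are (start, end) 1-based inclusive, sorted by ascending
    genomic start regardless of strand.  ``cds_segments`` are
    (start, end, phase) triples, same ordering.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        for s, e, _ in self.cds_segments:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(
                    f"{self.gene_id}: CDS segment {s}-{e} not contained in any exon"
                )

    @property
    def span_length(self) -> int:
        """Inclusive genomic span, end - start + 1."""
        return self.end - self.start + 1

    @property
    def paper_gene_length(self) -> int:
        """Gene length as end - start (the printed-table convention)."""
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, loadable from one YAML file.

    The signature patterns are the two motifs that define a complete
    Ser/Thr kinase catalytic domain in this family: the ATP-binding region
    ([IL]GXGXFGVA, X = any residue) and the activation-loop active site
    ([VI]CHRDLKLENTLL).
    """

    promoter_length: int = 2000
    signatures: dict[str, str] = field(
        default_factory=lambda: {
            "ATP_binding": "[IL]GXGXFGVA",
            "active_site": "[VI]CHRDLKLENTLL",
        }
    )
    signature_max_mismatch: int = 1
    coverage_min: float = 0.80
    identity_min: float = 0.70
    bootstrap_replicates: int = 1000
    rng_seed: int = 42
    cis_elements: dict[str, str] = field(
        default_factory=lambda: {
            "ABRE": "CACGTG",
            "LTR": "CCGAAA",
            "TC-rich": "ATTTTCTTCA",
            "TCA": "GAGAAGAATA",
            "HSE": "AAAAAATTTC",
            "TGACG": "TGACG",
            "MBS": "CAACTG",
        }
    )
    name_prefix: str = "FAM"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    distance_model: str = "p"  # "p" or "poisson"
    pka_set: str = "bjellqvist"
    scan_both_strands: bool = True
    # documented but unused by the signature scanner: the BLASTP E-value
    # threshold of the database pre-filter this scanner replaces
    blastp_evalue: float = 1e-10

    def validate(self) -> None:
        if not 0 < self.coverage_min <= 1:
            raise ValueError("coverage_min must be in (0, 1]")
        if not 0 < self.identity_min <= 1:
            raise ValueError("identity_min must be in (0, 1]")
        if self.promoter_length <= 0:
            raise ValueError("promoter_length must be positive")
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap_replicates must be >= 0")
        for name, motif in self.cis_elements.items():
            if not motif:
                raise ValueError(f"cis element {name!r} has empty motif")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (residues uppercased).

    Raises on duplicate ids and on empty files.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModels.

    One mRNA per gene is expected; if several are present the first by
    coordinate is taken and a warning is logged.  CDS segments outside
    exon bounds and exon/CDS features without Parent links are errors.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise ValueError(f"{path}: missing ##gff-version directive")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{line_no}: expected 9 columns")
            seqid, _, ftype, start, end, _, strand, phase, attrs = cols
            start_i, end_i = int(start), int(end)
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{line_no}: gene without ID")
                genes[gid] = {
                    "chromosome": seqid,
                    "strand": strand,
                    "start": start_i,
                    "end": end_i,
                    "mrnas": {},
                }
                order.append(gid)
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if parent is None or parent not in genes:
                    raise ValueError(f"{path}:{line_no}: mRNA without known Parent")
                mrna_parent[mid] = parent
                genes[parent]["mrnas"][mid] = {"exons": [], "cds": [], "start": start_i}
            elif ftype in {"exon", "CDS"}:
                parent = a.get("Parent")
                if parent is None or parent not in mrna_parent:
                    raise ValueError(
                        f"{path}:{line_no}: {ftype} without known mRNA Parent"
                    )
                mrna = genes[mrna_parent[parent]]["mrnas"][parent]
                if ftype == "exon":
                    mrna["exons"].append((start_i, end_i))
                else:
                    ph = 0 if phase == "." else int(phase)
                    mrna["cds"].append((start_i, end_i, ph))
    models = []
    for gid in order:
        g = genes[gid]
        if not g["mrnas"]:
            raise ValueError(f"gene {gid}: no mRNA")
        if len(g["mrnas"]) > 1:
            logger.warning("gene %s has %d mRNAs; taking the first", gid, len(g["mrnas"]))
        mrna = sorted(g["mrnas"].values(), key=lambda m: m["start"])[0]
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=g["chromosome"],
                strand=g["strand"],
                start=g["start"],
                end=g["end"],
                exons=mrna["exons"],
                cds_segments=mrna["cds"],
            )
        )
    logger.info("read %d gene models from %s", len(models), path)
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit GeneModels as GFF3 (gene/mRNA/exon/CDS, one mRNA per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            mid = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chromosome}\tgenefamscan\tgene\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chromosome}\tgenefamscan\tmRNA\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={mid};Parent={m.gene_id}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chromosome}\tgenefamscan\texon\t{s}\t{e}\t.\t"
                    f"{m.strand}\t.\tParent={mid}\n"
                )
            for s, e, ph in m.cds_segments:
                fh.write(
                    f"{m.chromosome}\tgenefamscan\tCDS\t{s}\t{e}\t.\t"
                    f"{m.strand}\t{ph}\tParent={mid}\n"
                )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _newick_node(node) -> str:
    bl = getattr(node, "branch_length", 0.0) or 0.0
    if not node.children:
        if not node.name:
            raise ValueError("unnamed leaf in tree")
        return f"{node.name}:{bl:.6g}"
    inner = ",".join(_newick_node(c) for c in node.children)
    support = getattr(node, "support", None)
    label = f"{support:.6g}" if support is not None else ""
    return f"({inner}){label}:{bl:.6g}"


def newick_string(tree) -> str:
    """Newick text for a tree (root node with .children/.name/
    .branch_length and optional .support); branch lengths to 6
    significant digits.  The root's own branch length is omitted."""
    node = tree.root if hasattr(tree, "root") else tree
    text = _newick_node(node)
    if node.children and text.rfind(":") > text.rfind(")"):
        text = text[: text.rfind(":")]
    return text + ";"


def write_newick(tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------


def write_matrix_tsv(
    matrix: Sequence[Sequence],
    row_names: Sequence[str],
    col_names: Sequence[str],
    path: str | Path,
) -> None:
    """Header row + one row per entity; tab-separated, '.' decimal."""
    rows = [list(r) for r in matrix]
    if len(rows) != len(row_names):
        raise ValueError(
            f"matrix has {len(rows)} rows but {len(row_names)} row names"
        )
    for r in rows:
        if len(r) != len(col_names):
            raise ValueError(
                f"matrix row has {len(r)} values but {len(col_names)} column names"
            )
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(col_names) + "\n")
        for name, row in zip(row_names, rows):
            fh.write(name + "\t" + "\t".join(str(v) for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[list[list[str]], list[str], list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col_names = header[1:]
        row_names, matrix = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_names.append(parts[0])
            matrix.append(parts[1:])
    return matrix, row_names, col_names
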