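"""Synthetic genomes with planted ground truth.

The generator emulates the study system every pipeline stage consumes: a
two-subgenome (A/D) multi-chromosome genome carrying a kinase gene
family whose members have nine exons, both catalytic-domain signatures
(ATP-binding and activation-loop) planted at fixed template offsets,
group-structured C-terminal tails (poly-E for Group I, poly-D for
Group II, an ABA-box-bearing tail for Group III), 2-kb promoters with
exact planted cis-element counts, homoeologous paralog pairs with
controlled synonymous/non-synonymous divergence, and decoy genes
(kinase-like with exactly one signature, and non-kinase).

All non-planted sequence is rejection-sampled to be motif-free (no
cis-element on either strand) and signature-free, so planted counts are
exact truth and count-equality tests are meaningful.  Everything is
deterministic given the profile seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from genefamscan.classify_groups import ABA_BOX_PATTERN, SNRK2_BOX_PATTERN
from genefamscan.family_id import scan_signatures
from genefamscan.io_formats import (
    GeneModel,
    SequenceRecord,
    get_logger,
    write_fasta,
    write_gff3,
)
from genefamscan.promoter_cis import (
    DEFAULT_ELEMENTS,
    expand_iupac,
    reverse_complement,
    scan_elements,
)
from genefamscan.protein_props import translate_cds

logger = get_logger(__name__)

# ---------------------------------------------------------------------------
# template layout (0-based protein offsets)
# ---------------------------------------------------------------------------

ATP_SIGNATURE_INSTANCE = "LGAGSFGVA"  # matches [IL]GXGXFGVA
ACTIVE_SITE_INSTANCE = "VCHRDLKLENTLL"  # matches [VI]CHRDLKLENTLL

_BG1, _BG2, _BG3 = 20, 100, 97
_ATP_OFFSET = _BG1  # 20
_ACT_OFFSET = _BG1 + len(ATP_SIGNATURE_INSTANCE) + 1 + _BG2  # 130
_KINASE_LEN = _ACT_OFFSET + len(ACTIVE_SITE_INSTANCE) + _BG3  # 240
_BG4, _BG5, _BG6 = 20, 14, 30
_BOX_OFFSET = _KINASE_LEN + _BG4  # 260
_TAIL_OFFSET = _BOX_OFFSET + len(SNRK2_BOX_PATTERN) + _BG5  # 290
TAIL_LEN = 40
PROTEIN_LEN = _TAIL_OFFSET + TAIL_LEN + _BG6  # 360

GROUP_TAILS = {
    "I": "SAEEEEGEEEESEEEEAEEEEGSEEEEAEEEEGSQLYKRT",
    "II": "SADDDDGDDDDSDDDDADDDDGSDDDDADDDDGSQLYKRT",
    "III": ABA_BOX_PATTERN + "SDDDDAGKLR",
}
for _g, _t in GROUP_TAILS.items():
    assert len(_t) == TAIL_LEN, (_g, len(_t))

# background alphabet excludes D/E (acidic patches are tail-driven) and
# K/R (the family's proteins are acidic overall; basic residues come
# from the planted motifs), keeping accidental signature matches unlikely
_BG_ALPHABET = "AGILNPQSTVFYHW"

_SIGNATURE_DEFS = {
    "ATP_binding": "[IL]GXGXFGVA",
    "active_site": "[VI]CHRDLKLENTLL",
}
_BOX_DEFS = {"snrk2_box": SNRK2_BOX_PATTERN, "aba_box": ABA_BOX_PATTERN}

_SYNONYMOUS: dict[str, list[str]] = {}


def _codon_sets() -> dict[str, list[str]]:
    if not _SYNONYMOUS:
        by_aa: dict[str, list[str]] = {}
        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    codon = b1 + b2 + b3
                    if codon in {"TAA", "TAG", "TGA"}:
                        continue
                    by_aa.setdefault(translate_cds(codon + "TAA"), []).append(codon)
        _SYNONYMOUS.update(by_aa)
    return _SYNONYMOUS


# ---------------------------------------------------------------------------
# profile and truth
# ---------------------------------------------------------------------------


@dataclass
class GeneratorProfile:
    """Study-condition knobs of the generator.

    Defaults mirror the system the pipeline characterizes: a 20-member
    family of nine-exon kinase genes split over the A and D subgenomes
    (one pair of members sits on unplaced scaffolds), 2-kb promoters.
    """

    family_size: int = 20
    exons_per_gene: int = 9
    promoter_length: int = 2000
    n_kinase_decoys: int = 10
    n_nonkinase_decoys: int = 10
    gc_fraction: float = 0.40
    rng_seed: int = 42
    max_chromosome_length: int | None = None

    def validate(self) -> None:
        if self.family_size < 2:
            raise ValueError("family_size must be >= 2 (pairs are needed)")
        if self.exons_per_gene < 1:
            raise ValueError("exons_per_gene must be >= 1")
        if self.promoter_length <= 0:
            raise ValueError("promoter_length must be positive")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")


@dataclass
class FamilyTruth:
    members: list[str] = field(default_factory=list)
    signature_positions: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    pairs: list[tuple[str, str, int, int]] = field(default_factory=list)  # a, b, n_syn, n_nonsyn
    cis_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    kinase_decoys: list[str] = field(default_factory=list)
    nonkinase_decoys: list[str] = field(default_factory=list)
    references: dict[str, str] = field(default_factory=dict)  # ref id -> group

    def to_json(self, path: str | Path) -> None:
        data = {
            "members": self.members,
            "signature_positions": self.signature_positions,
            "pairs": self.pairs,
            "cis_counts": self.cis_counts,
            "groups": self.groups,
            "kinase_decoys": self.kinase_decoys,
            "nonkinase_decoys": self.nonkinase_decoys,
            "references": self.references,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "FamilyTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            members=d["members"],
            signature_positions={
                g: {k: tuple(v) for k, v in sigs.items()}
                for g, sigs in d["signature_positions"].items()
            },
            pairs=[tuple(p) for p in d["pairs"]],
            cis_counts=d["cis_counts"],
            groups=d["groups"],
            kinase_decoys=d["kinase_decoys"],
            nonkinase_decoys=d["nonkinase_decoys"],
            references=d.get("references", {}),
        )


@dataclass
class GeneratedFamily:
    genome: list[SequenceRecord]
    models: list[GeneModel]
    cds: list[SequenceRecord]
    proteins: list[SequenceRecord]
    promoters: list[SequenceRecord]
    references: list[SequenceRecord]
    truth: FamilyTruth

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fna",
            "gff": out / "genes.gff3",
            "cds": out / "cds.fna",
            "proteins": out / "proteins.faa",
            "promoters": out / "promoters.fna",
            "references": out / "references.faa",
            "truth": out / "truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3(self.models, paths["gff"])
        write_fasta(self.cds, paths["cds"])
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(self.promoters, paths["promoters"])
        write_fasta(self.references, paths["references"])
        self.truth.to_json(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# motif-free DNA background
# ---------------------------------------------------------------------------


def _forbidden_strings(table=None) -> list[str]:
    table = DEFAULT_ELEMENTS if table is None else table
    out: set[str] = set()
    for motif in table.values():
        for concrete in expand_iupac(motif):
            out.add(concrete)
            out.add(reverse_complement(concrete))
    return sorted(out)


_FORBIDDEN = _forbidden_strings()


def motif_free_dna(rng: np.random.Generator, length: int, gc: float = 0.40) -> str:
    """Random DNA of given length containing no cis-element motif on
    either strand (rejection sampling: offending windows are re-drawn)."""
    if length <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length, p=p))
    for _ in range(1000):
        text = "".join(seq)
        dirty = False
        for motif in _FORBIDDEN:
            pos = text.find(motif)
            while pos != -1:
                dirty = True
                hit = pos + int(rng.integers(0, len(motif)))
                seq[hit] = str(rng.choice(bases, p=p))
                pos = text.find(motif, pos + 1)
        if not dirty:
            return text
    raise RuntimeError("could not sample motif-free background")


# ---------------------------------------------------------------------------
# promoter planting
# ---------------------------------------------------------------------------


def plant_promoter_elements(
    gene_id: str,
    counts_by_element: dict[str, int],
    length: int = 2000,
    seed: int | np.random.Generator = 0,
    table: dict[str, str] | None = None,
) -> str:
    """A promoter of exactly ``length`` bp containing each element
    exactly its requested count (forward strand, non-overlapping) and no
    other table-motif occurrence on either strand."""
    table = DEFAULT_ELEMENTS if table is None else table
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for name, count in counts_by_element.items():
        if name not in table:
            raise ValueError(f"unknown element {name!r}")
        if count < 0:
            raise ValueError(f"negative count for {name!r}")
    instances: list[str] = []
    for name, count in sorted(counts_by_element.items()):
        instances.extend([table[name]] * count)
    if sum(len(m) for m in instances) >= length:
        raise ValueError(f"{gene_id}: planted motifs exceed promoter length")
    expected = {name: counts_by_element.get(name, 0) for name in table}
    for _attempt in range(60):
        seq = list(motif_free_dna(rng, length))
        placed: list[tuple[int, int]] = []
        ok = True
        order = list(rng.permutation(len(instances)))
        for idx in order:
            motif = instances[idx]
            for _try in range(200):
                start = int(rng.integers(0, length - len(motif) + 1))
                span = (start, start + len(motif))
                if all(span[1] <= s or span[0] >= e for s, e in placed):
                    placed.append(span)
                    seq[span[0] : span[1]] = list(motif)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        text = "".join(seq)
        if scan_elements(text, table, both_strands=True) == expected:
            return text
    raise ValueError(f"{gene_id}: cannot satisfy non-overlapping placement")


# ---------------------------------------------------------------------------
# proteins and CDS
# ---------------------------------------------------------------------------


def _verify_protein(protein: str, expect_aba: bool) -> bool:
    hits = scan_signatures(protein, _SIGNATURE_DEFS, max_mismatch=1)
    atp = [h for h in hits if h.signature_name == "ATP_binding"]
    act = [h for h in hits if h.signature_name == "active_site"]
    if len(atp) != 1 or len(act) != 1:
        return False
    if atp[0].start != _ATP_OFFSET + 1 or act[0].start != _ACT_OFFSET + 1:
        return False
    box_hits = scan_signatures(protein, _BOX_DEFS, max_mismatch=2)
    snrk2 = [h for h in box_hits if h.signature_name == "snrk2_box"]
    aba = [h for h in box_hits if h.signature_name == "aba_box"]
    if len(snrk2) != 1:
        return False
    return len(aba) == (1 if expect_aba else 0)


def _random_bg(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BG_ALPHABET), size=n))


def _mutable_positions() -> list[int]:
    """Background (freely mutable) 0-based positions of the template."""
    return (
        list(range(0, _BG1))
        + list(range(_ATP_OFFSET + 10, _ACT_OFFSET))
        + list(range(_ACT_OFFSET + 13, _KINASE_LEN))
        + list(range(_KINASE_LEN, _BOX_OFFSET))
        + list(range(_BOX_OFFSET + 16, _TAIL_OFFSET))
        + list(range(_TAIL_OFFSET + TAIL_LEN, PROTEIN_LEN))
    )


def _template_proteins(
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, list[str]], list[int]]:
    """One family-wide template background instantiated with each group
    tail, plus per-group codon lists and the mutable positions.

    All groups share the same background residues AND the same codon
    choices for them, so both protein identity and synonymous-site
    divergence behave like a real single family: synonymous differences
    accumulate only through the explicit drift applied along the
    template -> group -> pair -> paralog lineage."""
    table = _codon_sets()

    def codons_for(seq: str) -> list[str]:
        return [str(rng.choice(table[r])) for r in seq]

    for _ in range(100):
        bg = [
            _random_bg(rng, _BG1),
            _random_bg(rng, _BG2),
            _random_bg(rng, _BG3),
            _random_bg(rng, _BG4),
            _random_bg(rng, _BG5),
            _random_bg(rng, _BG6),
        ]
        bg_codons = [codons_for(s) for s in bg]
        fixed_codons = {
            "atp": codons_for(ATP_SIGNATURE_INSTANCE + "K"),
            "act": codons_for(ACTIVE_SITE_INSTANCE),
            "box": codons_for(SNRK2_BOX_PATTERN),
        }
        proteins: dict[str, str] = {}
        codons: dict[str, list[str]] = {}
        for group, tail in GROUP_TAILS.items():
            protein = "".join(
                [
                    bg[0], ATP_SIGNATURE_INSTANCE, "K", bg[1],
                    ACTIVE_SITE_INSTANCE, bg[2], bg[3],
                    SNRK2_BOX_PATTERN, bg[4], tail, bg[5],
                ]
            )
            assert len(protein) == PROTEIN_LEN
            proteins[group] = protein
            codons[group] = (
                bg_codons[0] + fixed_codons["atp"] + bg_codons[1]
                + fixed_codons["act"] + bg_codons[2] + bg_codons[3]
                + fixed_codons["box"] + bg_codons[4]
                + codons_for(tail) + bg_codons[5]
            )
        if all(
            _verify_protein(p, expect_aba=(g == "III"))
            for g, p in proteins.items()
        ):
            return proteins, codons, _mutable_positions()
    raise RuntimeError("could not build a clean template protein")


def _derive_lineage(
    rng: np.random.Generator,
    protein: str,
    codons: list[str],
    mutable: list[int],
    n_sub: int,
    n_syn_drift: int,
    expect_aba: bool,
) -> tuple[str, list[str]]:
    """A descendant of (protein, codons): ``n_sub`` residue substitutions
    at mutable positions (codon replaced accordingly) plus
    ``n_syn_drift`` silent codon swaps anywhere."""
    table = _codon_sets()
    for _ in range(100):
        seq = list(protein)
        new_codons = list(codons)
        for pos in rng.choice(mutable, size=n_sub, replace=False):
            pos = int(pos)
            choices = [r for r in _BG_ALPHABET if r != seq[pos]]
            aa = str(rng.choice(choices))
            seq[pos] = aa
            new_codons[pos] = str(rng.choice(table[aa]))
        cand = "".join(seq)
        if not _verify_protein(cand, expect_aba):
            continue
        for pos in rng.choice(len(seq), size=n_syn_drift, replace=False):
            pos = int(pos)
            new_codons[pos] = str(rng.choice(table[seq[pos]]))
        return cand, new_codons
    raise RuntimeError("could not derive protein without disturbing signatures")


def _backtranslate(rng: np.random.Generator, protein: str) -> str:
    table = _codon_sets()
    codons = [str(rng.choice(table[r])) for r in protein]
    return "".join(codons) + "TAA"


def mutate_paralog_cds(
    cds: str,
    n_syn: int,
    n_nonsyn: int,
    seed: int | np.random.Generator,
    mutable_codons: list[int] | None = None,
) -> tuple[str, list[dict]]:
    """Apply exactly ``n_syn`` synonymous and ``n_nonsyn`` non-synonymous
    single-nucleotide changes at distinct codons, never creating a stop.

    Returns the mutated CDS and a change log (codon index, position,
    from/to base, class).  The terminal stop codon is never touched.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    translate_cds(cds)  # validates (no internal stop)
    n_codons = len(cds) // 3
    stops = {"TAA", "TAG", "TGA"}
    last = n_codons - 1 if cds[-3:] in stops else n_codons
    candidates = list(range(last)) if mutable_codons is None else [
        c for c in mutable_codons if c < last
    ]
    table = _codon_sets()
    aa_of = {c: a for a, cs in table.items() for c in cs}

    def single_nt_changes(codon: str):
        for pos in range(3):
            for base in "ACGT":
                if base != codon[pos]:
                    mutated = codon[:pos] + base + codon[pos + 1 :]
                    if mutated not in stops:
                        yield pos, base, mutated

    syn_capable = [
        i for i in candidates
        if any(
            aa_of[m] == aa_of[cds[3 * i : 3 * i + 3]]
            for _, _, m in single_nt_changes(cds[3 * i : 3 * i + 3])
        )
    ]
    if len(syn_capable) < n_syn:
        raise ValueError(
            f"only {len(syn_capable)} codons admit synonymous changes; "
            f"{n_syn} requested"
        )
    if len(candidates) < n_syn + n_nonsyn:
        raise ValueError("not enough distinct codons for requested changes")
    seq = list(cds)
    log: list[dict] = []
    chosen_syn = [int(i) for i in rng.choice(syn_capable, size=n_syn, replace=False)]
    remaining = [i for i in candidates if i not in set(chosen_syn)]
    nonsyn_capable = [
        i for i in remaining
        if any(
            aa_of[m] != aa_of[cds[3 * i : 3 * i + 3]]
            for _, _, m in single_nt_changes(cds[3 * i : 3 * i + 3])
        )
    ]
    if len(nonsyn_capable) < n_nonsyn:
        raise ValueError("not enough codons admit non-synonymous changes")
    chosen_nonsyn = [
        int(i) for i in rng.choice(nonsyn_capable, size=n_nonsyn, replace=False)
    ]
    for codon_idx, want_syn in [(i, True) for i in chosen_syn] + [
        (i, False) for i in chosen_nonsyn
    ]:
        codon = cds[3 * codon_idx : 3 * codon_idx + 3]
        options = [
            (pos, base, m)
            for pos, base, m in single_nt_changes(codon)
            if (aa_of[m] == aa_of[codon]) == want_syn
        ]
        pos, base, mutated = options[int(rng.integers(0, len(options)))]
        seq[3 * codon_idx + pos] = base
        log.append(
            {
                "codon": codon_idx,
                "position": pos,
                "from": codon[pos],
                "to": base,
                "class": "synonymous" if want_syn else "nonsynonymous",
            }
        )
    return "".join(seq), log


# ---------------------------------------------------------------------------
# gene bodies
# ---------------------------------------------------------------------------


def _split_cds(rng: np.random.Generator, cds_len: int, n_exons: int) -> list[int]:
    base = cds_len // n_exons
    lengths = [base] * n_exons
    lengths[-1] += cds_len - base * n_exons
    for i in range(n_exons - 1):
        delta = int(rng.integers(-10, 11))
        if lengths[i] + delta >= 20 and lengths[i + 1] - delta >= 20:
            lengths[i] += delta
            lengths[i + 1] -= delta
    return lengths


@dataclass
class _GeneBody:
    sequence: str  # sense strand, exon/intron concatenation
    exons: list[tuple[int, int]]  # 1-based within sequence, sense order


def _build_gene_body(
    rng: np.random.Generator, cds: str, n_exons: int, gc: float
) -> _GeneBody:
    exon_lengths = _split_cds(rng, len(cds), n_exons)
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    cursor = 0
    pos = 0
    for i, el in enumerate(exon_lengths):
        pieces.append(cds[cursor : cursor + el])
        exons.append((pos + 1, pos + el))
        pos += el
        cursor += el
        if i < n_exons - 1:
            intron = motif_free_dna(rng, int(rng.integers(80, 301)), gc)
            pieces.append(intron)
            pos += len(intron)
    return _GeneBody("".join(pieces), exons)


def _phases(exon_lengths: list[int]) -> list[int]:
    """GFF3 phase for each CDS segment in transcription order."""
    phases = []
    cum = 0
    for el in exon_lengths:
        phases.append((3 - cum % 3) % 3)
        cum += el
    return phases


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

_PAPER_A_CHROMS = [
    "A01", "A02", "A03", "A05", "A10", "A11", "A11", "A11",
    "scaffold2734_A11", "A12",
]
_PAPER_D_CHROMS = [
    "D01", "D02", "D02", "D05", "D10", "D11", "D11", "D11",
    "scaffold4551_D11", "D12",
]
# pair i joins A-member i with D-member _PAPER_PAIRING[i] (0-based into
# the D list), reproducing the study's homoeologous pairing
_PAPER_PAIRING = [0, 1, 2, 3, 4, 6, 8, 7, 5, 9]
_PAPER_GROUPS = ["III", "II", "III", "II", "I", "II", "III", "II", "III", "III"]


def _member_layout(profile: GeneratorProfile):
    """(chromosome, sense-strand?) per member plus pairing and groups."""
    n = profile.family_size
    n_pairs = n // 2
    if n == 20:
        a_chroms, d_chroms = _PAPER_A_CHROMS, _PAPER_D_CHROMS
        pairing, groups = _PAPER_PAIRING, _PAPER_GROUPS
    else:
        a_chroms = [f"A{i + 1:02d}" for i in range(n_pairs + n % 2)]
        d_chroms = [f"D{i + 1:02d}" for i in range(n_pairs)]
        pairing = list(range(n_pairs))
        cycle = ["III", "II", "I"]
        groups = [cycle[i % 3] for i in range(n_pairs + n % 2)]
    return a_chroms, d_chroms, pairing, groups


def generate_family_genome(profile: GeneratorProfile) -> GeneratedFamily:
    """Generate the genome, gene models, CDS/protein/promoter records,
    reference proteins, and the planted truth."""
    profile.validate()
    rng = np.random.default_rng(profile.rng_seed)
    gc = profile.gc_fraction
    a_chroms, d_chroms, pairing, groups = _member_layout(profile)
    n_pairs = profile.family_size // 2
    unpaired = profile.family_size % 2

    truth = FamilyTruth()
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    promoters: dict[str, str] = {}
    member_chrom: dict[str, tuple[str, str]] = {}  # id -> (chrom, strand)

    templates, template_codons, mutable = _template_proteins(rng)
    base_cache: dict[str, tuple[str, list[str]]] = {}

    def group_base(group: str) -> tuple[str, list[str]]:
        # each group diverges from the family template by ~25 background
        # substitutions (plus silent drift) on top of its distinctive tail
        if group not in base_cache:
            base_cache[group] = _derive_lineage(
                rng, templates[group], template_codons[group], mutable,
                25, 20, group == "III",
            )
        return base_cache[group]

    # --- members (pairs first, optional unpaired last) ---
    member_ids: list[str] = []
    a_ids: list[str] = []
    d_ids: list[str] = []
    for i in range(n_pairs):
        chrom_a = a_chroms[i]
        gid_a = f"Syn_{chrom_a}G{1000 + i:04d}"
        a_ids.append(gid_a)
    for j in range(n_pairs):
        chrom_d = d_chroms[j]
        gid_d = f"Syn_{chrom_d}G{2000 + j:04d}"
        d_ids.append(gid_d)

    for i in range(n_pairs):
        group = groups[i]
        base, base_codons = group_base(group)
        prot_a, codons_a = _derive_lineage(
            rng, base, base_codons, mutable, 8, 10, group == "III"
        )
        cds_a = "".join(codons_a) + "TAA"
        n_syn = int(rng.integers(6, 13))
        n_nonsyn = int(rng.integers(1, 5))
        mutable_codons = [p for p in mutable]
        for _ in range(20):
            cds_b, _log = mutate_paralog_cds(
                cds_a, n_syn, n_nonsyn, rng, mutable_codons=mutable_codons
            )
            prot_b = translate_cds(cds_b)
            if _verify_protein(prot_b, group == "III"):
                break
        else:
            raise RuntimeError("paralog mutation kept breaking signatures")
        gid_a, gid_b = a_ids[i], d_ids[pairing[i]]
        proteins[gid_a], cds_map[gid_a] = prot_a, cds_a
        proteins[gid_b], cds_map[gid_b] = prot_b, cds_b
        truth.pairs.append((gid_a, gid_b, n_syn, n_nonsyn))
        truth.groups[gid_a] = group
        truth.groups[gid_b] = group
        member_chrom[gid_a] = (a_chroms[i], "+")
        member_chrom[gid_b] = (d_chroms[pairing[i]], "+")
    if unpaired:
        group = groups[n_pairs]
        base, base_codons = group_base(group)
        chrom = a_chroms[n_pairs]
        gid = f"Syn_{chrom}G{1000 + n_pairs:04d}"
        prot, codons = _derive_lineage(
            rng, base, base_codons, mutable, 8, 10, group == "III"
        )
        proteins[gid] = prot
        cds_map[gid] = "".join(codons) + "TAA"
        truth.groups[gid] = group
        member_chrom[gid] = (chrom, "+")
        a_ids.append(gid)
    member_ids = a_ids[: n_pairs + unpaired] + d_ids
    truth.members = sorted(member_ids)

    # a few members on the minus strand for strand coverage
    for gid in member_ids:
        if rng.random() < 0.3:
            member_chrom[gid] = (member_chrom[gid][0], "-")

    sig_span = {
        "ATP_binding": (_ATP_OFFSET + 1, _ATP_OFFSET + len(ATP_SIGNATURE_INSTANCE)),
        "active_site": (_ACT_OFFSET + 1, _ACT_OFFSET + len(ACTIVE_SITE_INSTANCE)),
    }
    for gid in member_ids:
        truth.signature_positions[gid] = dict(sig_span)

    # --- promoters with planted cis-element counts ---
    element_names = list(DEFAULT_ELEMENTS)
    for gid in member_ids:
        counts = {
            name: int(rng.poisson(0.8)) for name in element_names
        }
        counts = {k: min(v, 4) for k, v in counts.items()}
        promoters[gid] = plant_promoter_elements(
            gid, counts, profile.promoter_length, rng
        )
        truth.cis_counts[gid] = counts

    # --- decoys ---
    decoy_proteins: dict[str, str] = {}
    for k in range(profile.n_kinase_decoys):
        gid = f"DecK_{k:03d}"
        which = "ATP_binding" if k % 2 == 0 else "active_site"
        instance = (
            ATP_SIGNATURE_INSTANCE + "K" if which == "ATP_binding"
            else ACTIVE_SITE_INSTANCE
        )
        for _ in range(100):
            prot = _random_bg(rng, 60) + instance + _random_bg(rng, 200)
            hits = scan_signatures(prot, _SIGNATURE_DEFS, max_mismatch=1)
            names = {h.signature_name for h in hits}
            if names == {which}:
                break
        else:
            raise RuntimeError("could not build kinase-like decoy")
        decoy_proteins[gid] = prot
        truth.kinase_decoys.append(gid)
    for k in range(profile.n_nonkinase_decoys):
        gid = f"DecN_{k:03d}"
        for _ in range(100):
            prot = _random_bg(rng, 260)
            if not scan_signatures(prot, _SIGNATURE_DEFS, max_mismatch=1):
                break
        else:
            raise RuntimeError("could not build non-kinase decoy")
        decoy_proteins[gid] = prot
        truth.nonkinase_decoys.append(gid)
    for gid, prot in decoy_proteins.items():
        proteins[gid] = prot
        cds_map[gid] = _backtranslate(rng, prot)

    # --- reference proteins (2 per group) for tree-based classification ---
    references: list[SequenceRecord] = []
    for group in ("I", "II", "III"):
        base, base_codons = group_base(group)
        for r in range(2):
            rid = f"REF_{group}_{r + 1}"
            prot, _ = _derive_lineage(
                rng, base, base_codons, mutable, 4, 0, group == "III"
            )
            references.append(SequenceRecord(rid, prot, f"group {group} reference"))
            truth.references[rid] = group

    # --- assemble chromosomes ---
    chrom_order: list[str] = []
    for c in a_chroms + d_chroms:
        if c not in chrom_order:
            chrom_order.append(c)
    members_by_chrom: dict[str, list[str]] = {c: [] for c in chrom_order}
    for gid in member_ids:
        members_by_chrom[member_chrom[gid][0]].append(gid)
    decoy_ids = truth.kinase_decoys + truth.nonkinase_decoys
    decoys_by_chrom: dict[str, list[str]] = {c: [] for c in chrom_order}
    for k, gid in enumerate(decoy_ids):
        decoys_by_chrom[chrom_order[k % len(chrom_order)]].append(gid)

    genome: list[SequenceRecord] = []
    models: list[GeneModel] = []
    for chrom in chrom_order:
        parts: list[str] = []
        pos = 0  # 0-based length so far

        def spacer():
            nonlocal pos
            s = motif_free_dna(rng, int(rng.integers(300, 801)), gc)
            parts.append(s)
            pos += len(s)

        spacer()
        for gid in members_by_chrom[chrom]:
            strand = member_chrom[gid][1]
            body = _build_gene_body(
                rng, cds_map[gid], profile.exons_per_gene, gc
            )
            promoter = promoters[gid]
            if strand == "+":
                parts.append(promoter)
                pos += len(promoter)
                gene_start = pos + 1
                parts.append(body.sequence)
                pos += len(body.sequence)
                gene_end = pos
                exons = [
                    (gene_start + s - 1, gene_start + e - 1) for s, e in body.exons
                ]
                tx_order = exons
            else:
                locus = reverse_complement(promoter + body.sequence)
                gene_start = pos + 1
                gene_end = pos + len(body.sequence)
                blen = len(body.sequence)
                exons = sorted(
                    (gene_start + (blen - e), gene_start + (blen - s))
                    for s, e in body.exons
                )
                parts.append(locus)
                pos += len(locus)
                tx_order = sorted(exons, reverse=True)
            exon_lengths_tx = [e - s + 1 for s, e in tx_order]
            phases = _phases(exon_lengths_tx)
            phase_by_exon = dict(zip(map(tuple, tx_order), phases))
            cds_segments = [
                (s, e, phase_by_exon[(s, e)]) for s, e in exons
            ]
            models.append(
                GeneModel(
                    gene_id=gid,
                    chromosome=chrom,
                    strand=strand,
                    start=gene_start,
                    end=gene_end,
                    exons=exons,
                    cds_segments=cds_segments,
                )
            )
            spacer()
        for gid in decoys_by_chrom[chrom]:
            cds = cds_map[gid]
            gene_start = pos + 1
            parts.append(cds)
            pos += len(cds)
            gene_end = pos
            models.append(
                GeneModel(
                    gene_id=gid,
                    chromosome=chrom,
                    strand="+",
                    start=gene_start,
                    end=gene_end,
                    exons=[(gene_start, gene_end)],
                    cds_segments=[(gene_start, gene_end, 0)],
                )
            )
            spacer()
        sequence = "".join(parts)
        if (
            profile.max_chromosome_length is not None
            and len(sequence) > profile.max_chromosome_length
        ):
            raise ValueError(
                f"chromosome {chrom} ({len(sequence)} bp) exceeds "
                f"max_chromosome_length={profile.max_chromosome_length}"
            )
        genome.append(SequenceRecord(chrom, sequence))

    ordered_ids = member_ids + decoy_ids
    result = GeneratedFamily(
        genome=genome,
        models=models,
        cds=[SequenceRecord(g, cds_map[g]) for g in ordered_ids],
        proteins=[SequenceRecord(g, proteins[g]) for g in ordered_ids],
        promoters=[SequenceRecord(g, promoters[g]) for g in member_ids],
        references=references,
        truth=truth,
    )
    logger.info(
        "generated %d members, %d decoys, %d chromosomes (seed %d)",
        len(member_ids), len(decoy_ids), len(genome), profile.rng_seed,
    )
    return result


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

VALID_CONDITIONS = {"cold", "heat", "salt", "drought", "ABA"}


def generate_expression_profiles(
    truth: FamilyTruth,
    conditions: tuple[str, ...] = ("cold", "heat", "salt", "drought"),
    timepoints: tuple[float, ...] = (0, 1, 3, 6, 12, 24),
    seed: int = 0,
    baseline_fpkm: float = 20.0,
    fold: float = 4.0,
    induced_timepoints: tuple[float, ...] = (3.0, 6.0),
    noise_sd: float = 0.2,
    ct_noise_sd: float = 0.1,
    tissues: tuple[str, ...] = ("leaf",),
    reference_gene: str = "histone3",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """FPKM matrix and qPCR Ct table with group-structured responses.

    Group III members are the stress-responsive set: they receive a
    multiplicative ``fold`` induction at the induced timepoints under
    every stressed condition, over a log-normal baseline (``noise_sd``
    in log2 units; 0 gives exact closure with the expression module).
    Ct tables carry a condition-independent reference gene and three
    technical replicates per sample.
    """
    bad = set(conditions) - VALID_CONDITIONS
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    if 0 not in timepoints and 0.0 not in timepoints:
        raise ValueError("timepoints must include 0 (control)")
    rng = np.random.default_rng(seed)
    genes = truth.members
    responsive = {g for g in genes if truth.groups.get(g) == "III"}
    planted_fold = {g: (fold if g in responsive else 1.0) for g in genes}

    columns = [f"{c}_{t:g}h" for c in conditions for t in sorted(timepoints)]
    data = np.empty((len(genes), len(columns)))
    for gi, g in enumerate(genes):
        base = baseline_fpkm
        for ci, col in enumerate(columns):
            t = float(col.rsplit("_", 1)[1][:-1])
            value = base
            if g in responsive and t in induced_timepoints:
                value *= fold
            if noise_sd > 0:
                value *= 2.0 ** rng.normal(0.0, noise_sd)
            data[gi, ci] = value
    fpkm = pd.DataFrame(data, index=genes, columns=columns)

    rows = []
    ref_ct = 20.0
    target_ct0 = 26.0
    for tissue in tissues:
        for cond in conditions:
            for t in sorted(timepoints):
                for rep in (1, 2, 3):
                    noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "gene": reference_gene, "tissue": tissue,
                            "condition": cond, "timepoint": float(t),
                            "replicate": rep, "ct": ref_ct + noise,
                        }
                    )
                for g in genes:
                    f = planted_fold[g] if t in induced_timepoints else 1.0
                    ct = target_ct0 - np.log2(f)
                    for rep in (1, 2, 3):
                        rows.append(
                            {
                                "gene": g, "tissue": tissue, "condition": cond,
                                "timepoint": float(t), "replicate": rep,
                                "ct": ct + (rng.normal(0.0, ct_noise_sd)
                                            if ct_noise_sd > 0 else 0.0),
                            }
                        )
    ct_table = pd.DataFrame(rows)
    return fpkm, ct_table, planted_fold
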