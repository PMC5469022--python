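"""Promoter extraction and cis-acting element counting.

Promoters are the 2 kb of genomic sequence immediately upstream of the
start codon (strand-aware, returned 5'->3' relative to the gene).
Cis-elements are counted by exact-string scanning of short motifs such
as ABRE (CACGTG, the ABA-responsive element), MBS (CAACTG, the
MYB-binding drought-inducibility site) or HSE (AAAAAATTTC, the heat
stress element).  Both strands are scanned by default; a motif whose
reverse complement equals itself (ABRE) is counted once per site.
Overlapping occurrences count separately.  ``N`` never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from genefamscan.io_formats import GeneModel, SequenceRecord, get_logger

logger = get_logger(__name__)

#: Default motif table (name -> exact motif over ACGT).
DEFAULT_ELEMENTS: dict[str, str] = {
    "ABRE": "CACGTG",
    "LTR": "CCGAAA",
    "TC-rich": "ATTTTCTTCA",
    "TCA": "GAGAAGAATA",
    "HSE": "AAAAAATTTC",
    "TGACG": "TGACG",
    "MBS": "CAACTG",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def expand_iupac(motif: str) -> list[str]:
    """Expand an IUPAC-coded motif into its concrete ACGT strings."""
    strings = [""]
    for c in motif.upper():
        if c not in _IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r} in motif {motif!r}")
        strings = [s + b for s in strings for b in _IUPAC[c]]
    return strings


def _count_occurrences(sequence: str, motif: str) -> int:
    """Overlapping exact occurrences of motif in sequence."""
    count = 0
    pos = sequence.find(motif)
    while pos != -1:
        count += 1
        pos = sequence.find(motif, pos + 1)
    return count


def extract_promoter(
    gene_model: GeneModel,
    genome: Mapping[str, str],
    length: int = 2000,
) -> str:
    """The ``length`` bp upstream of the first CDS base, 5'->3' relative
    to the gene; truncated (with a warning) at the chromosome edge."""
    if not gene_model.cds_segments:
        raise ValueError(f"{gene_model.gene_id}: gene model has no CDS")
    if gene_model.chromosome not in genome:
        raise ValueError(f"chromosome {gene_model.chromosome!r} not in genome")
    chrom = genome[gene_model.chromosome]
    if gene_model.strand == "+":
        cds_start = gene_model.cds_segments[0][0]  # 1-based
        lo = max(1, cds_start - length)
        promoter = chrom[lo - 1 : cds_start - 1]
    else:
        cds_end = gene_model.cds_segments[-1][1]
        hi = min(len(chrom), cds_end + length)
        promoter = reverse_complement(chrom[cds_end:hi])
    if len(promoter) < length:
        logger.warning(
            "%s: promoter truncated to %d bp at chromosome edge",
            gene_model.gene_id, len(promoter),
        )
    return promoter


def scan_elements(
    promoter: str,
    table: Mapping[str, str] | None = None,
    both_strands: bool = True,
) -> dict[str, int]:
    """Count occurrences of each element motif in the promoter.

    Forward-strand hits plus (when ``both_strands``) reverse-complement
    hits; palindromic motifs are counted once per site.
    """
    table = DEFAULT_ELEMENTS if table is None else table
    promoter = promoter.upper()
    counts: dict[str, int] = {}
    for name, motif in table.items():
        total = 0
        for concrete in expand_iupac(motif):
            total += _count_occurrences(promoter, concrete)
            rc = reverse_complement(concrete)
            if both_strands and rc != concrete:
                total += _count_occurrences(promoter, rc)
        counts[name] = total
    return counts


@dataclass
class CisElementMatrix:
    """Per-gene counts of each named cis-element plus presence summaries."""

    counts: pd.DataFrame  # genes x elements, ints

    @property
    def presence(self) -> pd.Series:
        """Per element: number of genes with count > 0."""
        return (self.counts > 0).sum(axis=0)


def element_matrix(
    promoters: Sequence[SequenceRecord],
    table: Mapping[str, str] | None = None,
    both_strands: bool = True,
) -> CisElementMatrix:
    """Scan every promoter and assemble the gene x element count matrix."""
    if not promoters:
        raise ValueError("element_matrix needs at least one promoter")
    table = DEFAULT_ELEMENTS if table is None else table
    rows = {
        rec.id: scan_elements(rec.residues, table, both_strands)
        for rec in promoters
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(table)).astype(int)
    logger.info(
        "element_matrix: %d promoters x %d elements (both_strands=%s)",
        df.shape[0], df.shape[1], both_strands,
    )
    return CisElementMatrix(df)
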