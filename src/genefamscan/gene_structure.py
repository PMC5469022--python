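"""Exon/intron architecture and intron phases.

Intron phase is defined on coding sequence: phase of intron *i* is the
cumulative CDS length 5' of that intron, mod 3 (0 = between codons).
UTR-containing first/last exons are supported; non-CDS bp do not enter
the phase computation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from genefamscan.io_formats import GeneModel, get_logger

logger = get_logger(__name__)


@dataclass
class GeneArchitecture:
    gene_id: str
    n_exons: int
    n_introns: int
    exon_lengths: list[int]
    intron_lengths: list[int]
    intron_phases: list[int]
    paper_gene_length: int
    span_length: int


def architecture(gene_model: GeneModel) -> GeneArchitecture:
    """Exon/intron lengths in transcription order plus intron phases."""
    exons = gene_model.exons
    if not exons:
        raise ValueError(f"{gene_model.gene_id}: no exons")
    exon_lengths = [e - s + 1 for s, e in exons]
    intron_lengths = [
        exons[i + 1][0] - exons[i][1] - 1 for i in range(len(exons) - 1)
    ]
    if any(l <= 0 for l in intron_lengths):
        raise ValueError(f"{gene_model.gene_id}: non-positive intron length")
    # CDS bp 5' of each intron, in genomic orientation
    phases: list[int] = []
    for i in range(len(exons) - 1):
        boundary = exons[i][1]  # genomic end of exon i
        if gene_model.strand == "+":
            cds_before = sum(
                min(e, boundary) - s + 1
                for s, e, _ in gene_model.cds_segments
                if s <= boundary
            )
        else:
            # transcription runs right to left: the intron after
            # transcription-order exon i lies 5' of genomic position
            # exons[-(i+1)][0]
            boundary = exons[len(exons) - 1 - i][0]
            cds_before = sum(
                e - max(s, boundary) + 1
                for s, e, _ in gene_model.cds_segments
                if e >= boundary
            )
        phases.append(cds_before % 3)
    if gene_model.strand == "-":
        exon_lengths = exon_lengths[::-1]
        intron_lengths = intron_lengths[::-1]
    return GeneArchitecture(
        gene_id=gene_model.gene_id,
        n_exons=len(exons),
        n_introns=len(exons) - 1,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        intron_phases=phases,
        paper_gene_length=gene_model.paper_gene_length,
        span_length=gene_model.span_length,
    )


@dataclass
class GroupStructureSummary:
    group: str
    n_members: int
    modal_exon_count: int
    gene_length_range: tuple[int, int]
    deviants: list[str] = field(default_factory=list)


def family_structure_report(
    models: list[GeneModel],
    groups: dict[str, str] | None = None,
) -> dict[str, GroupStructureSummary]:
    """Per-group modal exon count, gene-length range, and members whose
    exon count deviates from the group mode.  Genes without a group
    label are summarized under "ungrouped"."""
    if not models:
        raise ValueError("no gene models")
    groups = groups or {}
    by_group: dict[str, list[GeneModel]] = {}
    for m in models:
        label = groups.get(m.gene_id) or "ungrouped"
        by_group.setdefault(label, []).append(m)
    report = {}
    for label, members in sorted(by_group.items()):
        archs = [architecture(m) for m in members]
        exon_counts = Counter(a.n_exons for a in archs)
        modal = exon_counts.most_common(1)[0][0]
        lengths = [a.paper_gene_length for a in archs]
        report[label] = GroupStructureSummary(
            group=label,
            n_members=len(members),
            modal_exon_count=modal,
            gene_length_range=(min(lengths), max(lengths)),
            deviants=[a.gene_id for a in archs if a.n_exons != modal],
        )
    return report
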