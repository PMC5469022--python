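"""Duplicated-pair detection and Nei-Gojobori (NG86) dS/dN estimation.

A pair of family members is called a duplicate when their global protein
alignment covers >= 80% of the longer sequence and the aligned region is
>= 70% identical.  A kept pair on the same chromosome is a tandem
duplicate; across chromosomes it is segmental (literal same-chromosome
reading, no adjacency window).

dS and dN come from the NG86 counting method on a codon alignment
back-threaded from the protein alignment: each codon position
contributes a synonymous-site fraction equal to the share of its
possible single-nucleotide changes (excluding changes to stop codons)
that preserve the amino acid; observed differences are classified by
averaging over all mutational pathways between the two codons, with
pathways passing through stop codons discarded and the remainder
re-weighted equally.  Proportions are Jukes-Cantor corrected,
d = -(3/4) ln(1 - (4/3) p).  omega = dN/dS; dS = 0 leaves omega
undefined (flagged).  Codons with a gap or N in either sequence are
skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log

from genefamscan.align_phylo import PairwiseAlignment, global_align
from genefamscan.io_formats import GeneModel, SequenceRecord, get_logger
from genefamscan.protein_props import translate_cds

logger = get_logger(__name__)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: dict[str, str] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _codon = _b1 + _b2 + _b3
            if _codon not in _STOPS:
                _CODON_TABLE[_codon] = translate_cds(_codon + "TAA")


@dataclass
class NGCounts:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None  # None when dS == 0

    @property
    def purifying(self) -> bool | None:
        return None if self.omega is None else self.omega < 1.0


@dataclass
class ParalogPair:
    gene_id_a: str
    gene_id_b: str
    identity: float
    coverage: float
    duplication_class: str  # tandem | segmental
    ng: NGCounts | None = None


@dataclass(frozen=True)
class DuplicationCriteria:
    coverage_min: float = 0.80
    identity_min: float = 0.70

    def __post_init__(self) -> None:
        if not (0 < self.coverage_min <= 1 and 0 < self.identity_min <= 1):
            raise ValueError("criteria must be in (0, 1]")


def find_duplicate_pairs(
    member_ids: list[str],
    proteins: dict[str, SequenceRecord],
    models: dict[str, GeneModel],
    criteria: DuplicationCriteria = DuplicationCriteria(),
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> list[ParalogPair]:
    """Score all unordered member pairs; keep those passing the
    coverage/identity criteria and class them tandem or segmental."""
    for gid in member_ids:
        if gid not in proteins:
            raise ValueError(f"member {gid} has no protein sequence")
        if gid not in models:
            raise ValueError(f"member {gid} has no gene model")
    pairs: list[ParalogPair] = []
    ordered = sorted(member_ids)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            aln = global_align(
                proteins[a], proteins[b], gap_open=gap_open, gap_extend=gap_extend
            )
            if aln.coverage >= criteria.coverage_min and aln.identity >= criteria.identity_min:
                same = models[a].chromosome == models[b].chromosome
                pairs.append(
                    ParalogPair(
                        a, b, aln.identity, aln.coverage,
                        "tandem" if same else "segmental",
                    )
                )
    logger.info("find_duplicate_pairs: %d pairs kept", len(pairs))
    return pairs


def codon_backtranslate_alignment(
    protein_alignment: PairwiseAlignment,
    cds_a: str,
    cds_b: str,
) -> list[tuple[str, str]]:
    """Thread the CDSs back through a protein alignment.

    Returns one (codon_a, codon_b) pair per alignment column; "---"
    marks a gap.  The de-gapped rows must translate exactly from the
    CDSs (terminal stop stripped).
    """
    out: list[tuple[str, str]] = []
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    ia = ib = 0
    for col, (ra, rb) in enumerate(
        zip(protein_alignment.aligned_a, protein_alignment.aligned_b)
    ):
        if ra == "-":
            codon_a = "---"
        else:
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            if len(codon_a) < 3 or translate_cds(codon_a + "TAA") != ra:
                raise ValueError(
                    f"CDS of {protein_alignment.id_a} does not encode residue "
                    f"{ra!r} at codon index {ia} (alignment column {col})"
                )
            ia += 1
        if rb == "-":
            codon_b = "---"
        else:
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            if len(codon_b) < 3 or translate_cds(codon_b + "TAA") != rb:
                raise ValueError(
                    f"CDS of {protein_alignment.id_b} does not encode residue "
                    f"{rb!r} at codon index {ib} (alignment column {col})"
                )
            ib += 1
        out.append((codon_a, codon_b))
    return out


def synonymous_site_fraction(codon: str) -> float:
    """Sum over the 3 positions of the fraction of possible changes
    (changes to stop codons excluded) that are synonymous."""
    if codon in _STOPS or codon not in _CODON_TABLE:
        raise ValueError(f"invalid codon {codon!r}")
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        possible = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutated = codon[:pos] + base + codon[pos + 1 :]
            if mutated in _STOPS:
                continue
            possible += 1
            if _CODON_TABLE[mutated] == aa:
                syn += 1
        if possible:
            s += syn / possible
    return s


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons,
    averaged with equal weight over all stop-free mutational pathways."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0
    syn_total = nsyn_total = 0.0
    n_paths = 0
    for order in permutations(diff_positions):
        current = codon_a
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _CODON_TABLE[current] == _CODON_TABLE[nxt]:
                syn += 1
            else:
                nsyn += 1
            current = nxt
        if ok:
            syn_total += syn
            nsyn_total += nsyn
            n_paths += 1
    if n_paths == 0:
        # all pathways pass through a stop; fall back to unrestricted
        # pathways so the k observed differences are still apportioned
        for order in permutations(diff_positions):
            current = codon_a
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                a_now = _CODON_TABLE.get(current, "*")
                a_nxt = _CODON_TABLE.get(nxt, "*")
                if a_now == a_nxt:
                    syn_total += 1
                else:
                    nsyn_total += 1
                current = nxt
            n_paths += 1
    return syn_total / n_paths, nsyn_total / n_paths


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Public counting primitive: (synonymous, non-synonymous)
    differences between two codons under equal pathway weighting."""
    for c in (codon_a, codon_b):
        if c in _STOPS or c not in _CODON_TABLE:
            raise ValueError(f"invalid codon {c!r}")
    return _pathway_differences(codon_a, codon_b)


def jukes_cantor(p: float) -> float:
    """JC correction d = -(3/4) ln(1 - (4/3) p); undefined for p >= 0.75."""
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor correction undefined for p = {p:.4f}")
    return -0.75 * log(1.0 - (4.0 / 3.0) * p)


def ng86(codon_alignment: list[tuple[str, str]]) -> NGCounts:
    """NG86 site and difference counts with JC correction."""
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for codon_a, codon_b in codon_alignment:
        if "-" in codon_a or "-" in codon_b or "N" in codon_a or "N" in codon_b:
            continue
        if codon_a in _STOPS or codon_b in _STOPS:
            raise ValueError(f"in-frame stop codon: {codon_a}/{codon_b}")
        n_codons += 1
        sa = synonymous_site_fraction(codon_a)
        sb = synonymous_site_fraction(codon_b)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = _pathway_differences(codon_a, codon_b)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no gap-free codon pairs in alignment")
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = dN / dS if dS > 0 else None
    return NGCounts(S, N, Sd, Nd, pS, pN, dS, dN, omega)


def pair_dnds(
    pair: ParalogPair,
    proteins: dict[str, SequenceRecord],
    cds: dict[str, str],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> ParalogPair:
    """Attach NG86 statistics to a duplicate pair."""
    aln = global_align(
        proteins[pair.gene_id_a], proteins[pair.gene_id_b],
        gap_open=gap_open, gap_extend=gap_extend,
    )
    codons = codon_backtranslate_alignment(
        aln, cds[pair.gene_id_a], cds[pair.gene_id_b]
    )
    pair.ng = ng86(codons)
    return pair


def selection_summary(pairs: list[ParalogPair]) -> dict:
    """Per-pair purifying flags and the family-level purifying count."""
    rows = []
    n_purifying = 0
    n_defined = 0
    for p in pairs:
        if p.ng is None or p.ng.omega is None:
            rows.append((p.gene_id_a, p.gene_id_b, None, None))
            continue
        n_defined += 1
        purifying = p.ng.omega < 1.0
        n_purifying += purifying
        rows.append((p.gene_id_a, p.gene_id_b, p.ng.omega, purifying))
    return {
        "pairs": rows,
        "n_pairs": len(pairs),
        "n_testable": n_defined,
        "n_purifying": n_purifying,
        "message": "no testable pairs" if n_defined == 0 else "",
    }
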