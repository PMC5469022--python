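"""Identify family candidates by conserved kinase-domain signatures.

A candidate is accepted when its protein carries both of the motifs that
make up a complete Ser/Thr kinase catalytic domain — the ATP-binding
region (consensus [IL]GXGXFGVA, with the ATP-anchoring lysine just
downstream) and the activation-loop active site ([VI]CHRDLKLENTLL, whose
aspartate is the catalytic residue) — with the ATP motif upstream of the
active site.  This deterministic signature filter replaces database
homology searches: it needs no external profile libraries and its
behaviour is fully testable against planted ground truth.

Pattern syntax: one-letter amino acids, ``X`` matches any residue,
``[AB]`` matches either alternative.  Mismatches are tolerated only at
literal (non-X, non-alternative) positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from genefamscan.io_formats import GeneModel, get_logger

logger = get_logger(__name__)

_CHROM_RE = re.compile(r"^([A-Za-z])(\d+)$")
_SCAFFOLD_RE = re.compile(r"^scaffold(\d+)_([A-Za-z])(\d+)$")


@dataclass(frozen=True)
class SignatureHit:
    signature_name: str
    start: int  # 1-based residue position
    end: int
    mismatches: int


@dataclass
class FamilyMember:
    gene_id: str
    hits: list[SignatureHit]
    protein_length: int
    assigned_name: str = ""
    chromosome: str = ""
    start: int = 0


def parse_pattern(pattern: str) -> list[frozenset[str] | None]:
    """Compile a signature pattern into per-position residue sets.

    ``None`` marks an X (wildcard) position; a frozenset marks either a
    literal (size 1) or an alternative set.
    """
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i)
            if j == -1:
                raise ValueError(f"unclosed '[' in pattern {pattern!r}")
            alts = pattern[i + 1 : j]
            if not alts or not alts.isalpha():
                raise ValueError(f"bad alternative {alts!r} in pattern {pattern!r}")
            positions.append(frozenset(alts.upper()))
            i = j + 1
        elif c == "X":
            positions.append(None)
            i += 1
        elif c.isalpha():
            positions.append(frozenset(c.upper()))
            i += 1
        else:
            raise ValueError(f"unexpected character {c!r} in pattern {pattern!r}")
    if not positions:
        raise ValueError("empty pattern")
    return positions


def _match_at(protein: str, pos: int, compiled, max_mismatch: int) -> int | None:
    """Mismatch count if the pattern matches at 0-based ``pos``, else None."""
    mism = 0
    for k, allowed in enumerate(compiled):
        if allowed is None:
            continue
        residue = protein[pos + k]
        if residue not in allowed:
            if len(allowed) > 1:
                return None  # alternatives are strict
            mism += 1
            if mism > max_mismatch:
                return None
    return mism


def scan_signatures(
    protein: str,
    signature_defs: dict[str, str],
    max_mismatch: int = 0,
) -> list[SignatureHit]:
    """All positions where each signature matches with <= max_mismatch
    substitutions at literal positions; leftmost-first per signature."""
    hits: list[SignatureHit] = []
    for name, pattern in signature_defs.items():
        compiled = parse_pattern(pattern)
        width = len(compiled)
        for pos in range(len(protein) - width + 1):
            mism = _match_at(protein, pos, compiled, max_mismatch)
            if mism is not None:
                hits.append(SignatureHit(name, pos + 1, pos + width, mism))
    return hits


def filter_candidates(
    proteins,
    signature_defs: dict[str, str],
    max_mismatch: int = 0,
) -> tuple[list[FamilyMember], list[tuple[str, str]]]:
    """Accept candidates carrying both signatures (ATP motif upstream of
    the active site); collapse redundant identical sequences.

    Returns (accepted members, rejection log of (gene_id, reason)).
    """
    if "ATP_binding" not in signature_defs or "active_site" not in signature_defs:
        raise ValueError("signature_defs must define ATP_binding and active_site")
    accepted: list[FamilyMember] = []
    log: list[tuple[str, str]] = []
    seen_sequences: dict[str, str] = {}
    for rec in proteins:
        if rec.residues in seen_sequences:
            log.append(
                (rec.id, f"redundant: identical to {seen_sequences[rec.residues]}")
            )
            continue
        hits = scan_signatures(rec.residues, signature_defs, max_mismatch)
        atp = [h for h in hits if h.signature_name == "ATP_binding"]
        act = [h for h in hits if h.signature_name == "active_site"]
        if not atp and not act:
            log.append((rec.id, "missing: ATP_binding, active_site"))
        elif not act:
            log.append((rec.id, "missing: active_site"))
        elif not atp:
            log.append((rec.id, "missing: ATP_binding"))
        elif not any(a.start < b.start for a in atp for b in act):
            log.append((rec.id, "domain order: ATP_binding not upstream of active_site"))
        else:
            seen_sequences[rec.residues] = rec.id
            accepted.append(FamilyMember(rec.id, hits, len(rec.residues)))
    logger.info(
        "filter_candidates: %d accepted, %d rejected", len(accepted), len(log)
    )
    return accepted, log


def chromosome_sort_key(chromosome: str) -> tuple:
    """Sort key implementing chromosome-ordered family naming.

    A-subgenome before D (alphabetical subgenome letter), chromosome
    number ascending, genes on placed chromosomes before genes on
    scaffolds anchored to that chromosome, scaffolds by their number.
    Unrecognized chromosome names sort last, alphabetically.
    """
    m = _CHROM_RE.match(chromosome)
    if m:
        return (0, m.group(1).upper(), int(m.group(2)), 0, 0, chromosome)
    m = _SCAFFOLD_RE.match(chromosome)
    if m:
        return (0, m.group(2).upper(), int(m.group(3)), 1, int(m.group(1)), chromosome)
    return (1, "", 0, 0, 0, chromosome)


def assign_names(
    members: list[FamilyMember],
    gene_models: dict[str, GeneModel],
    prefix: str = "FAM",
) -> list[FamilyMember]:
    """Assign ``<prefix><ordinal>`` names following chromosome order and
    position (top to bottom) within each chromosome.

    Ties on (chromosome, start) break by gene_id lexicographically (logged).
    """
    for m in members:
        if m.gene_id not in gene_models:
            raise ValueError(f"member {m.gene_id} has no gene model")
        model = gene_models[m.gene_id]
        m.chromosome = model.chromosome
        m.start = model.start

    def key(m: FamilyMember):
        return (*chromosome_sort_key(m.chromosome), m.start, m.gene_id)

    ordered = sorted(members, key=key)
    for i in range(1, len(ordered)):
        a, b = ordered[i - 1], ordered[i]
        if (a.chromosome, a.start) == (b.chromosome, b.start):
            logger.info(
                "tie at %s:%d broken lexicographically: %s before %s",
                a.chromosome, a.start, a.gene_id, b.gene_id,
            )
    for ordinal, m in enumerate(ordered, start=1):
        m.assigned_name = f"{prefix}{ordinal}"
    return ordered
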