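import itertools
import math

import numpy as np
import pytest

from genefamscan.align_phylo import global_align
from genefamscan.dup_dnds import (
    DuplicationCriteria,
    codon_backtranslate_alignment,
    find_duplicate_pairs,
    jukes_cantor,
    ng86,
    selection_summary,
    synonymous_site_fraction,
)
from genefamscan.io_formats import GeneModel, SequenceRecord
from genefamscan.synthetic_data import mutate_paralog_cds
from genefamscan.protein_props import translate_cds

STOPS = {"TAA", "TAG", "TGA"}
CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS
]
AA = {c: translate_cds(c + "TAA") for c in CODONS}


# ---------------------------------------------------------------------------
# independent NG86 oracle: explicit enumeration, no code shared with the
# implementation
# ---------------------------------------------------------------------------


def oracle_sites(codon):
    total = 0.0
    for pos in range(3):
        changes = []
        for base in "ACGT":
            if base != codon[pos]:
                mut = codon[:pos] + base + codon[pos + 1 :]
                if mut not in STOPS:
                    changes.append(AA[mut] == AA[codon])
        if changes:
            total += sum(changes) / len(changes)
    return total


def oracle_differences(ca, cb):
    positions = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(positions):
        cur, syn, nsyn, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            if AA[cur] == AA[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if not blocked:
            paths.append((syn, nsyn))
    if not paths:
        return None
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


class TestNg86Oracle:
    def test_hand_worked_fourfold_site(self):
        result = ng86([("GGG", "GGA"), ("GGG", "GGG")])
        assert result.S == pytest.approx(2.0)
        assert result.N == pytest.approx(4.0)
        assert result.Sd == pytest.approx(1.0)
        assert result.pS == pytest.approx(0.5)
        assert result.dS == pytest.approx(-0.75 * math.log(1 / 3), abs=1e-4)
        assert result.dN == 0.0

    def test_identical_alignment_omega_undefined(self):
        result = ng86([("ATG", "ATG"), ("GGA", "GGA")])
        assert result.Sd == result.Nd == 0.0
        assert result.omega is None

    def test_site_fractions_match_oracle_for_all_codons(self):
        for codon in CODONS:
            assert synonymous_site_fraction(codon) == pytest.approx(
                oracle_sites(codon)
            )

    def test_differences_match_oracle_on_many_codon_pairs(self):
        from genefamscan.dup_dnds import pathway_differences

        rng = np.random.default_rng(17)
        idx = rng.integers(0, len(CODONS), size=(400, 2))
        for i, j in idx:
            ca, cb = CODONS[i], CODONS[j]
            want = oracle_differences(ca, cb)
            if want is None:
                continue
            assert pathway_differences(ca, cb) == pytest.approx(want), (ca, cb)

    def test_site_conservation(self):
        # pairs differing by at most one position (non-saturating)
        rng = np.random.default_rng(23)
        pairs = []
        for i in rng.integers(0, len(CODONS), size=40):
            ca = CODONS[i]
            pos = int(rng.integers(0, 3))
            base = str(rng.choice(list("ACGT")))
            cb = ca[:pos] + base + ca[pos + 1 :]
            if cb not in STOPS:
                pairs.append((ca, cb))
        result = ng86(pairs)
        assert result.S + result.N == pytest.approx(3 * len(pairs), abs=1e-9)

    def test_gap_and_n_codons_skipped(self):
        result = ng86(
            [("GGG", "GGA"), ("GGG", "GGG"), ("GGG", "GGG"),
             ("---", "ATG"), ("ANG", "ATG")]
        )
        # only the three gap/N-free codons count: S = 3 x 1.0
        assert result.S == pytest.approx(3.0)
        assert result.S + result.N == pytest.approx(9.0)

    def test_stop_in_frame_is_error(self):
        with pytest.raises(ValueError, match="stop"):
            ng86([("TAA", "ATG")])

    def test_saturation_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            jukes_cantor(0.8)


class TestPlantedRecovery:
    def test_planted_counts_recovered_exactly(self):
        # single-position changes at distinct codons: Sd and Nd must
        # equal the planted counts exactly, over 20 seeded simulations
        rng = np.random.default_rng(0)
        base = "".join(
            CODONS[i] for i in rng.integers(0, len(CODONS), size=300)
        ) + "TAA"
        for seed in range(20):
            srng = np.random.default_rng(seed)
            n_syn = int(srng.integers(0, 16))
            n_nonsyn = int(srng.integers(0, 16))
            mutated, log = mutate_paralog_cds(base, n_syn, n_nonsyn, seed)
            assert len(log) == n_syn + n_nonsyn
            aln = global_align(
                translate_cds(base), translate_cds(mutated)
            )
            codons = codon_backtranslate_alignment(aln, base, mutated)
            result = ng86(codons)
            assert result.Sd == pytest.approx(n_syn)
            assert result.Nd == pytest.approx(n_nonsyn)
            if n_syn and result.dS > 0 and n_nonsyn / result.N < n_syn / result.S:
                assert result.omega < 1.0

    def test_family_pairs_recover_planted_counts(self, small_family):
        proteins = {r.id: r for r in small_family.proteins}
        cds = {r.id: r.residues for r in small_family.cds}
        for a, b, n_syn, n_nonsyn in small_family.truth.pairs:
            aln = global_align(proteins[a], proteins[b])
            codons = codon_backtranslate_alignment(aln, cds[a], cds[b])
            result = ng86(codons)
            assert result.Sd == pytest.approx(n_syn)
            assert result.Nd == pytest.approx(n_nonsyn)
            assert result.omega is not None and result.omega < 1.0


class TestMutateParalog:
    def test_zero_changes_identity(self):
        cds = "ATGGCTGCA" + "TAA"
        mutated, log = mutate_paralog_cds(cds, 0, 0, 1)
        assert mutated == cds and log == []

    def test_protein_changes_only_at_nonsynonymous_sites(self):
        rng = np.random.default_rng(4)
        base = "".join(
            CODONS[i] for i in rng.integers(0, len(CODONS), size=60)
        ) + "TAA"
        mutated, _ = mutate_paralog_cds(base, 3, 1, 2)
        pa, pb = translate_cds(base), translate_cds(mutated)
        assert sum(x != y for x, y in zip(pa, pb)) == 1

    def test_insufficient_codons_is_error(self):
        cds = "ATG" * 10 + "TAA"
        with pytest.raises(ValueError):
            mutate_paralog_cds(cds, 50, 0, 1)


class TestDuplicatePairs:
    def _inputs(self):
        prot = {
            "a": SequenceRecord("a", "MKVAYWDELTRN" * 5),
            "b": SequenceRecord("b", "MKVAYWDELTRN" * 5),
            "c": SequenceRecord("c", "MKVAYWDELTRH" * 5),
        }
        models = {
            "a": GeneModel("a", "A01", "+", 1, 100, [(1, 100)]),
            "b": GeneModel("b", "A01", "+", 500, 600, [(500, 600)]),
            "c": GeneModel("c", "D01", "+", 1, 100, [(1, 100)]),
        }
        return prot, models

    def test_same_chromosome_is_tandem(self):
        prot, models = self._inputs()
        pairs = find_duplicate_pairs(["a", "b"], prot, models)
        assert len(pairs) == 1 and pairs[0].duplication_class == "tandem"

    def test_cross_chromosome_is_segmental(self):
        prot, models = self._inputs()
        pairs = find_duplicate_pairs(["a", "c"], prot, models)
        assert len(pairs) == 1 and pairs[0].duplication_class == "segmental"

    def test_low_identity_excluded(self):
        prot, models = self._inputs()
        prot["c"] = SequenceRecord("c", "GGGGHHHHIIII" * 5)
        pairs = find_duplicate_pairs(["a", "c"], prot, models)
        assert pairs == []

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            DuplicationCriteria(coverage_min=1.5)

    def test_homoeologous_pairs_all_segmental(self, family42):
        proteins = {r.id: r for r in family42.proteins}
        models = {m.gene_id: m for m in family42.models}
        pairs = find_duplicate_pairs(family42.truth.members, proteins, models)
        kept = {frozenset((p.gene_id_a, p.gene_id_b)): p for p in pairs}
        for a, b, _, _ in family42.truth.pairs:
            pair = kept[frozenset((a, b))]
            assert pair.duplication_class == "segmental"
            assert pair.identity >= 0.9


class TestBacktranslation:
    def test_gap_free_concatenation(self):
        aln = global_align("MK", "MK")
        codons = codon_backtranslate_alignment(aln, "ATGAAATAA", "ATGAAGTAA")
        assert codons == [("ATG", "ATG"), ("AAA", "AAG")]

    def test_gap_column(self):
        aln = global_align("MKV", "MV")
        codons = codon_backtranslate_alignment(aln, "ATGAAAGTTTAA", "ATGGTTTAA")
        assert ("AAA", "---") in codons

    def test_mismatching_cds_is_error(self):
        aln = global_align("MK", "MK")
        with pytest.raises(ValueError, match="codon index"):
            codon_backtranslate_alignment(aln, "ATGGGGTAA", "ATGAAATAA")


def test_selection_summary_flags():
    from genefamscan.dup_dnds import NGCounts, ParalogPair

    def pair(omega):
        p = ParalogPair("a", "b", 0.9, 0.9, "segmental")
        p.ng = NGCounts(10, 20, 1, 1, 0.1, 0.05, 0.1, 0.05, omega)
        return p

    report = selection_summary([pair(0.12), pair(1.5), pair(None)])
    assert report["n_purifying"] == 1
    assert report["n_testable"] == 2
    empty = selection_summary([pair(None)])
    assert empty["message"] == "no testable pairs"
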