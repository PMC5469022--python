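import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from genefamscan.align_phylo import (
    DistanceMatrix,
    bootstrap_support,
    center_star_msa,
    global_align,
    pdistance_matrix,
    upgma,
)
from genefamscan.io_formats import SequenceRecord

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_align_score(a, b, score, gap_open, gap_extend):
    """Exhaustive enumeration of all global alignments (no DP reuse)."""

    best = [float("-inf")]

    def recurse(i, j, acc, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], acc)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, acc + score[(a[i], b[j])], "M")
        if i < len(a):  # gap in b
            cost = gap_extend if last == "GB" else gap_open
            recurse(i + 1, j, acc - cost, "GB")
        if j < len(b):  # gap in a
            cost = gap_extend if last == "GA" else gap_open
            recurse(i, j + 1, acc - cost, "GA")

    recurse(0, 0, 0.0, None)
    return best[0]


def scipy_upgma_cophenetic(ids, values):
    """Cophenetic distances from scipy average-linkage clustering."""
    condensed = squareform(values, checks=False)
    z = linkage(condensed, method="average")
    return squareform(cophenet(z))


def tree_cophenetic(tree, ids):
    """Cophenetic matrix of a tree: 2 x LCA height for each leaf pair."""
    n = len(ids)
    out = np.zeros((n, n))
    index = {name: i for i, name in enumerate(ids)}

    def walk(node):
        if not node.children:
            return [node.name]
        sides = [walk(c) for c in node.children]
        for left, right in itertools.combinations(sides, 2):
            for x in left:
                for y in right:
                    out[index[x], index[y]] = out[index[y], index[x]] = (
                        2 * node.height
                    )
        return [l for side in sides for l in side]

    walk(tree.root)
    return out


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("MKVAYW", "MKVAYW")
        assert aln.identity == 1.0 and aln.coverage == 1.0

    def test_single_gap_column(self):
        aln = global_align("AW", "W")
        assert aln.n_aligned_columns == 1
        assert aln.identity == 1.0
        assert aln.coverage == 0.5

    def test_degapping_recovers_inputs(self):
        aln = global_align("MKVAYWDEL", "MKWDEL")
        assert aln.aligned_a.replace("-", "") == "MKVAYWDEL"
        assert aln.aligned_b.replace("-", "") == "MKWDEL"

    def test_unknown_residue_is_error(self):
        with pytest.raises(ValueError, match="not in substitution matrix"):
            global_align("MK1", "MK")

    def test_score_symmetry(self):
        a, b = "MKVAYWDEL", "MKWDELTTR"
        assert global_align(a, b).score == global_align(b, a).score
        assert global_align(a, b).identity == global_align(b, a).identity

    def test_matches_exhaustive_enumeration(self):
        # random sequence pairs of length <= 5 over a 4-letter alphabet,
        # scored against an oracle that enumerates every alignment
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        alphabet = "ARND"
        score = {(x, y): float(m[x, y]) for x in alphabet for y in alphabet}
        rng = np.random.default_rng(5)
        for _ in range(120):
            la, lb = rng.integers(1, 6, size=2)
            a = "".join(rng.choice(list(alphabet), size=la))
            b = "".join(rng.choice(list(alphabet), size=lb))
            got = global_align(a, b, gap_open=10.0, gap_extend=0.5).score
            want = brute_force_align_score(a, b, score, 10.0, 0.5)
            assert got == pytest.approx(want), (a, b)

    def test_alignment_score_consistent_with_strings(self):
        # recompute the score from the reported alignment strings
        rng = np.random.default_rng(3)
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        for _ in range(20):
            a = "".join(rng.choice(list("MKVAYWDELTRN"), size=rng.integers(3, 15)))
            b = "".join(rng.choice(list("MKVAYWDELTRN"), size=rng.integers(3, 15)))
            aln = global_align(a, b)
            total, last = 0.0, None
            for x, y in zip(aln.aligned_a, aln.aligned_b):
                if x == "-" or y == "-":
                    state = "A" if x == "-" else "B"
                    total -= 0.5 if last == state else 10.0
                    last = state
                else:
                    total += float(m[x, y])
                    last = None
            assert total == pytest.approx(aln.score), (a, b)


# ---------------------------------------------------------------------------
# center-star MSA
# ---------------------------------------------------------------------------


class TestCenterStar:
    def test_two_sequences_equals_pairwise(self):
        recs = [SequenceRecord("a", "MKVAYW"), SequenceRecord("b", "MKYW")]
        msa = center_star_msa(recs)
        aln = global_align(recs[0], recs[1])
        assert msa[0].residues == aln.aligned_a
        assert msa[1].residues == aln.aligned_b

    def test_identical_sequences_gap_free(self):
        recs = [SequenceRecord(i, "MKVAYW") for i in "abc"]
        msa = center_star_msa(recs)
        assert all(r.residues == "MKVAYW" for r in msa)

    def test_degapping_and_width(self, small_family):
        seqs = [
            r for r in small_family.proteins
            if r.id in small_family.truth.members
        ]
        msa = center_star_msa(seqs)
        width = len(msa[0].residues)
        assert width >= max(len(s.residues) for s in seqs)
        originals = {s.id: s.residues for s in seqs}
        for row in msa:
            assert len(row.residues) == width
            assert row.residues.replace("-", "") == originals[row.id]

    def test_fewer_than_two_is_error(self):
        with pytest.raises(ValueError):
            center_star_msa([SequenceRecord("a", "MK")])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = [SequenceRecord("a", "AAAA"), SequenceRecord("b", "AAAA")]
        assert pdistance_matrix(msa).values[0, 1] == 0.0

    def test_quarter_difference(self):
        msa = [SequenceRecord("a", "AAAA"), SequenceRecord("b", "AAAT")]
        assert pdistance_matrix(msa).values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        msa = [SequenceRecord("a", "A-AA"), SequenceRecord("b", "AAAA")]
        assert pdistance_matrix(msa).values[0, 1] == 0.0
        msa = [SequenceRecord("a", "T-AA"), SequenceRecord("b", "AAAA")]
        assert pdistance_matrix(msa).values[0, 1] == pytest.approx(1 / 3)

    def test_no_shared_columns_is_error(self):
        msa = [SequenceRecord("a", "A--"), SequenceRecord("b", "-AA")]
        with pytest.raises(ValueError, match="a.*b"):
            pdistance_matrix(msa)

    def test_poisson_correction_larger(self):
        msa = [SequenceRecord("a", "AAAT"), SequenceRecord("b", "AATT")]
        p = pdistance_matrix(msa, "p").values[0, 1]
        pc = pdistance_matrix(msa, "poisson").values[0, 1]
        assert pc > p


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


class TestUpgma:
    def test_hand_worked_three_taxa(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = upgma(d)
        by_name = {l.name: l for l in tree.root.leaves()}
        assert by_name["A"].branch_length == pytest.approx(1.0)
        assert by_name["B"].branch_length == pytest.approx(1.0)
        assert by_name["C"].branch_length == pytest.approx(2.0)
        inner = next(c for c in tree.root.children if c.children)
        assert sorted(inner.leaf_names()) == ["A", "B"]
        assert inner.branch_length == pytest.approx(1.0)

    def test_two_taxa(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = upgma(d)
        for leaf in tree.root.leaves():
            assert leaf.branch_length == pytest.approx(1.5)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(11)
        ids = list("ABCDE")
        for _ in range(25):
            raw = rng.uniform(0.1, 2.0, size=(5, 5))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0.0)
            tree = upgma(DistanceMatrix(ids, values))
            mine = tree_cophenetic(tree, ids)
            want = scipy_upgma_cophenetic(ids, values)
            assert np.allclose(mine, want, atol=1e-12)

    def test_ultrametric_output(self, small_family):
        seqs = [
            r for r in small_family.proteins
            if r.id in small_family.truth.members
        ]
        msa = center_star_msa(seqs)
        tree = upgma(pdistance_matrix(msa))
        assert tree.max_path_spread() < 1e-9

    def test_nan_distance_is_error(self):
        values = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            upgma(DistanceMatrix(["A", "B"], values))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _clade_msa():
    rng = np.random.default_rng(2)
    base1 = "".join(rng.choice(list("MKVAYW"), size=60))
    base2 = "".join(rng.choice(list("DELTRN"), size=60))

    def vary(base, k):
        seq = list(base)
        for pos in rng.choice(60, size=k, replace=False):
            seq[pos] = str(rng.choice(list("GHIS")))
        return "".join(seq)

    return [
        SequenceRecord("a1", vary(base1, 2)),
        SequenceRecord("a2", vary(base1, 2)),
        SequenceRecord("b1", vary(base2, 2)),
        SequenceRecord("b2", vary(base2, 2)),
    ]


class TestBootstrap:
    def test_planted_clades_highly_supported(self):
        tree = bootstrap_support(_clade_msa(), replicates=200, seed=9)
        supports = [
            n.support for n in tree.internal_nodes() if n.support is not None
        ]
        assert supports and all(s >= 0.95 for s in supports)

    def test_supports_in_unit_interval(self):
        tree = bootstrap_support(_clade_msa(), replicates=50, seed=1)
        for node in tree.internal_nodes():
            if node.support is not None:
                assert 0.0 <= node.support <= 1.0

    def test_zero_replicates_forbidden(self):
        with pytest.raises(ValueError):
            bootstrap_support(_clade_msa(), replicates=0, seed=1)

    def test_same_seed_reproducible(self):
        t1 = bootstrap_support(_clade_msa(), replicates=100, seed=4)
        t2 = bootstrap_support(_clade_msa(), replicates=100, seed=4)
        s1 = sorted(n.support for n in t1.internal_nodes() if n.support is not None)
        s2 = sorted(n.support for n in t2.internal_nodes() if n.support is not None)
        assert s1 == s2

    def test_support_converges_with_replicates(self):
        msa = _clade_msa()
        t1 = bootstrap_support(msa, replicates=1000, seed=6)
        t2 = bootstrap_support(msa, replicates=2000, seed=13)
        bp1 = {k: n.support for k, n in t1.bipartitions().items()}
        bp2 = {k: n.support for k, n in t2.bipartitions().items()}
        for key, s1 in bp1.items():
            if key in bp2:
                sigma = np.sqrt(max(s1 * (1 - s1), 1e-4) / 1000)
                assert abs(bp2[key] - s1) <= 2 * sigma + 0.02
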