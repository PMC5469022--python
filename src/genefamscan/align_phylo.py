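"""Pairwise and multiple protein alignment, distance matrices, and UPGMA
trees with bootstrap supports.

Pairwise alignment is global (Needleman-Wunsch) with affine gaps under a
BLOSUM62 substitution matrix: a gap of length L costs
``gap_open + (L - 1) * gap_extend``.  The multiple alignment is a
center-star construction (align everything to the sequence with minimal
total pairwise distance, merging by "once a gap, always a gap") — a
deterministic stand-in for progressive aligners, adequate for the highly
similar sequences of a single gene family but not for deeply diverged
inputs.

Distances are p-distances with pairwise deletion (optionally
Poisson-corrected, -ln(1 - p)).  UPGMA joins the closest pair, placing
the new node at half the joined distance, with size-weighted arithmetic
means for merged distances; its output is ultrametric by construction.
Bootstrap support of an internal edge is the fraction of
column-resampled replicates whose UPGMA tree contains the same leaf
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from genefamscan.io_formats import SequenceRecord, get_logger

logger = get_logger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def n_aligned_columns(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        )

    @property
    def n_matches(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and x == y
        )

    @property
    def identity(self) -> float:
        cols = self.n_aligned_columns
        return self.n_matches / cols if cols else 0.0

    @property
    def coverage(self) -> float:
        longer = max(
            len(self.aligned_a.replace("-", "")),
            len(self.aligned_b.replace("-", "")),
        )
        return self.n_aligned_columns / longer


def _matrix_arrays(matrix) -> tuple[dict[str, int], np.ndarray]:
    alpha = matrix.alphabet
    index = {r: i for i, r in enumerate(alpha)}
    values = np.asarray(matrix, dtype=float)
    return index, values


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gaps.

    Traceback ties prefer match/mismatch over a gap in ``a`` over a gap
    in ``b``, making the reported alignment deterministic.
    """
    id_a, id_b = "a", "b"
    if isinstance(a, SequenceRecord):
        id_a, a = a.id, a.residues
    if isinstance(b, SequenceRecord):
        id_b, b = b.id, b.residues
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    matrix = _BLOSUM62 if matrix is None else matrix
    index, values = _matrix_arrays(matrix)
    for s in (a, b):
        for r in s:
            if r not in index:
                raise ValueError(f"residue {r!r} not in substitution matrix")

    n, m = len(a), len(b)
    idx_a = np.array([index[r] for r in a])
    idx_b = np.array([index[r] for r in b])
    sub = values[np.ix_(idx_a, idx_b)]

    # M: a[i-1] aligned to b[j-1]; GA: gap in a (consumes b);
    # GB: gap in b (consumes a)
    M = np.full((n + 1, m + 1), NEG_INF)
    GA = np.full((n + 1, m + 1), NEG_INF)
    GB = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    js = np.arange(1, m + 1)
    GA[0, 1:] = -(gap_open + (js - 1) * gap_extend)
    ii = np.arange(1, n + 1)
    GB[1:, 0] = -(gap_open + (ii - 1) * gap_extend)

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], GA[i - 1]), GB[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        GB[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], GA[i - 1, 1:]) - gap_open,
            GB[i - 1, 1:] - gap_extend,
        )
        # GA within-row recurrence via prefix max:
        # GA[i, j] = max(max(M[i, j-1], GB[i, j-1]) - open, GA[i, j-1] - ext)
        base = np.maximum(M[i, :-1], GB[i, :-1]) - gap_open + gap_extend * js
        GA[i, 1:] = np.maximum.accumulate(base) - gap_extend * js

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    finals = {"M": M[n, m], "GA": GA[n, m], "GB": GB[n, m]}
    state = max(("M", "GA", "GB"), key=lambda s: (finals[s], s == "M", s == "GA"))
    score = finals[state]
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand in ("M", "GA", "GB"):
                v = {"M": M, "GA": GA, "GB": GB}[cand][i, j]
                if abs(v - target) < eps:
                    state = cand
                    break
        elif state == "GA":
            out_a.append("-")
            out_b.append(b[j - 1])
            val = GA[i, j]
            j -= 1
            if abs(M[i, j] - gap_open - val) < eps:
                state = "M"
            elif abs(GB[i, j] - gap_open - val) < eps:
                state = "GB"
            else:
                state = "GA"
        else:  # GB
            out_a.append(a[i - 1])
            out_b.append("-")
            val = GB[i, j]
            i -= 1
            if abs(M[i, j] - gap_open - val) < eps:
                state = "M"
            elif abs(GA[i, j] - gap_open - val) < eps:
                state = "GA"
            else:
                state = "GB"
    return PairwiseAlignment(
        id_a, id_b, "".join(reversed(out_a)), "".join(reversed(out_b)), score
    )


# ---------------------------------------------------------------------------
# center-star MSA
# ---------------------------------------------------------------------------


def _merge_into_master(master: str, pair_center: str, pair_other: str,
                       rows: list[list[str]]) -> tuple[str, str]:
    """Merge a (center, other) pairwise alignment into the master center
    string, inserting gaps into existing rows as needed ("once a gap,
    always a gap").  Returns the updated master and the other sequence
    padded to the master's gapping."""
    out_master: list[str] = []
    out_other: list[str] = []
    insertions: list[int] = []  # master columns needing a new gap
    i = j = 0  # i over master, j over pair_center
    while i < len(master) or j < len(pair_center):
        mc = master[i] if i < len(master) else None
        pc = pair_center[j] if j < len(pair_center) else None
        if mc == "-" and (pc != "-" or j >= len(pair_center)):
            out_master.append("-")
            out_other.append("-")
            i += 1
        elif pc == "-" and (mc != "-" or i >= len(master)):
            out_master.append("-")
            out_other.append(pair_other[j])
            insertions.append(len(out_master) - 1)
            j += 1
        else:
            out_master.append(mc)
            out_other.append(pair_other[j])
            i += 1
            j += 1
    for col in insertions:
        for row in rows:
            row.insert(col, "-")
    return "".join(out_master), "".join(out_other)


def center_star_msa(
    sequences: list[SequenceRecord],
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> list[SequenceRecord]:
    """Center-star multiple alignment; rows returned in input order."""
    if len(sequences) < 2:
        raise ValueError("center_star_msa needs at least 2 sequences")
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(sequences)
    pairwise: dict[tuple[int, int], PairwiseAlignment] = {}
    total_dist = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(
                sequences[i], sequences[j], matrix, gap_open, gap_extend
            )
            pairwise[(i, j)] = aln
            d = 1.0 - aln.identity
            total_dist[i] += d
            total_dist[j] += d
    center = min(range(n), key=lambda k: (total_dist[k], ids[k]))
    logger.info("center-star center: %s", ids[center])

    master = sequences[center].residues
    rows: list[list[str]] = []
    row_ids: list[str] = []
    for k in range(n):
        if k == center:
            continue
        key = (center, k) if center < k else (k, center)
        aln = pairwise[key]
        if key[0] == center:
            pc, po = aln.aligned_a, aln.aligned_b
        else:
            pc, po = aln.aligned_b, aln.aligned_a
        master, padded = _merge_into_master(master, pc, po, rows)
        rows.append(list(padded))
        row_ids.append(ids[k])
    # pad any short rows (gaps appended at the end of later merges)
    width = len(master)
    aligned = {ids[center]: master}
    for rid, row in zip(row_ids, rows):
        row.extend("-" * (width - len(row)))
        aligned[rid] = "".join(row)
    out = [SequenceRecord(s.id, aligned[s.id], s.description) for s in sequences]
    for rec, src in zip(out, sequences):
        if rec.residues.replace("-", "") != src.residues:
            raise AssertionError(f"MSA row {rec.id} does not de-gap to its input")
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(v < 0):  # NaN compares False; upgma rejects NaN itself
            raise ValueError("negative distances")
        self.values = v


def pdistance_matrix(
    msa: list[SequenceRecord], model: str = "p"
) -> DistanceMatrix:
    """p-distance (or Poisson-corrected) with pairwise deletion."""
    if model not in {"p", "poisson"}:
        raise ValueError(f"unknown distance model {model!r}")
    ids = [r.id for r in msa]
    arr = np.array([list(r.residues) for r in msa])
    if arr.ndim != 2:
        raise ValueError("MSA rows differ in length")
    n = len(ids)
    d = np.zeros((n, n))
    nongap = arr != "-"
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no shared non-gap columns between {ids[i]} and {ids[j]}"
                )
            p = float((arr[i][shared] != arr[j][shared]).sum()) / n_shared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined for p=1 ({ids[i]}, {ids[j]})"
                    )
                p = -float(np.log(1.0 - p))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0
    branch_length: float = 0.0
    support: float | None = None

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class UltrametricTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if node.children:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial leaf bipartitions, keyed by the normalized side
        (the side not containing the alphabetically first leaf)."""
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}
        for node in self.internal_nodes():
            clade = set(node.leaf_names())
            if len(clade) <= 1 or len(all_leaves - clade) <= 1:
                continue
            side = clade if anchor not in clade else all_leaves - clade
            out[frozenset(side)] = node
        return out

    def max_path_spread(self) -> float:
        """Spread of root-to-leaf path lengths (0 for ultrametric)."""
        depths = []

        def walk(node: TreeNode, depth: float) -> None:
            if not node.children:
                depths.append(depth)
            for c in node.children:
                walk(c, depth + c.branch_length)

        walk(self.root, 0.0)
        return max(depths) - min(depths)


def upgma(dist: DistanceMatrix) -> UltrametricTree:
    """UPGMA agglomeration.

    Joins the minimal-distance pair (ties: lexicographically smallest
    sorted id pair, cluster id = smallest leaf name); the new node sits
    at height d_min / 2; distances to other clusters are size-weighted
    arithmetic means.
    """
    n = len(dist.ids)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    if np.any(np.isnan(dist.values)):
        raise ValueError("NaN in distance matrix")
    clusters: dict[str, TreeNode] = {
        name: TreeNode(name=name) for name in dist.ids
    }
    sizes = {name: 1 for name in dist.ids}
    d: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((dist.ids[i], dist.ids[j]))] = dist.values[i, j]
    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted(kv[0]))),
        )
        pair, dmin = best
        ca, cb = sorted(pair)
        height = dmin / 2.0
        node_a, node_b = clusters.pop(ca), clusters.pop(cb)
        node_a.branch_length = height - node_a.height
        node_b.branch_length = height - node_b.height
        new = TreeNode(children=[node_a, node_b], height=height)
        new_id = ca  # smallest leaf name in merged cluster
        na, nb = sizes.pop(ca), sizes.pop(cb)
        for other in clusters:
            da = d.pop(frozenset((ca, other)))
            db = d.pop(frozenset((cb, other)))
            d[frozenset((new_id, other))] = (na * da + nb * db) / (na + nb)
        del d[pair]
        clusters[new_id] = new
        sizes[new_id] = na + nb
    root = next(iter(clusters.values()))
    root.branch_length = 0.0
    return UltrametricTree(root)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    msa: list[SequenceRecord],
    replicates: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> UltrametricTree:
    """UPGMA tree from the full MSA, with per-edge bootstrap supports.

    Columns are resampled with replacement per replicate; support of an
    internal edge is the fraction of replicates whose tree contains the
    same leaf bipartition.  Replicates whose resampled columns leave
    some pair with no shared sites are discarded (logged)."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    width = len(msa[0].residues)
    if width < 2:
        raise ValueError("MSA must have at least 2 columns")
    tree = upgma(pdistance_matrix(msa, model))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    used = 0
    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        resampled = [
            SequenceRecord(r.id, "".join(r.residues[c] for c in cols))
            for r in msa
        ]
        try:
            rep_tree = upgma(pdistance_matrix(resampled, model))
        except ValueError:
            continue
        used += 1
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if used < replicates:
        logger.warning(
            "bootstrap: %d of %d replicates discarded", replicates - used, replicates
        )
    if used == 0:
        raise ValueError("all bootstrap replicates failed")
    for bp, node in target.items():
        node.support = counts[bp] / used
    return tree
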