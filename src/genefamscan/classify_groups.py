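"""Group I/II/III assignment from tree clades and C-terminal composition.

The kinase family splits into three groups: Group III members carry a
C-terminal ABA-specific box (Domain II) and are strongly ABA-activated;
Group II members lack the box but are aspartate-rich; Group I members
carry a glutamate-rich (poly-E) acidic patch and are not ABA-activated.
All members carry the family-specific box (Domain I) required for
osmotic-stress activation.

Tree-based assignment is primary: a member takes the majority group of
the reference leaves inside its smallest reference-containing clade.
C-terminal typing — the maximal D+E sliding window in the C-terminal
third, plus box pattern matches — is the cross-check; disagreements
(Group III without an ABA box, Group I without a poly-E patch) are
flagged, not overridden.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from genefamscan.align_phylo import TreeNode, UltrametricTree
from genefamscan.family_id import scan_signatures
from genefamscan.io_formats import get_logger

logger = get_logger(__name__)

#: Consensus patterns for the two C-terminal boxes (editable via config).
#: Domain I (family-specific box): 16 residues, Gln...Pro.
SNRK2_BOX_PATTERN = "QALSEQDVMSIVQEAP"
#: Domain II (ABA-specific box): 30 residues, Leu...Met, aspartate-rich.
ABA_BOX_PATTERN = "LDIDDSDMEDLDSDLDDIDMDSSGEIVQAM"


@dataclass
class CtermTyping:
    gene_id: str
    acidic_window: tuple[int, int]  # 1-based residue range analyzed
    n_asp: int
    n_glu: int
    patch_type: str  # poly-D | poly-E | indeterminate
    snrk2_box_present: bool
    aba_box_present: bool


@dataclass
class GroupAssignment:
    gene_id: str
    group: str  # I | II | III | unassigned
    method: str  # tree | cterm
    evidence: list[str] = field(default_factory=list)


def cterm_typing(
    gene_id: str,
    protein: str,
    window: int = 30,
    min_acidic: int = 6,
    snrk2_box: str = SNRK2_BOX_PATTERN,
    aba_box: str = ABA_BOX_PATTERN,
    box_max_mismatch: int = 2,
) -> CtermTyping:
    """Acidic-patch typing and box detection in the C-terminal third."""
    if len(protein) < 60:
        raise ValueError(f"{gene_id}: protein too short ({len(protein)} aa)")
    third_start = len(protein) - len(protein) // 3  # 0-based
    cterm = protein[third_start:]
    width = min(window, len(cterm))
    best_start, best_count = 0, -1
    for s in range(len(cterm) - width + 1):
        count = sum(1 for r in cterm[s : s + width] if r in "DE")
        if count > best_count:
            best_start, best_count = s, count
    window_seq = cterm[best_start : best_start + width]
    n_asp = window_seq.count("D")
    n_glu = window_seq.count("E")
    if n_asp + n_glu < min_acidic:
        patch = "indeterminate"
    elif n_asp > n_glu:
        patch = "poly-D"
    elif n_glu > n_asp:
        patch = "poly-E"
    else:
        patch = "indeterminate"
    boxes = {
        "snrk2_box": snrk2_box,
        "aba_box": aba_box,
    }
    hits = scan_signatures(cterm, boxes, box_max_mismatch)
    present = {h.signature_name for h in hits}
    abs_start = third_start + best_start + 1
    return CtermTyping(
        gene_id=gene_id,
        acidic_window=(abs_start, abs_start + width - 1),
        n_asp=n_asp,
        n_glu=n_glu,
        patch_type=patch,
        snrk2_box_present="snrk2_box" in present,
        aba_box_present="aba_box" in present,
    )


def _parent_map(root: TreeNode) -> dict[int, TreeNode]:
    parents: dict[int, TreeNode] = {}

    def walk(node: TreeNode) -> None:
        for c in node.children:
            parents[id(c)] = node
            walk(c)

    walk(root)
    return parents


def assign_groups_tree(
    tree: UltrametricTree,
    reference_labels: dict[str, str],
) -> dict[str, GroupAssignment]:
    """Each member takes the majority group of the reference leaves in
    its smallest reference-containing clade; ties leave it unassigned."""
    leaves = {l.name: l for l in tree.root.leaves()}
    refs_present = set(reference_labels) & set(leaves)
    if not refs_present:
        raise ValueError("tree contains no labeled reference leaves")
    parents = _parent_map(tree.root)
    out: dict[str, GroupAssignment] = {}
    for name, leaf in leaves.items():
        if name in reference_labels:
            continue
        node = leaf
        clade_refs: list[str] = []
        while True:
            clade_refs = [
                n for n in node.leaf_names() if n in reference_labels
            ]
            if clade_refs or id(node) not in parents:
                break
            node = parents[id(node)]
        votes = Counter(reference_labels[r] for r in clade_refs)
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            logger.warning("%s: tied reference vote %s; unassigned", name, dict(votes))
            out[name] = GroupAssignment(name, "unassigned", "tree", clade_refs)
        else:
            out[name] = GroupAssignment(name, ranked[0][0], "tree", clade_refs)
    return out


def reconcile(
    tree_groups: dict[str, GroupAssignment],
    cterm_typings: dict[str, CtermTyping],
) -> tuple[dict[str, GroupAssignment], list[str], pd.DataFrame]:
    """Final assignments (tree wins), conflict flags, and a consistency
    matrix of tree group x C-terminal patch type."""
    if set(tree_groups) != set(cterm_typings):
        raise ValueError("tree and C-terminal inputs cover different members")
    conflicts: list[str] = []
    cells: Counter = Counter()
    final: dict[str, GroupAssignment] = {}
    for gid, assignment in tree_groups.items():
        typing = cterm_typings[gid]
        cells[(assignment.group, typing.patch_type)] += 1
        final[gid] = assignment
        if assignment.group == "III" and not typing.aba_box_present:
            conflicts.append(f"{gid}: Group III but no ABA-specific box")
        if assignment.group == "I" and typing.patch_type != "poly-E":
            conflicts.append(f"{gid}: Group I but patch is {typing.patch_type}")
    groups = sorted({g for g, _ in cells} | {"I", "II", "III"})
    patches = sorted({p for _, p in cells} | {"poly-D", "poly-E", "indeterminate"})
    matrix = pd.DataFrame(0, index=groups, columns=patches)
    for (g, p), n in cells.items():
        matrix.loc[g, p] = n
    for c in conflicts:
        logger.warning("reconcile conflict: %s", c)
    return final, conflicts, matrix
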