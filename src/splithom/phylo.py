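"""Midpoint rooting and Faith's phylogenetic diversity.

Faith's PD of a species set is the sum of branch lengths of the minimal
subtree spanning those tips; with ``include_root`` (the default, matching
the convention of the classic picante implementation) the path from the
spanning subtree up to the root is included.  Used to quantify the
phylogenetic breadth of the species carrying homologs of each xenobiotic
enzyme class, and to order the classes.
"""

from __future__ import annotations

import pandas as pd
from skbio import TreeNode

_TIE_TOL = 1e-9


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root a tree at the midpoint of its longest tip-to-tip path.

    Total branch length is conserved.  Ties in the longest path are broken
    by the lexicographically smallest tip-name pair; a zero-length longest
    path is fatal.
    """
    tree = tree.copy()
    if tree.count(tips=True) < 2:
        raise ValueError("midpoint rooting requires >= 2 tips")
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    longest = dm.data.max()
    if longest <= 0:
        raise ValueError("longest tip-to-tip path has zero length; cannot midpoint-root")
    pairs = []
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if dm.data[i, j] >= longest - _TIE_TOL:
                pairs.append(tuple(sorted((a, ids[j]))))
    tip_a, tip_b = min(pairs)
    half = longest / 2.0

    node_a, node_b = tree.find(tip_a), tree.find(tip_b)
    lca = tree.lowest_common_ancestor([node_a, node_b])

    def _dist_up(node: TreeNode) -> float:
        d = 0.0
        while node is not lca:
            d += node.length or 0.0
            node = node.parent
        return d

    # the midpoint lies on the side whose tip is at least `half` from the LCA
    start = node_a if _dist_up(node_a) >= half - _TIE_TOL else node_b
    walked = 0.0
    node = start
    while node is not lca and walked + (node.length or 0.0) < half - _TIE_TOL:
        walked += node.length or 0.0
        node = node.parent
    delta = min(half - walked, node.length or 0.0)
    rooted = tree.root_at(node, above=delta) if delta > _TIE_TOL else tree.root_at(node)
    return rooted


def faith_pd(tree: TreeNode, tip_subset: set[str] | list[str], include_root: bool = True) -> float:
    """Sum of branch lengths of the minimal subtree connecting
    ``tip_subset``, optionally including the path up to the root."""
    names = sorted(set(tip_subset))
    if not names:
        raise ValueError("tip subset must be nonempty")
    tip_names = {t.name for t in tree.tips()}
    unknown = [n for n in names if n not in tip_names]
    if unknown:
        raise KeyError(f"tips not in tree: {', '.join(unknown)}")

    nodes = [tree.find(n) for n in names]
    marked: set[int] = set()
    marked_nodes = []
    for node in nodes:
        cur = node
        while cur is not None:
            if id(cur) in marked:
                break
            marked.add(id(cur))
            marked_nodes.append(cur)
            cur = cur.parent
    total = sum(n.length or 0.0 for n in marked_nodes if n.parent is not None)
    if include_root:
        return total
    # subtract the exclusive path from the subset's LCA up to the root
    lca = tree.lowest_common_ancestor(nodes) if len(nodes) > 1 else nodes[0]
    cur = lca
    while cur is not None and cur.parent is not None:
        total -= cur.length or 0.0
        cur = cur.parent
    return total


def rank_classes_by_pd(
    class_species: dict[str, set[str]],
    tree: TreeNode,
    include_root: bool = True,
) -> pd.DataFrame:
    """Order xenobiotic classes by Faith's PD of their species sets,
    descending; ties broken lexicographically; empty classes get PD 0 and
    rank last."""
    rows = []
    for cls in sorted(class_species):
        species = set(class_species[cls])
        pd_val = faith_pd(tree, species, include_root=include_root) if species else 0.0
        rows.append((cls, len(species), pd_val))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(
        [(cls, n, pd_val, rank) for rank, (cls, n, pd_val) in enumerate(rows, start=1)],
        columns=["class", "n_species", "pd", "rank"],
    )
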