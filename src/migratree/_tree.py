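"""Low-level helpers shared by the tree-handling modules.

Trees are held as :class:`dendropy.Tree` objects throughout the package.
Topology statistics, however, operate on plain-Python views extracted here:
leaf-label sets, canonical bipartition ("split") sets, and adjacency maps for
edge-count path lengths.  Keeping these views independent of dendropy's own
bipartition encoding makes cross-namespace comparisons trivial and the kernels
easy to verify against brute force.
"""

from __future__ import annotations

from collections import deque

import dendropy

__all__ = [
    "parse_newick",
    "to_newick",
    "leaf_labels",
    "prune_to_taxa",
    "nontrivial_splits",
    "restrict_splits",
    "leaf_path_lengths",
    "n_internal_edges",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick tree from a string (underscores preserved)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    if tree.seed_node is None or not list(tree.leaf_node_iter()):
        raise ValueError("Newick string contains no leaves")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to one-line Newick (no rooting token)."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def prune_to_taxa(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Restriction of *tree* to the given leaf labels (unifurcations removed)."""
    keep = set(labels)
    have = leaf_labels(tree)
    missing = keep - have
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    if keep == have:
        return tree.clone(depth=1)
    return tree.extract_tree_with_taxa_labels(labels=keep)


def _leafsets(tree: dendropy.Tree) -> dict:
    """Map each node to the frozenset of leaf labels below it."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset([node.taxon.label])
        else:
            acc = frozenset()
            for child in node.child_nodes():
                acc |= out[child]
            out[node] = acc
    return out


def nontrivial_splits(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Canonical non-trivial bipartitions of the unrooted topology.

    Each split is represented by the side that does *not* contain the
    lexicographically smallest leaf label, so splits from trees built over
    different taxon namespaces compare directly.  Polytomies simply
    contribute fewer splits (soft-polytomy reading).
    """
    all_leaves = leaf_labels(tree)
    n = len(all_leaves)
    if n < 4:
        return frozenset()
    ref = min(all_leaves)
    sets = _leafsets(tree)
    splits = set()
    for node, below in sets.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = all_leaves - below if ref in below else below
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return frozenset(splits)


def restrict_splits(
    splits, keep: frozenset[str]
) -> frozenset[frozenset[str]]:
    """Split set of the topology induced on the leaf subset *keep*.

    Restricting each bipartition to the retained taxa and dropping the ones
    that become trivial yields exactly the split set of the pruned tree, so
    subset searches (the disagree statistic) never need to rebuild trees.
    """
    n = len(keep)
    if n < 4:
        return frozenset()
    ref = min(keep)
    out = set()
    for side in splits:
        part = side & keep
        if ref in part:
            part = keep - part
        if 2 <= len(part) <= n - 2:
            out.add(part)
    return frozenset(out)


def _unrooted_adjacency(tree: dendropy.Tree):
    """Adjacency map of the unrooted topology (degree-2 nodes suppressed)."""
    adj: dict = {}

    def link(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            link(node, child)
    # suppress degree-2 vertices (a rooted tree's root, unifurcations)
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            nbrs = adj[node]
            if len(nbrs) == 2 and not node.is_leaf():
                a, b = tuple(nbrs)
                adj[a].discard(node)
                adj[b].discard(node)
                link(a, b)
                del adj[node]
                changed = True
    return adj


def leaf_path_lengths(tree: dendropy.Tree) -> dict:
    """Edge-count path length between every unordered leaf pair.

    Counts edges on the unrooted topology (the rooted tree's root vertex is
    suppressed first), ignoring branch lengths.  Keys are frozensets of the
    two leaf labels.
    """
    adj = _unrooted_adjacency(tree)
    leaves = [n for n in adj if n.is_leaf()]
    dists: dict = {}
    for src in leaves:
        seen = {src: 0}
        queue = deque([src])
        while queue:
            node = queue.popleft()
            for nbr in adj[node]:
                if nbr not in seen:
                    seen[nbr] = seen[node] + 1
                    queue.append(nbr)
        for other in leaves:
            if other is src:
                continue
            key = frozenset([src.taxon.label, other.taxon.label])
            dists[key] = seen[other]
    return dists


def n_internal_edges(tree: dendropy.Tree) -> int:
    """Number of internal (non-pendant) edges of the unrooted topology."""
    adj = _unrooted_adjacency(tree)
    count = 0
    seen = set()
    for node, nbrs in adj.items():
        for nbr in nbrs:
            key = frozenset([id(node), id(nbr)])
            if key in seen:
                continue
            seen.add(key)
            if not node.is_leaf() and not nbr.is_leaf():
                count += 1
    return count
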