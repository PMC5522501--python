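"""Target topologies for the gene-tree comparisons.

Each gene tree is contrasted with three hypothetical divergence scenarios:

* **speciation** — the species phylogeny itself (divergence tracks descent);
* **migration** — a phenotype-constrained topology in which each migratory
  category (resident / partial / obligate) forms its own top-level clade
  while the species-tree relationships are kept *within* each clade;
* **random** — trees obtained from the gene tree by repeated random
  subtree swaps, which randomize branching structure rather than merely
  relabelling taxa.

All targets are pruned to the taxa shared with the gene tree before use.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from . import _tree

__all__ = [
    "build_phenotype_topology",
    "random_branch_shuffle",
    "TargetSet",
    "make_target_set",
]


def build_phenotype_topology(
    species_tree: dendropy.Tree, phenotypes: dict
) -> dendropy.Tree:
    """Phenotype-constrained topology from a species tree.

    Returns a rooted tree with one top-level clade per phenotype category
    present (ordered 0, 1, 2 for reproducible output); inside each clade the
    topology is the species tree restricted to that category's taxa.  Branch
    lengths are set to 1 throughout — the comparison statistics are
    topology-only.
    """
    leaves = _tree.leaf_labels(species_tree)
    missing = leaves - set(phenotypes)
    if missing:
        raise ValueError(f"no phenotype for taxa: {sorted(missing)}")
    by_cat: dict[int, list[str]] = {}
    for taxon in sorted(leaves):
        by_cat.setdefault(phenotypes[taxon], []).append(taxon)
    cats = sorted(by_cat)
    if len(cats) < 2:
        raise ValueError(
            "all taxa share one phenotype: constrained tree equals the "
            "induced tree; nothing to contrast"
        )
    fragments = []
    for cat in cats:
        taxa = by_cat[cat]
        if len(taxa) == 1:
            fragments.append(taxa[0])
        else:
            sub = _tree.prune_to_taxa(species_tree, taxa)
            frag = sub.as_string(
                schema="newick",
                suppress_rooting=True,
                suppress_edge_lengths=True,
                suppress_internal_node_labels=True,
                unquoted_underscores=True,
            ).strip().rstrip(";")
            fragments.append(frag)
    tree = _tree.parse_newick("(" + ",".join(fragments) + ");")
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = 1.0
    return tree


def random_branch_shuffle(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Randomized topology over the same leaf set via subtree swaps.

    Performs K successive moves (K = number of internal edges of the
    unrooted topology): each move picks two node-disjoint non-root subtrees
    uniformly at random and exchanges their attachment points.  Leaf
    multiset and vertex degrees are preserved; a 3-leaf tree is returned
    unchanged (it has a single unrooted topology).
    """
    out = tree.clone(depth=1)
    n_leaves = len(_tree.leaf_labels(out))
    if n_leaves < 4:
        return out
    k_moves = max(1, _tree.n_internal_edges(out))
    rng = np.random.default_rng(seed)
    for _ in range(k_moves):
        # preorder enter/exit indices make the ancestor test O(1), so a
        # uniform valid pair can be drawn by rejection sampling
        nodes = [
            n for n in out.preorder_node_iter() if n is not out.seed_node
        ]
        enter, exit_ = {}, {}
        counter = 0

        def visit(node):
            nonlocal counter
            enter[node] = counter
            counter += 1
            for child in node.child_nodes():
                visit(child)
            exit_[node] = counter

        visit(out.seed_node)

        def valid(a, b):
            if a is b or a.parent_node is b.parent_node:
                return False
            disjoint = exit_[a] <= enter[b] or exit_[b] <= enter[a]
            return disjoint

        pair = None
        for _try in range(200):
            a = nodes[int(rng.integers(0, len(nodes)))]
            b = nodes[int(rng.integers(0, len(nodes)))]
            if valid(a, b):
                pair = (a, b)
                break
        if pair is None:  # tiny trees: enumerate instead
            pairs = [
                (a, b)
                for i, a in enumerate(nodes)
                for b in nodes[i + 1 :]
                if valid(a, b)
            ]
            if not pairs:
                break
            pair = pairs[int(rng.integers(0, len(pairs)))]
        a, b = pair
        pa, pb = a.parent_node, b.parent_node
        pa.remove_child(a)
        pb.remove_child(b)
        pa.add_child(b)
        pb.add_child(a)
    return out


@dataclass
class TargetSet:
    """The pruned target topologies for one gene tree."""

    speciation: dendropy.Tree
    migration: dendropy.Tree
    randoms: list
    shared_taxa: frozenset[str]
    gene_tree: dendropy.Tree  # pruned to the shared taxa


def make_target_set(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    phenotypes: dict,
    n_random: int = 100,
    seed: int = 0,
) -> TargetSet:
    """Build the speciation / migration / random targets for one gene.

    All trees are pruned to the taxa shared between the gene tree and the
    species tree; the random set is generated from the (pruned) gene tree by
    :func:`random_branch_shuffle`.
    """
    shared = _tree.leaf_labels(gene_tree) & _tree.leaf_labels(species_tree)
    if len(shared) < 4:
        raise ValueError(
            f"only {len(shared)} taxa shared between gene tree and species "
            "tree; need >= 4"
        )
    gene_p = _tree.prune_to_taxa(gene_tree, shared)
    spec_p = _tree.prune_to_taxa(species_tree, shared)
    phen = {t: phenotypes[t] for t in shared}
    migration = build_phenotype_topology(spec_p, phen)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_random)
    randoms = [
        random_branch_shuffle(gene_p, seed=int(s)) for s in sub_seeds
    ]
    return TargetSet(spec_p, migration, randoms, frozenset(shared), gene_p)
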