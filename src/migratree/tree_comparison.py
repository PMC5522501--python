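"""Topology-distance statistics and the randomization-null verdict.

Three statistics compare a gene tree with a target topology, all computed
after pruning both trees to their shared taxa and all ignoring branch
lengths:

* **nodal** — RMSD between the two trees' matrices of leaf-to-leaf
  topological path lengths (edge counts on the unrooted topology);
* **splits** — 1 − 2·|shared non-trivial splits| / (|splits₁| + |splits₂|),
  a normalized Robinson–Foulds distance in [0, 1];
* **disagree** — the minimum number of taxa whose removal renders the two
  topologies identical, reported as count/total (exact subset search up to
  12 taxa, greedy taxon pruning above).

Significance is judged against the distribution of the same statistic over a
set of randomized trees: the verdict is *similar* below mean − SD,
*different* above mean + SD, *within_noise* inside that one-SD band.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from ._tree import (
    leaf_labels,
    leaf_path_lengths,
    nontrivial_splits,
    prune_to_taxa,
    restrict_splits,
)

__all__ = [
    "nodal_rmsd",
    "splits_distance",
    "disagree",
    "classify_against_null",
    "TopologyComparison",
    "GeneComparison",
    "compare_gene_tree",
]

EXACT_DISAGREE_MAX_TAXA = 12


def _shared_taxa(t1, t2, minimum: int):
    shared = leaf_labels(t1) & leaf_labels(t2)
    if len(shared) < minimum:
        raise ValueError(
            f"only {len(shared)} shared taxa; need >= {minimum}"
        )
    return frozenset(shared)


def nodal_rmsd(t1, t2) -> float:
    """Root-mean-square difference of leaf-pair topological path lengths."""
    shared = _shared_taxa(t1, t2, 3)
    d1 = leaf_path_lengths(prune_to_taxa(t1, shared))
    d2 = leaf_path_lengths(prune_to_taxa(t2, shared))
    sq = [
        (d1[frozenset(p)] - d2[frozenset(p)]) ** 2
        for p in itertools.combinations(sorted(shared), 2)
    ]
    return math.sqrt(sum(sq) / len(sq))


def _topologically_identical(s1, s2) -> bool:
    """Identity for the disagree search: one topology refines the other.

    Equal split sets are identical; a polytomy is compatible with (treated
    as identical to) any resolution of it, i.e. subset in either direction.
    """
    return s1 <= s2 or s2 <= s1


def _splits_dist(s1, s2) -> float:
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * len(s1 & s2) / denom


def splits_distance(t1, t2) -> float:
    """Normalized shared-splits distance in [0, 1] on the common taxa."""
    shared = _shared_taxa(t1, t2, 4)
    s1 = restrict_splits(nontrivial_splits(t1), shared)
    s2 = restrict_splits(nontrivial_splits(t2), shared)
    return _splits_dist(s1, s2)


def disagree(t1, t2) -> tuple[int, int]:
    """Minimum taxa to remove for topological identity, as (count, total).

    Exact over removal subsets of increasing size when the shared set has at
    most :data:`EXACT_DISAGREE_MAX_TAXA` taxa; above that, a greedy heuristic
    iteratively removes the taxon whose removal most reduces the splits
    distance (ties by label order).  The greedy count is an upper bound on
    the exact minimum.  Identity means equal non-trivial split sets, so a
    polytomy is compatible with any resolution of it.
    """
    shared = _shared_taxa(t1, t2, 3)
    total = len(shared)
    s1 = restrict_splits(nontrivial_splits(t1), shared)
    s2 = restrict_splits(nontrivial_splits(t2), shared)
    if _topologically_identical(s1, s2):
        return 0, total
    if total <= EXACT_DISAGREE_MAX_TAXA:
        ordered = sorted(shared)
        for size in range(1, total - 2):
            for combo in itertools.combinations(ordered, size):
                keep = shared - set(combo)
                if _topologically_identical(
                    restrict_splits(s1, keep), restrict_splits(s2, keep)
                ):
                    return size, total
        return total - 3, total  # 3 remaining taxa are always identical
    # greedy taxon pruning
    current = set(shared)
    count = 0
    c1, c2 = s1, s2
    while not _topologically_identical(c1, c2):
        best = None
        for taxon in sorted(current):
            keep = frozenset(current - {taxon})
            r1 = restrict_splits(c1, keep)
            r2 = restrict_splits(c2, keep)
            dist = _splits_dist(r1, r2)
            if best is None or dist < best[0] - 1e-12:
                best = (dist, taxon, r1, r2)
        _, taxon, c1, c2 = best
        current.remove(taxon)
        count += 1
    return count, total


def classify_against_null(statistic: float, null_values) -> str:
    """Verdict of a statistic against its randomization null.

    The one-SD confidence band is [mean − SD, mean + SD] of the null values;
    below it → ``similar``, above it → ``different``, inside → ``within_noise``.
    """
    null_values = np.asarray(list(null_values), dtype=float)
    if null_values.size < 2:
        raise ValueError("need >= 2 null values for a verdict")
    mean = float(null_values.mean())
    sd = float(null_values.std(ddof=1))
    if statistic < mean - sd:
        return "similar"
    if statistic > mean + sd:
        return "different"
    return "within_noise"


@dataclass
class TopologyComparison:
    """One (target, method) comparison with its null and verdict."""

    method: str
    target: str
    statistic: float
    null_mean: float
    null_sd: float
    verdict: str
    disagree_count: int | None = None
    disagree_total: int | None = None


@dataclass
class GeneComparison:
    gene: str
    rows: list
    best_fit: dict  # method -> "speciation" | "migration" | "indistinguishable"


_METHODS = ("nodal", "splits", "disagree")


def _statistic(method: str, t1, t2):
    if method == "nodal":
        return nodal_rmsd(t1, t2), None
    if method == "splits":
        return splits_distance(t1, t2), None
    if method == "disagree":
        count, total = disagree(t1, t2)
        return count / total, (count, total)
    raise ValueError(f"unknown method {method!r}")


def compare_gene_tree(
    gene_tree,
    targets,
    methods=_METHODS,
    gene: str = "",
) -> GeneComparison:
    """Compare one gene tree with its speciation/migration/random targets.

    For each method, the statistic is computed against the speciation and
    migration targets (and against the first random tree, as the random
    target itself); the null distribution is the statistic over the whole
    random set.  The best-fit target per method is the one with the smaller
    statistic; exact ties are reported as ``indistinguishable``.
    """
    gene_p = getattr(targets, "gene_tree", gene_tree)
    rows: list[TopologyComparison] = []
    best: dict[str, str] = {}
    for method in methods:
        null_vals = [
            _statistic(method, gene_p, r)[0] for r in targets.randoms
        ]
        named = [
            ("speciation", targets.speciation),
            ("migration", targets.migration),
            ("random", targets.randoms[0]),
        ]
        stats = {}
        for name, target in named:
            stat, extra = _statistic(method, gene_p, target)
            verdict = classify_against_null(stat, null_vals)
            rows.append(
                TopologyComparison(
                    method=method,
                    target=name,
                    statistic=stat,
                    null_mean=float(np.mean(null_vals)),
                    null_sd=float(np.std(null_vals, ddof=1)),
                    verdict=verdict,
                    disagree_count=extra[0] if extra else None,
                    disagree_total=extra[1] if extra else None,
                )
            )
            stats[name] = stat
        if math.isclose(stats["speciation"], stats["migration"]):
            best[method] = "indistinguishable"
        elif stats["speciation"] < stats["migration"]:
            best[method] = "speciation"
        else:
            best[method] = "migration"
    return GeneComparison(gene=gene, rows=rows, best_fit=best)
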