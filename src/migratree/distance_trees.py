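"""Kimura two-parameter distances, neighbour joining, and bootstrap supports.

Gene trees are built the classic distance way: pairwise K2P distances
(transitions and transversions weighted separately) feed a neighbour-joining
agglomeration, and branch reliability is assessed by resampling alignment
columns with replacement and recording, for each internal edge of the
full-data tree, the fraction of replicate trees containing the same split.

Gap and ambiguous (N) positions are removed pairwise: each pair of sequences
is compared over the columns where both carry an unambiguous base.  A pair
whose divergence exceeds the K2P log-domain boundary has no defined distance;
such saturation aborts tree building rather than being silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tree
from .metadata_io import GeneAlignment

__all__ = [
    "SaturationError",
    "K2PEstimate",
    "DistanceMatrix",
    "k2p_distance",
    "k2p_matrix",
    "neighbor_joining",
    "bootstrap_supports",
    "concatenate_alignments",
]


class SaturationError(ValueError):
    """Raised when a pairwise distance is undefined under K2P."""


@dataclass(frozen=True)
class K2PEstimate:
    """K2P distance components for one sequence pair.

    P and Q are the proportions of comparable sites differing by a
    transition and a transversion respectively; d is the corrected distance
    in substitutions per site.
    """

    P: float
    Q: float
    d: float
    comparable_sites: int


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < 0):
            raise ValueError("distance matrix has negative entries")


_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i  # A=0 C=1 G=2 T=3; purines even, pyrimidines odd


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[arr]


def _pq_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    both = (a >= 0) & (b >= 0)
    m = int(both.sum())
    diff = both & (a != b)
    # transitions stay within purines {A,G} or pyrimidines {C,T}
    ts = diff & ((a % 2) == (b % 2))
    return int(ts.sum()), int(diff.sum() - ts.sum()), m


def _k2p_from_pq(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined (P={P:.4f}, Q={Q:.4f}): "
            "sequences too divergent"
        )
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_distance(seq_a: str, seq_b: str) -> K2PEstimate:
    """K2P distance between two aligned sequences (pairwise deletion).

    ``d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`` over the columns where both
    sequences carry an unambiguous base.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    a, b = _encode(seq_a.upper()), _encode(seq_b.upper())
    n_ts, n_tv, m = _pq_counts(a, b)
    if m == 0:
        raise ValueError("no comparable sites between the two sequences")
    P, Q = n_ts / m, n_tv / m
    return K2PEstimate(P, Q, _k2p_from_pq(P, Q), m)


def k2p_matrix(aln: GeneAlignment) -> DistanceMatrix:
    """All-pairs K2P distance matrix for an alignment."""
    labels = aln.species
    if len(labels) < 3:
        raise ValueError("need >= 3 sequences for a distance matrix")
    enc = np.stack([_encode(aln.rows[s]) for s in labels])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            n_ts, n_tv, m = _pq_counts(enc[i], enc[j])
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} "
                    f"and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = _k2p_from_pq(n_ts / m, n_tv / m)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# neighbour joining

def neighbor_joining(dm: DistanceMatrix):
    """Neighbour-joining tree from a distance matrix.

    Deterministic: ties in the Q criterion are broken by the smallest
    (row, column) index pair in the current label order.  Negative estimated
    branch lengths are clamped to zero.  Returns an unrooted tree (the seed
    vertex is the final trifurcation).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    d = dm.values.copy()
    frags = list(dm.labels)

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.10g}"

    while len(frags) > 3:
        m = len(frags)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qv = q[iu]
        # smallest Q; ties by lowest (i, j) with i < j in current order
        near = np.flatnonzero(qv <= qv.min() + 1e-12)
        pick = near[0]  # triu ordering is already lexicographic in (i, j)
        i, j = int(iu[0][pick]), int(iu[1][pick])
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        new_frag = f"({frags[i]}:{fmt(li)},{frags[j]}:{fmt(lj)})"
        dn = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        dn = np.maximum(dn, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[1:, 1:] = d[np.ix_(keep, keep)]
        d_new[0, 1:] = d_new[1:, 0] = dn[keep]
        d = d_new
        frags = [new_frag] + [frags[k] for k in keep]
    # final trifurcation from the three-point formulas
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    newick = (
        f"({frags[0]}:{fmt(l0)},{frags[1]}:{fmt(l1)},{frags[2]}:{fmt(l2)});"
    )
    tree = _tree.parse_newick(newick)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_supports(aln: GeneAlignment, n_reps: int = 1000, seed: int = 0):
    """NJ tree with split supports from column-resampling bootstrap.

    Each replicate resamples alignment columns with replacement, rebuilds the
    K2P/NJ tree, and scores which internal edges of the full-data tree recur.
    Replicates where any pairwise distance is saturated or has no comparable
    sites are dropped (and counted); more than 50% dropped is an error.
    Supports are fractions in [0, 1] stored as internal node labels.
    """
    full = neighbor_joining(k2p_matrix(aln))
    full_splits = _tree.nontrivial_splits(full)
    labels = aln.species
    enc = np.stack([_encode(aln.rows[s]) for s in labels])
    length = enc.shape[1]
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in full_splits}
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        sub = enc[:, cols]
        try:
            dmat = k2p_matrix_from_encoded(labels, sub)
            rep_tree = neighbor_joining(dmat)
        except (SaturationError, ValueError):
            dropped += 1
            continue
        rep_splits = _tree.nontrivial_splits(rep_tree)
        for s in full_splits & rep_splits:
            counts[s] += 1
    if dropped > n_reps / 2:
        raise SaturationError(
            f"{dropped}/{n_reps} bootstrap replicates had undefined "
            "distances; inspect the alignment for saturation"
        )
    kept = n_reps - dropped
    # annotate internal nodes of the full tree with their split's support
    all_leaves = _tree.leaf_labels(full)
    ref = min(all_leaves)
    for node in full.preorder_node_iter():
        if node.is_leaf() or node is full.seed_node:
            continue
        below = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        side = all_leaves - below if ref in below else below
        if side in counts and kept > 0:
            node.label = f"{counts[side] / kept:.3f}"
    return full


def k2p_matrix_from_encoded(labels, enc: np.ndarray) -> DistanceMatrix:
    """K2P matrix from a pre-encoded (taxa x columns) int8 array."""
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            n_ts, n_tv, m = _pq_counts(enc[i], enc[j])
            if m == 0:
                raise ValueError("no comparable sites in replicate")
            d[i, j] = d[j, i] = _k2p_from_pq(n_ts / m, n_tv / m)
    return DistanceMatrix(list(labels), d)


# ---------------------------------------------------------------------------
# concatenation

def concatenate_alignments(alns) -> GeneAlignment:
    """Concatenate gene alignments into one supermatrix.

    Gene blocks are appended in lexicographic gene-name order; the row set is
    the union of species, with all-gap padding where a species lacks a gene.
    """
    alns = list(alns)
    if not alns:
        raise ValueError("no alignments to concatenate")
    ordered = sorted(alns, key=lambda a: a.gene)
    species = sorted({s for a in ordered for s in a.rows})
    rows = {s: [] for s in species}
    for aln in ordered:
        pad = "-" * aln.n_columns
        for s in species:
            rows[s].append(aln.rows.get(s, pad))
    name = "+".join(a.gene for a in ordered)
    return GeneAlignment(name, {s: "".join(parts) for s, parts in rows.items()})
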