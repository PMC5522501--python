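"""Codon-model selection tests: site-model and branch-model dN/dS LRTs.

The substitution process is a 61-state codon model: instantaneous changes are
restricted to single-nucleotide replacements, with rate multipliers kappa for
transitions and omega (dN/dS) for nonsynonymous changes, weighted by the
target codon's equilibrium frequency (F3x4, estimated from the alignment).
Log-likelihoods are computed by Felsenstein pruning over the 61-state
alphabet with per-class eigendecomposition of the rate matrix; site classes
are mixed at the likelihood level.

Two tests are provided:

* **site models** — the neutral null M1 (a purifying class with omega in
  [0, 1] plus a neutral omega = 1 class) against M2, which adds a class with
  omega >= 1; LRT with 2 degrees of freedom, positive selection at p < 0.05.
* **branch scan** — for every branch, a two-ratio model (free foreground
  omega on that branch, one background omega elsewhere) against a single-
  ratio null; LRT with 1 df, Holm–Bonferroni corrected across branches,
  selection called at corrected p <= 0.05.

Branch-length *shape* is taken from the supplied (NJ) tree; a single free
scale multiplier is optimized under every model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from scipy.special import expit, logsumexp

from .metadata_io import GeneAlignment

__all__ = [
    "CODONS",
    "CodonModelParams",
    "SiteModelFit",
    "BranchTestResult",
    "NGEstimate",
    "f3x4_frequencies",
    "rate_matrix",
    "CodonLikelihood",
    "codon_log_likelihood",
    "fit_site_models",
    "branch_selection_scan",
    "holm_bonferroni",
    "ng86_dnds",
]

# ---------------------------------------------------------------------------
# genetic code (universal) and precomputed change masks

_BASES = "ACGT"
_CODON_TABLE = {}
_STOPS = {"TAA", "TAG", "TGA"}
_AA = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

CODONS: list[str] = sorted(_AA)
N_STATES = len(CODONS)  # 61
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _build_masks():
    single = np.zeros((N_STATES, N_STATES), dtype=bool)
    is_ts = np.zeros((N_STATES, N_STATES), dtype=bool)
    is_nonsyn = np.zeros((N_STATES, N_STATES), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            is_ts[i, j] = (ci[k], cj[k]) in _TRANSITIONS
            is_nonsyn[i, j] = _AA[ci] != _AA[cj]
    return single, is_ts, is_nonsyn


_SINGLE, _IS_TS, _IS_NONSYN = _build_masks()


# ---------------------------------------------------------------------------
# parameters

@dataclass
class CodonModelParams:
    """Parameters of the codon substitution process.

    ``omega_classes`` is a list of (omega, proportion) pairs; proportions
    must sum to 1.  ``tree_scale`` multiplies all branch lengths of the
    input tree.
    """

    kappa: float = 2.0
    codon_frequencies: np.ndarray | None = None  # 61 sense-codon freqs
    omega_classes: list = field(default_factory=lambda: [(0.5, 1.0)])
    tree_scale: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.tree_scale <= 0:
            raise ValueError("tree_scale must be > 0")
        props = [p for _, p in self.omega_classes]
        if abs(sum(props) - 1.0) > 1e-8:
            raise ValueError("omega class proportions must sum to 1")
        if any(w < 0 for w, _ in self.omega_classes):
            raise ValueError("omega must be >= 0")
        if self.codon_frequencies is not None:
            self.codon_frequencies = np.asarray(
                self.codon_frequencies, dtype=float
            )


def f3x4_frequencies(aln: GeneAlignment) -> np.ndarray:
    """F3x4 empirical codon frequencies from an in-frame alignment.

    Nucleotide frequencies are tallied per codon position over unambiguous
    bases; codon frequencies are their products renormalized over the 61
    sense codons, floored at 1e-6 to keep the likelihood defined when a
    base is unobserved at some position.
    """
    counts = np.ones((3, 4)) * 0.5  # small pseudocount
    for seq in aln.rows.values():
        for pos in range(len(seq)):
            base = seq[pos]
            k = _BASES.find(base)
            if k >= 0:
                counts[pos % 3, k] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, _BASES.index(c[0])]
            * freqs[1, _BASES.index(c[1])]
            * freqs[2, _BASES.index(c[2])]
            for c in CODONS
        ]
    )
    pi = np.maximum(pi, 1e-6)
    return pi / pi.sum()


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalized codon rate matrix Q for one omega class."""
    s = np.where(_IS_TS, kappa, 1.0)
    s = s * np.where(_IS_NONSYN, omega, 1.0)
    q = np.where(_SINGLE, s, 0.0) * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


class _EigQ:
    """Eigendecomposition of a reversible Q for fast transition matrices."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        sym = (d[:, None] * q) / d[None, :]
        w, u = np.linalg.eigh(sym)
        self.w = w
        self.left = u / d[:, None]
        self.right = u.T * d[None, :]

    def transition(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.w * t)) @ self.right
        return np.clip(p, 0.0, None)

    def transitions(self, ts: np.ndarray) -> np.ndarray:
        """Batched transition matrices for an array of durations."""
        expwt = np.exp(self.w[None, :] * ts[:, None])  # (E, 61)
        p = (self.left[None, :, :] * expwt[:, None, :]) @ self.right
        return np.clip(p, 0.0, None)


# ---------------------------------------------------------------------------
# likelihood engine

class CodonLikelihood:
    """Pruning-based log-likelihood for one codon alignment on one tree.

    Site patterns are compressed once at construction; leaves with a gap or
    ambiguity inside a codon contribute a marginalized (all-ones) partial
    for that site.  The tree supplies the branch-length shape; every
    likelihood call takes a free global scale.
    """

    def __init__(self, aln: GeneAlignment, tree, pi: np.ndarray | None = None):
        if aln.n_columns % 3 != 0:
            raise ValueError(
                f"alignment length {aln.n_columns} is not a multiple of 3"
            )
        self.n_codons = aln.n_columns // 3
        self.pi = f3x4_frequencies(aln) if pi is None else np.asarray(pi)
        tree_leaves = {
            leaf.taxon.label for leaf in tree.leaf_node_iter()
        }
        missing = tree_leaves - set(aln.rows)
        if missing:
            raise ValueError(f"tree leaves absent from alignment: {missing}")
        self.taxa = sorted(tree_leaves)
        # encode codon states; -1 = missing (gap/N anywhere in the codon)
        states = np.empty((len(self.taxa), self.n_codons), dtype=np.int64)
        for r, sid in enumerate(self.taxa):
            seq = aln.rows[sid]
            for c in range(self.n_codons):
                codon = seq[3 * c : 3 * c + 3]
                if codon in _STOPS:
                    raise ValueError(
                        f"in-frame stop codon {codon} in row {sid!r} at "
                        f"codon position {c}"
                    )
                states[r, c] = _CODON_INDEX.get(codon, -1)
        patterns, self.weights = np.unique(states, axis=1, return_counts=True)
        self.n_patterns = patterns.shape[1]
        self._leaf_partial = {}
        for r, sid in enumerate(self.taxa):
            part = np.zeros((N_STATES, self.n_patterns))
            for p in range(self.n_patterns):
                s = patterns[r, p]
                if s < 0:
                    part[:, p] = 1.0
                else:
                    part[s, p] = 1.0
            self._leaf_partial[sid] = part
        # flatten tree into postorder edge structure
        self._tree = tree.clone(depth=1)
        self._postorder = list(self._tree.postorder_node_iter())
        self.edges = []  # (node, parent, base_length) for non-seed nodes
        for node in self._postorder:
            if node.parent_node is not None:
                length = node.edge.length
                self.edges.append(
                    (node, node.parent_node, float(length or 0.0))
                )
        self._branch_of = self._branch_assignment()

    # -- single-class pruning with per-edge transition matrices ------------
    def _class_site_loglik(self, pmats: dict) -> np.ndarray:
        partial = {}
        logscale = np.zeros(self.n_patterns)
        for node in self._postorder:
            if node.is_leaf():
                partial[node] = self._leaf_partial[node.taxon.label]
                continue
            acc = np.ones((N_STATES, self.n_patterns))
            for child in node.child_nodes():
                acc = acc * (pmats[child] @ partial[child])
            m = acc.max(axis=0)
            safe = np.where(m > 0, m, 1.0)
            logscale += np.log(safe)
            partial[node] = acc / safe
        root = self._postorder[-1]
        site = self.pi @ partial[root]
        with np.errstate(divide="ignore"):
            return np.log(site) + logscale

    def _pmats(self, eig: _EigQ, scale: float) -> dict:
        ts = np.array([length for _, _, length in self.edges]) * scale
        batch = eig.transitions(ts)
        return {
            node: batch[k] for k, (node, _, _) in enumerate(self.edges)
        }

    def site_mixture_loglik(
        self, kappa: float, omega_classes, scale: float
    ) -> float:
        """Log-likelihood with sites mixed over omega classes.

        The rate matrices of all classes share one normalization so that
        the expected substitution rate of the mixture is 1 per unit branch
        length.
        """
        qs = [rate_matrix(kappa, w, self.pi) for w, _ in omega_classes]
        props = np.array([p for _, p in omega_classes])
        mus = np.array([-(self.pi * np.diag(q)).sum() for q in qs])
        norm = float(props @ mus)
        if norm <= 0:
            return -np.inf
        per_class = np.empty((len(qs), self.n_patterns))
        for k, q in enumerate(qs):
            eig = _EigQ(q / norm, self.pi)
            per_class[k] = self._class_site_loglik(self._pmats(eig, scale))
        with np.errstate(divide="ignore"):
            site = logsumexp(per_class, axis=0, b=props[:, None])
        return float(site @ self.weights)

    def branch_loglik(
        self, kappa: float, omega_by_branch: dict, scale: float,
        background_omega: float,
    ) -> float:
        """Log-likelihood with a single site class but per-branch omega.

        ``omega_by_branch`` maps branch keys (see :meth:`branch_keys`) to
        foreground omegas; every other branch uses ``background_omega``.
        The background rate matrix sets the normalization so foreground
        and null models share a branch-length scale.
        """
        q_bg = rate_matrix(kappa, background_omega, self.pi)
        norm = -(self.pi * np.diag(q_bg)).sum()
        eigs = {None: _EigQ(q_bg / norm, self.pi)}
        for key, w in omega_by_branch.items():
            if w not in eigs:
                eigs[w] = _EigQ(rate_matrix(kappa, w, self.pi) / norm, self.pi)
        pmats = {}
        for node, _, length in self.edges:
            key = self._branch_of[node]
            w = omega_by_branch.get(key)
            eig = eigs[w] if w is not None else eigs[None]
            pmats[node] = eig.transition(length * scale)
        site = self._class_site_loglik(pmats)
        return float(site @ self.weights)

    # -- branch bookkeeping ------------------------------------------------
    def _branch_assignment(self) -> dict:
        """Map each edge's head node to an unrooted-branch key.

        The two child edges of a bifurcating root form a single unrooted
        branch and share one key.
        """
        assign = {}
        root = self._tree.seed_node
        root_children = root.child_nodes()
        merge_root = len(root_children) == 2
        for node, _, _ in self.edges:
            if merge_root and node.parent_node is root:
                assign[node] = self._branch_key(root_children[0])
            else:
                assign[node] = self._branch_key(node)
        return assign

    def _branch_key(self, node) -> str:
        return unrooted_branch_key(node, self.taxa)

    def branch_keys(self) -> list[str]:
        """Distinct unrooted-branch identifiers, in a stable order."""
        seen = []
        for node, _, _ in self.edges:
            key = self._branch_of[node]
            if key not in seen:
                seen.append(key)
        return seen


def unrooted_branch_key(node, all_taxa) -> str:
    """Stable identifier of the unrooted branch above *node*.

    Names the smaller side of the branch's split, labels joined by ``|``
    (ties go to the side below the node).
    """
    below = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    if len(below) > len(all_taxa) / 2:
        below = sorted(set(all_taxa) - set(below))
    return "|".join(below)


def codon_log_likelihood(
    aln: GeneAlignment, tree, params: CodonModelParams
) -> float:
    """Log-likelihood of an in-frame codon alignment under given parameters."""
    lik = CodonLikelihood(aln, tree, pi=params.codon_frequencies)
    return lik.site_mixture_loglik(
        params.kappa, params.omega_classes, params.tree_scale
    )


# ---------------------------------------------------------------------------
# model fits

@dataclass
class SiteModelFit:
    lnL_M1: float
    lnL_M2: float
    LRT: float
    p: float
    params_M1: dict
    params_M2: dict


@dataclass
class BranchTestResult:
    branch_id: str
    lnL_null: float
    lnL_alt: float
    LRT: float
    p_raw: float
    p_corrected: float
    selected: bool
    omega_foreground: float
    omega_background: float


def _maximize(fun, starts, bounds):
    """Bounded quasi-Newton maximization over several starts."""
    best = None
    for x0 in starts:
        res = optimize.minimize(
            lambda x: -fun(x),
            x0=np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-9},
        )
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res.x)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("codon-model optimizer failed to converge")
    return best


_B = (-12.0, 12.0)  # generic bound for transformed parameters


def _m1_unpack(x):
    kappa, scale = np.exp(x[0]), np.exp(x[1])
    p0, w0 = expit(x[2]), expit(x[3])
    return kappa, scale, [(w0, p0), (1.0, 1.0 - p0)]


def _m2_unpack(x):
    kappa, scale = np.exp(x[0]), np.exp(x[1])
    p0, q = expit(x[2]), expit(x[3])
    w0 = expit(x[4])
    w2 = 1.0 + np.exp(x[5])
    p1 = (1.0 - p0) * q
    p2 = (1.0 - p0) * (1.0 - q)
    return kappa, scale, [(w0, p0), (1.0, p1), (w2, p2)]


def _logit(p):
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


def _fit_m1(lik: CodonLikelihood, rng, n_starts: int):
    """Maximize the M1-style likelihood; returns (lnL, packed params)."""

    def f_m1(x):
        kappa, scale, classes = _m1_unpack(x)
        return lik.site_mixture_loglik(kappa, classes, scale)

    base1 = [np.log(2.0), 0.0, 0.0, _logit(0.5)]
    starts1 = [base1] + [
        list(np.asarray(base1) + rng.normal(0, 1.0, size=4))
        for _ in range(n_starts - 1)
    ]
    return _maximize(f_m1, starts1, [_B] * 4)


def fit_site_models(
    aln: GeneAlignment, tree, n_starts: int = 3, seed: int = 0
) -> SiteModelFit:
    """Fit M1-style and M2-style site models and their LRT.

    M1 has classes (omega0 in [0,1], p0) and (omega=1, 1−p0); M2 adds
    (omega2 >= 1, p2).  kappa, proportions, omegas and the tree scale are
    optimized by bounded quasi-Newton from one heuristic start plus seeded
    random restarts (and, for M2, a start embedding the M1 optimum).  The
    LRT is floored at 0 (nested models) and referred to chi-square with
    2 degrees of freedom.
    """
    lik = CodonLikelihood(aln, tree)
    rng = np.random.default_rng(seed)

    def f_m2(x):
        kappa, scale, classes = _m2_unpack(x)
        return lik.site_mixture_loglik(kappa, classes, scale)

    lnL1, x1 = _fit_m1(lik, rng, n_starts)
    kappa1, scale1, classes1 = _m1_unpack(x1)

    # embed the M1 optimum: p2 -> 0, omega2 -> 1 (at the transform bounds)
    embed = [x1[0], x1[1], x1[2], _B[1], x1[3], _B[0]]
    base2 = [np.log(2.0), 0.0, 0.0, _logit(0.8), _logit(0.5), np.log(1.0)]
    starts2 = [embed, base2] + [
        list(np.asarray(base2) + rng.normal(0, 1.0, size=6))
        for _ in range(n_starts - 2)
    ]
    lnL2, x2 = _maximize(f_m2, starts2, [_B] * 6)
    kappa2, scale2, classes2 = _m2_unpack(x2)

    lrt = max(2.0 * (lnL2 - lnL1), 0.0)
    p = float(stats.chi2.sf(lrt, df=2))
    return SiteModelFit(
        lnL_M1=lnL1,
        lnL_M2=lnL2,
        LRT=lrt,
        p=p,
        params_M1={
            "kappa": kappa1, "tree_scale": scale1,
            "omega_classes": classes1,
        },
        params_M2={
            "kappa": kappa2, "tree_scale": scale2,
            "omega_classes": classes2,
        },
    )


def _m0_unpack(x):
    return np.exp(x[0]), np.exp(x[1]), np.exp(x[2])  # kappa, scale, omega


def branch_selection_scan(
    aln: GeneAlignment, tree, alpha: float = 0.05, seed: int = 0
) -> list[BranchTestResult]:
    """Two-ratio branch LRT for every branch, Holm–Bonferroni corrected.

    Null: one omega for the whole tree.  Alternative (per branch): a free
    foreground omega on that branch, background omega elsewhere; both share
    kappa and the tree scale (re-optimized).  Branch ids name the smaller
    side of the corresponding split.
    """
    lik = CodonLikelihood(aln, tree)

    def f_m0(x):
        kappa, scale, w = _m0_unpack(x)
        return lik.site_mixture_loglik(kappa, [(w, 1.0)], scale)

    rng = np.random.default_rng(seed)
    base0 = [np.log(2.0), 0.0, np.log(0.3)]
    starts0 = [base0] + [
        list(np.asarray(base0) + rng.normal(0, 0.5, size=3)) for _ in range(2)
    ]
    lnL0, x0 = _maximize(f_m0, starts0, [_B] * 3)
    kappa0, scale0, w0 = _m0_unpack(x0)

    results = []
    raw_ps = []
    for key in lik.branch_keys():

        def f_alt(x, key=key):
            kappa, scale, w_bg = _m0_unpack(x[:3])
            w_fg = np.exp(x[3])
            return lik.branch_loglik(
                kappa, {key: w_fg}, scale, background_omega=w_bg
            )

        warm = [x0[0], x0[1], x0[2], x0[2]]
        high = [x0[0], x0[1], x0[2], np.log(2.0)]
        lnL_alt, x_alt = _maximize(f_alt, [warm, high], [_B] * 4)
        lrt = max(2.0 * (lnL_alt - lnL0), 0.0)
        p_raw = float(stats.chi2.sf(lrt, df=1))
        raw_ps.append(p_raw)
        results.append(
            BranchTestResult(
                branch_id=key,
                lnL_null=lnL0,
                lnL_alt=lnL_alt,
                LRT=lrt,
                p_raw=p_raw,
                p_corrected=np.nan,
                selected=False,
                omega_foreground=float(np.exp(x_alt[3])),
                omega_background=float(np.exp(x_alt[2])),
            )
        )
    reject, corrected = holm_bonferroni(raw_ps, alpha=alpha)
    for res, rej, pc in zip(results, reject, corrected):
        res.p_corrected = float(pc)
        res.selected = bool(rej)
    return results


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Holm step-down correction: (reject flags, corrected p-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    corrected = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        corrected[idx] = min(running, 1.0)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject, corrected


# ---------------------------------------------------------------------------
# NG86 counting cross-check

@dataclass
class NGEstimate:
    dN: float | None
    dS: float | None
    ratio: float | None
    Sd: float
    Nd: float
    S_sites: float
    N_sites: float
    undefined: str | None = None  # reason when ratio is not computable


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous potential sites of one codon (NG86).

    Changes creating stop codons count as nonsynonymous, so every codon
    contributes exactly 3 sites.
    """
    s = n = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutated = codon[:pos] + base + codon[pos + 1 :]
            if mutated not in _STOPS and _AA[mutated] == _AA[codon]:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over mutation pathways."""
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    paths = []
    for perm in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all pathways blocked by stops; count direct change
        return 0.0, float(len(diffs))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(cds_a: str, cds_b: str) -> NGEstimate:
    """Nei–Gojobori (1986) dN/dS with Jukes–Cantor correction.

    Codons containing a gap or ambiguity in either sequence are skipped
    (pairwise deletion); in-frame stop codons are an error.  Changes that
    would create a stop codon count as nonsynonymous potential sites, while
    mutation pathways passing through a stop are excluded when averaging
    observed differences.  The ratio is flagged undefined when dS = 0 or a
    rate saturates the JC correction.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must have equal length")
    if len(cds_a) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    s_sites_a = s_sites_b = n_sites_a = n_sites_b = 0.0
    sd = nd = 0.0
    for k in range(0, len(cds_a), 3):
        c1, c2 = cds_a[k : k + 3].upper(), cds_b[k : k + 3].upper()
        if c1 in _STOPS or c2 in _STOPS:
            raise ValueError(f"in-frame stop codon at position {k}")
        if c1 not in _AA or c2 not in _AA:
            continue
        s1, n1 = _codon_site_counts(c1)
        s2, n2 = _codon_site_counts(c2)
        s_sites_a += s1
        n_sites_a += n1
        s_sites_b += s2
        n_sites_b += n2
        if c1 != c2:
            ds_, dn_ = _pathway_counts(c1, c2)
            sd += ds_
            nd += dn_
    s_sites = (s_sites_a + s_sites_b) / 2.0
    n_sites = (n_sites_a + n_sites_b) / 2.0
    if s_sites == 0 or n_sites == 0:
        return NGEstimate(None, None, None, sd, nd, s_sites, n_sites,
                          undefined="no comparable sites")
    ds = _jc_correct(sd / s_sites)
    dn = _jc_correct(nd / n_sites)
    if ds is None or dn is None:
        return NGEstimate(dn, ds, None, sd, nd, s_sites, n_sites,
                          undefined="saturated")
    if ds == 0.0:
        return NGEstimate(dn, ds, None, sd, nd, s_sites, n_sites,
                          undefined="dS = 0")
    return NGEstimate(dn, ds, dn / ds, sd, nd, s_sites, n_sites)
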