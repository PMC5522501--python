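"""Structural repeat genotyping and trait association.

Candidate genes for migratory behaviour carry length-polymorphic structural
features: short tandem repeats in 3'UTRs (an AG microsatellite in ADCYAP1,
a TG/CG microsatellite in CREB1, lengths in bp) and polyglutamine runs
(CLOCK exon 20 regions R1/R2, NPAS2; lengths in amino acids, codons
CAA/CAG).  This module measures those lengths from aligned sequence given a
column window, regresses them on the migratory predictors (migratory
distance in km, breeding latitude in degrees from the equator) by ordinary
least squares, and compares within-group variability with a Welch t test on
means and an F ratio test on variances (groups are called statistically
similar when both p > 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RepeatGenotype",
    "RegressionFit",
    "VariabilityComparison",
    "PolyQResult",
    "microsat_length",
    "polyq_lengths",
    "fit_linear",
    "compare_variability",
]

_Q_CODONS = {"CAA", "CAG"}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class RepeatGenotype:
    """One species' repeat length at one locus (bp for DNA, aa for poly-Q)."""

    species_id: str
    gene: str
    region_id: str
    unit: str  # "bp" or "aa"
    length: int
    motif: str

    def __post_init__(self):
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if self.unit not in ("bp", "aa"):
            raise ValueError("unit must be 'bp' or 'aa'")


@dataclass
class RegressionFit:
    predictor: str
    n: int
    df: int
    residual_error: float
    F: float
    p: float
    r_squared: float
    slope: float
    intercept: float


@dataclass
class VariabilityComparison:
    group_a: str
    group_b: str
    welch_t: float
    welch_p: float
    var_F: float
    var_p: float
    similar: bool


@dataclass
class PolyQResult:
    lengths: list[int]  # in positional order
    missing_regions: int  # regions padded with 0


def microsat_length(
    seq: str, motif_spec: str, window: tuple[int, int],
    min_units: int = 3,
) -> int:
    """Longest tandem run of motif units inside a column window, in bp.

    ``motif_spec`` is one unit or several alternation units separated by
    ``|`` (e.g. ``"AG"``, ``"TG|CG"``); all units must share one length.
    Gaps are removed from the window before scanning; runs shorter than
    *min_units* report 0.  Coordinates are 0-based half-open alignment
    columns.
    """
    units = [u.strip().upper() for u in motif_spec.split("|")]
    if not units or any(not u for u in units):
        raise ValueError(f"malformed motif spec {motif_spec!r}")
    ulen = len(units[0])
    if any(len(u) != ulen for u in units) or ulen == 0:
        raise ValueError(
            f"motif units in {motif_spec!r} must share one length"
        )
    start, stop = window
    if start < 0 or stop > len(seq) or start >= stop:
        raise ValueError(f"window {window} outside sequence bounds")
    target = seq[start:stop].upper().replace("-", "")
    unit_set = set(units)
    best = 0
    for offset in range(len(target)):
        run = 0
        pos = offset
        while target[pos : pos + ulen] in unit_set:
            run += 1
            pos += ulen
        best = max(best, run)
    if best < min_units:
        return 0
    return best * ulen


def polyq_lengths(
    cds: str, frame: int = 0, regions_expected: int = 1
) -> PolyQResult:
    """Lengths of the k longest glutamine runs in a translated CDS.

    Translates with the universal code from *frame* (gaps removed first),
    finds runs of consecutive Q residues (codons CAA/CAG), keeps the
    *regions_expected* longest runs and reports their lengths in positional
    order.  Runs of a single Q do not count as a region; if fewer regions
    than expected are found, the missing ones are reported as 0 with a
    count in ``missing_regions``.  An internal stop codon is an error.
    """
    seq = cds.upper().replace("-", "")[frame:]
    seq = seq[: len(seq) - len(seq) % 3]
    protein = []
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        if codon in _STOPS:
            if k + 3 < len(seq):
                raise ValueError(
                    f"internal stop codon {codon} at nucleotide {k}"
                )
            break
        protein.append("Q" if codon in _Q_CODONS else _aa(codon))
    runs = []  # (start, length)
    i = 0
    prot = "".join(protein)
    while i < len(prot):
        if prot[i] == "Q":
            j = i
            while j < len(prot) and prot[j] == "Q":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    candidates = [r for r in runs if r[1] >= 2]
    top = sorted(candidates, key=lambda r: (-r[1], r[0]))[:regions_expected]
    top.sort(key=lambda r: r[0])
    lengths = [r[1] for r in top]
    missing = regions_expected - len(lengths)
    lengths += [0] * missing
    return PolyQResult(lengths=lengths, missing_regions=missing)


def _aa(codon: str) -> str:
    from .selection import _AA

    return _AA.get(codon, "X")


def fit_linear(lengths: dict, predictors: dict, predictor_name: str = "") -> RegressionFit:
    """OLS of repeat length on one migratory predictor.

    *lengths* and *predictors* map species id to value; species missing
    either are dropped.  Reports slope, intercept, r², the F test of the
    slope with (1, n−2) df and the residual standard error.
    """
    shared = sorted(set(lengths) & {
        s for s, v in predictors.items() if v is not None
    })
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 paired observations, have {len(shared)}"
        )
    x = np.array([predictors[s] for s in shared], dtype=float)
    y = np.array([lengths[s] for s in shared], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    n = len(shared)
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    sse = float(np.sum((y - fitted) ** 2))
    df = n - 2
    resid_err = float(np.sqrt(sse / df))
    ssy = float(np.sum((y - y.mean()) ** 2))
    if ssy == 0:  # constant response: no signal by definition
        r2, fstat, p = 0.0, 0.0, 1.0
    else:
        r2 = float(res.rvalue**2)
        if sse == 0:
            fstat, p = float("inf"), 0.0
        else:
            fstat = r2 / (1 - r2) * df if r2 < 1 else float("inf")
            p = float(stats.f.sf(fstat, 1, df))
    return RegressionFit(
        predictor=predictor_name,
        n=n,
        df=df,
        residual_error=resid_err,
        F=fstat,
        p=p,
        r_squared=r2,
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def compare_variability(
    alleles_a, alleles_b, label_a: str = "a", label_b: str = "b",
    similar_p: float = 0.001,
) -> VariabilityComparison:
    """Welch t test on means and F ratio test on variances of two groups.

    Groups are called similar when both p-values exceed *similar_p*
    (default 0.001).  Two zero-variance groups with equal means are similar
    by convention (t = 0, F = 1, p = 1).
    """
    a = np.asarray(list(alleles_a), dtype=float)
    b = np.asarray(list(alleles_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return VariabilityComparison(
                label_a, label_b, 0.0, 1.0, 1.0, 1.0, True
            )
        t, tp = float("inf"), 0.0
        f, fp = 1.0, 1.0
    else:
        t, tp = stats.ttest_ind(a, b, equal_var=False)
        if vb == 0 or va == 0:
            f, fp = float("inf"), 0.0
        else:
            f = float(va / vb)
            tail = stats.f.sf(f, a.size - 1, b.size - 1)
            fp = float(2 * min(tail, 1 - tail))
            fp = min(fp, 1.0)
    similar = bool(tp > similar_p and fp > similar_p)
    return VariabilityComparison(
        label_a, label_b, float(t), float(tp), float(f), fp, similar
    )
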