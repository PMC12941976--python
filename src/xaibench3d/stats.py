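"""Nonparametric comparison layer for benchmark scores.

Kruskal-Wallis H with an eta-squared effect size across methods, pairwise
Mann-Whitney U with exact permutation p-values for small samples, Bonferroni
correction applied per dataset-metric combination, Cohen's r from the
Z-score, and IQR outlier filtering of per-sample metric values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as sps

#: pooled-sample-size limit below which the exact permutation test runs in "auto"
EXACT_MAX_POOLED_N = 12


@dataclass
class StatResult:
    """Outcome of one group or pairwise comparison."""

    test: str  # "kruskal_wallis" | "mann_whitney"
    statistic: float  # H, or min(U1, U2)
    p_raw: float
    effect_size: float  # eta-squared or Cohen's r
    effect_label: str = ""
    z_score: float | None = None  # Mann-Whitney only
    p_corrected: float | None = None
    group_labels: tuple = ()
    n_per_group: tuple = ()
    exact: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p-value {self.p_raw} outside [0, 1]")


@dataclass
class OutlierBounds:
    """Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""

    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr


def effect_size_label(r: float) -> str:
    """Conventional interpretation bands: 0.1 small, 0.3 medium, 0.5 large."""
    r = abs(r)
    if r >= 0.5:
        return "large"
    if r >= 0.3:
        return "medium"
    if r >= 0.1:
        return "small"
    return "negligible"


def cohen_r(z_score: float, n_total: int) -> float:
    """Cohen's r = |Z| / sqrt(n)."""
    if n_total < 2:
        raise ValueError("n_total must be at least 2")
    return abs(z_score) / sqrt(n_total)


def kruskal_wallis(groups, group_labels=None) -> StatResult:
    """Kruskal-Wallis H test across k groups with midrank tie correction.

    The effect size is the epsilon-squared-style estimator
    eta^2 = (H - k + 1) / (n - k), clamped at zero when H < k - 1
    (small samples can produce nominally negative values).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need at least two non-empty groups")
    k = len(groups)
    n = sum(g.size for g in groups)
    labels = tuple(group_labels) if group_labels is not None else tuple(range(k))
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        # all values identical: no evidence of any difference
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    eta2 = max(0.0, (h - k + 1) / (n - k)) if n > k else float("nan")
    return StatResult(
        test="kruskal_wallis",
        statistic=float(h),
        p_raw=float(p),
        effect_size=float(eta2),
        effect_label=effect_size_label(sqrt(eta2)) if np.isfinite(eta2) else "",
        group_labels=labels,
        n_per_group=tuple(int(g.size) for g in groups),
    )


def _mwu_normal_z(u1: float, ranks: np.ndarray, n1: int, n2: int) -> float:
    """Z-score of U1 under the tie-corrected normal null, continuity corrected."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)
    return float((diff - cc) / sqrt(var))


def mann_whitney(a, b, mode: str = "auto", alternative: str = "two-sided") -> StatResult:
    """Mann-Whitney U test with an exact permutation option.

    Exact mode enumerates all C(n1+n2, n1) assignments of the pooled ranks
    to the first group and computes the permutation p-value of U; it
    requires tie-free data.  Approx mode uses the tie-corrected normal
    approximation with a 0.5 continuity correction.  Auto switches to exact
    when n1 + n2 <= 12 and the pooled data are tie-free.  The Z-score from
    the normal approximation is always retained for the Cohen's r effect
    size; the reported statistic is min(U1, U2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    tie_free = np.unique(pooled).size == n
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = float(n1 * n2 - u1)
    z = _mwu_normal_z(u1, ranks, n1, n2)

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_MAX_POOLED_N and tie_free)
    if mode == "exact" and not tie_free:
        raise ValueError("exact permutation p-values require tie-free data")

    if use_exact:
        mu = n1 * n2 / 2.0
        total = comb(n, n1)
        offset = n1 * (n1 + 1) / 2.0
        eps = 1e-9
        hits = 0
        for idx in combinations(range(n), n1):
            u_perm = ranks[list(idx)].sum() - offset
            if alternative == "two-sided":
                hit = abs(u_perm - mu) >= abs(u1 - mu) - eps
            elif alternative == "greater":
                hit = u_perm >= u1 - eps
            else:
                hit = u_perm <= u1 + eps
            hits += hit
        p = hits / total
        exact = True
    else:
        if alternative == "two-sided":
            p = 2.0 * sps.norm.sf(abs(z))
        elif alternative == "greater":
            p = sps.norm.sf(z)
        else:
            p = sps.norm.cdf(z)
        p = float(min(1.0, p))
        exact = False

    r = cohen_r(z, n)
    return StatResult(
        test="mann_whitney",
        statistic=min(u1, u2),
        p_raw=float(p),
        effect_size=r,
        effect_label=effect_size_label(r),
        z_score=z,
        n_per_group=(n1, n2),
        exact=exact,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: each p multiplied by m, capped at 1.

    ``m`` defaults to the number of p-values; in the benchmark it is the
    number of method pairs within one dataset-metric combination.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than the number of p-values ({p.size})")
    return np.minimum(1.0, p * m)


def iqr_filter(values) -> tuple[np.ndarray, OutlierBounds | None, np.ndarray]:
    """Remove values outside the Tukey fences, preserving order.

    Quartiles use linear-interpolation quantiles.  With fewer than 4 values
    the filter is skipped with a warning and everything is kept.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn(
            f"IQR filter skipped: need >= 4 values, got {values.size}",
            stacklevel=2,
        )
        return values.copy(), None, np.array([], dtype=int)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    bounds = OutlierBounds(q1=float(q1), q3=float(q3))
    keep = (values >= bounds.lower) & (values <= bounds.upper)
    return values[keep], bounds, np.flatnonzero(~keep)
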