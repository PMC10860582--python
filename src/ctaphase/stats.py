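"""Agreement and group-comparison statistics for volume method comparison.

Pearson r with Fisher-z 95% CI, ICC(2,1) with its F-based CI, simple OLS,
percentile Bland-Altman limits (2.5th/97.5th), a Shapiro-Wilk normality
gate, Kruskal-Wallis across groups, and median/IQR summaries.  Percentiles
use the linear-interpolation definition throughout, pinned for
reproducibility.

The intraclass correlation is the two-way random-effects, absolute-
agreement, single-measures form — ICC(2,1) in the Shrout & Fleiss
taxonomy, ICC(A,1) in McGraw & Wong — computed from the two-way ANOVA mean
squares, the conventional choice when comparing two measurement methods on
the same subjects.  Unlike Pearson's r it penalizes systematic offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementResult",
    "GroupComparison",
    "BlandAltman",
    "pearson_ci",
    "icc_ci",
    "ols_fit",
    "bland_altman",
    "shapiro_wilk_gate",
    "kruskal_wallis",
    "median_iqr",
    "agreement",
]


@dataclass
class AgreementResult:
    """Correlation/ICC agreement between two volume series, with OLS fit."""

    r: float
    r_ci: tuple
    r_p: float
    icc: float
    icc_ci: tuple
    icc_p: float
    n: int
    slope: float
    intercept: float


@dataclass
class GroupComparison:
    """Per-group medians with IQR plus the Kruskal-Wallis comparison."""

    labels: tuple
    ns: tuple
    medians: tuple
    iqrs: tuple  # (q1, q3) per group
    kw_statistic: float
    kw_p: float


@dataclass
class BlandAltman:
    """Mean difference with empirical 2.5th/97.5th percentile limits."""

    mean_diff: float
    lo: float
    hi: float
    n: int


def _check_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def pearson_ci(x, y, level: float = 0.95) -> tuple[float, tuple, float]:
    """Pearson r, Fisher-z confidence interval, and two-sided P.

    The CI uses the Fisher z-transform with standard error 1/sqrt(n-3); the
    P-value comes from the exact t-distribution with n-2 df.
    """
    x, y = _check_pair(x, y, 4)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    with np.errstate(divide="ignore"):
        ci = res.confidence_interval(confidence_level=level)
    return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)


def _anova_mean_squares(x: np.ndarray, y: np.ndarray) -> tuple:
    """Two-way (subjects x methods) ANOVA mean squares for paired data."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc_ci(x, y, level: float = 0.95) -> tuple[float, tuple, float]:
    """ICC(2,1) (absolute agreement, single measures) with F-based CI and P.

    Computed from the two-way ANOVA mean squares (rows = subjects, columns =
    methods); the confidence interval is the standard Satterthwaite-df
    F interval of McGraw & Wong, and P comes from F = MSR/MSE with
    (n-1, (n-1)(k-1)) df.
    """
    x, y = _check_pair(x, y, 4)
    if np.ptp(x) == 0 and np.ptp(y) == 0 and np.all(x == y):
        raise ValueError("ICC undefined: all pairs identical (no variance)")
    n, k, msr, msc, mse = _anova_mean_squares(x, y)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: degenerate variance decomposition")
    icc = (msr - mse) / denom

    alpha = 1.0 - level
    if mse == 0:
        ci = (icc, icc)
        p = 0.0
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        p = float(sps.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
        ci = (float(lower), float(upper))
    return float(icc), ci, p


def ols_fit(x, y) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    x, y = _check_pair(x, y, 2)
    if np.ptp(x) == 0:
        raise ValueError("OLS undefined for constant x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept)


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman summary of differences d = x − y.

    Agreement limits are the empirical 2.5th and 97.5th percentiles of the
    differences (linear-interpolation definition), not mean ± 1.96 SD, so
    they stay meaningful for skewed volume data.  Orientation: pass the
    estimate first and the reference second, so a positive mean difference
    means overestimation.
    """
    x, y = _check_pair(x, y, 3)
    d = x - y
    lo, hi = np.percentile(d, [2.5, 97.5])
    return BlandAltman(float(d.mean()), float(lo), float(hi), len(d))


def shapiro_wilk_gate(values, alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk normality P-value and gate (True = compatible with normal).

    A False gate justifies reporting medians/IQR and rank-based tests for
    volume data.  Valid for 3 <= n <= 5000.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or not (3 <= len(values) <= 5000):
        raise ValueError("Shapiro-Wilk requires a 1D sample with 3 <= n <= 5000")
    if not np.all(np.isfinite(values)):
        raise ValueError("inputs must be finite")
    p = float(sps.shapiro(values).pvalue)
    return p, p >= alpha


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square P across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one value")
    total = np.concatenate(groups)
    if len(total) < 3:
        raise ValueError("need at least 3 values in total")
    if np.ptp(total) == 0:
        raise ValueError("Kruskal-Wallis undefined: all values identical")
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def median_iqr(values) -> tuple[float, tuple]:
    """Median and (25th, 75th) percentiles, linear-interpolation definition."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 1:
        raise ValueError("need a non-empty 1D sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def agreement(estimate, reference, level: float = 0.95) -> AgreementResult:
    """Full agreement panel of an estimate against a reference.

    Pearson r + CI + P, ICC(2,1) + CI + P, and the OLS fit of the estimate
    on the reference.
    """
    x, y = _check_pair(estimate, reference, 4)
    r, r_ci, r_p = pearson_ci(x, y, level)
    icc, icc_ci_, icc_p = icc_ci(x, y, level)
    slope, intercept = ols_fit(y, x)  # estimate regressed on reference
    return AgreementResult(
        r=r, r_ci=r_ci, r_p=r_p,
        icc=icc, icc_ci=icc_ci_, icc_p=icc_p,
        n=len(x), slope=slope, intercept=intercept,
    )
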