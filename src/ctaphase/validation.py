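"""End-to-end validation experiments with independent oracles.

Each function here runs one self-contained experiment on synthetic data —
timing parameter recovery, phase monotonicity, protocol-preset phase
clustering, statistical oracle equivalence, test calibration, volumetry
exactness, and cohort-direction recovery — and returns plain numbers.  The
oracles in this module (brute-force product-moment correlation, normal-
equation OLS, sort-based percentiles, rank-based Kruskal-Wallis H, exact
permutation distributions, voxel-loop volume counting) are deliberately
written along different code paths from the package implementation they
check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .pipeline import build_report
from .stats import bland_altman, icc_ci, kruskal_wallis, median_iqr, ols_fit, pearson_ci
from .synthetic import (
    BolusModel,
    BolusParams,
    CohortParams,
    PhantomGeometry,
    preset_test_bolus_t_acq,
    simulate_cohort,
    simulate_cta_snapshot,
    simulate_ctp_series,
    simulate_probability_map,
)
from .tac import cta_roi_values, extract_roi_curve
from .timing import estimate_timing, phase_rank
from .volumetry import (
    lesion_volume_from_probability,
    thresholded_volume,
    voxel_volume_mL,
)

__all__ = [
    "timing_recovery_experiment",
    "phase_monotonicity_experiment",
    "preset_phase_experiment",
    "stats_oracle_experiment",
    "kruskal_type1_experiment",
    "pearson_ci_coverage_experiment",
    "volumetry_exactness_experiment",
    "cohort_direction_experiment",
]


def _subseed(seed: int, k: int) -> int:
    """Derived RNG seed, kept below 2**31."""
    return int(np.random.SeedSequence([int(seed), int(k)]).generate_state(1)[0] % (2**31 - 1))


def _random_bolus(rng: np.random.Generator, noise_sd: float, seed: int) -> BolusParams:
    """Bolus parameters jittered around the defaults, one phantom's worth."""
    return BolusParams(
        t0=rng.uniform(10.0, 14.0),
        alpha=rng.uniform(2.6, 3.4),
        beta=rng.uniform(1.3, 1.7),
        amplitude=rng.uniform(150.0, 220.0),
        venous_delay=rng.uniform(3.0, 4.5),
        venous_dispersion=rng.uniform(2.2, 2.8),
        noise_sd=noise_sd,
        seed=seed,
    )


def _estimate_one(params: BolusParams, t_acq: float, geometry: PhantomGeometry):
    series, _ = simulate_ctp_series(params, geometry)
    aif = extract_roi_curve(series, geometry.arterial_roi())
    vof = extract_roi_curve(series, geometry.venous_roi())
    snapshot = simulate_cta_snapshot(params, geometry, t_acq)
    a_hu, v_hu = cta_roi_values(snapshot, geometry.arterial_roi(), geometry.venous_roi())
    return estimate_timing(aif, vof, a_hu, v_hu)


def timing_recovery_experiment(
    n_phantoms: int = 50, noise_sd: float = 0.0, seed: int = 0
) -> dict:
    """Recover known CTA acquisition times on simulated phantoms.

    For each phantom the acquisition time is drawn uniformly over the
    informative bolus window (from just after bolus arrival to the end of
    the venous washout) and re-estimated through the full extraction +
    intersection pipeline.  Returns absolute errors in seconds.
    """
    rng = np.random.default_rng(seed)
    geometry = PhantomGeometry()
    errors = []
    for i in range(n_phantoms):
        params = _random_bolus(rng, noise_sd, _subseed(seed, i))
        lo, hi = BolusModel(params).bolus_window()
        t_acq = rng.uniform(lo, hi)
        est = _estimate_one(params, t_acq, geometry)
        errors.append(abs(est.t_est - t_acq))
    errors = np.asarray(errors)
    return {
        "errors_s": errors,
        "max_abs_error_s": float(errors.max()),
        "median_abs_error_s": float(np.median(errors)),
        "frame_interval_s": BolusParams().frame_interval,
        "n": n_phantoms,
    }


def phase_monotonicity_experiment(n_sweep: int = 200, seed: int = 0) -> dict:
    """Sweep the acquisition time forward and check phases never regress."""
    params = BolusParams(noise_sd=0.0, seed=_subseed(seed, 0))
    geometry = PhantomGeometry()
    model = BolusModel(params)
    lo, hi = model.bolus_window()
    ranks = []
    for t_acq in np.linspace(lo, hi, n_sweep):
        est = _estimate_one(params, float(t_acq), geometry)
        ranks.append(phase_rank(est.phase))
    ranks = np.asarray(ranks)
    violations = int(np.sum(np.diff(ranks) < 0))
    return {"ranks": ranks, "n_violations": violations, "n": n_sweep}


def preset_phase_experiment(n_phantoms: int = 50, seed: int = 0) -> dict:
    """Phase distribution under the "test-bolus peak + 12 s" CTA protocol."""
    rng = np.random.default_rng(seed)
    geometry = PhantomGeometry()
    phases = []
    for i in range(n_phantoms):
        params = _random_bolus(rng, noise_sd=5.0, seed=_subseed(seed, i))
        t_acq = preset_test_bolus_t_acq(params, jitter_sd=0.6, rng=rng)
        est = _estimate_one(params, t_acq, geometry)
        phases.append(est.phase)
    frac_mid = float(np.mean([p == "mid_arterial" for p in phases]))
    return {"phases": phases, "mid_arterial_fraction": frac_mid, "n": n_phantoms}


# ---------------------------------------------------------------------------
# Brute-force statistical oracles
# ---------------------------------------------------------------------------


def pearson_oracle(x, y) -> float:
    """Product-moment correlation via the raw sum formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def ols_oracle(x, y) -> tuple:
    """OLS slope/intercept by solving the normal equations directly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.array([[len(x), x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return float(slope), float(intercept)


def quantile_oracle(values, q: float) -> float:
    """Linear-interpolation percentile computed from sorted order statistics."""
    s = sorted(float(v) for v in values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def kruskal_h_oracle(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from first-principles mid-ranks."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        ng = len(g)
        rsum = sum(ranks[start : start + ng])
        h += rsum**2 / ng
        start += ng
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts: dict = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = 1.0 - sum(c**3 - c for c in counts.values()) / (n**3 - n)
    return h / tie


def kruskal_permutation_p(group_a, group_b) -> float:
    """Exact permutation P of the two-group Kruskal-Wallis H statistic."""
    pooled = list(group_a) + list(group_b)
    na = len(group_a)
    h_obs = kruskal_h_oracle([list(group_a), list(group_b)])
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        h = kruskal_h_oracle([a, b])
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


# Fixed 6-pair method-comparison table for the ICC spot check.  The frozen
# expectation in the tests was computed independently with exact rational
# ANOVA arithmetic on this table.
ICC_FIXED_TABLE = (
    (20.0, 24.0),
    (30.0, 28.0),
    (45.0, 50.0),
    (60.0, 64.0),
    (80.0, 74.0),
    (100.0, 112.0),
)


def icc_anova_oracle(pairs) -> float:
    """ICC(2,1) recomputed with exact rational ANOVA arithmetic."""
    from fractions import Fraction

    data = [[Fraction(v) for v in row] for row in pairs]
    n = len(data)
    k = len(data[0])
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((v - grand) ** 2 for row in data for v in row)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(icc)


def stats_oracle_experiment(n_datasets: int = 100, seed: int = 0) -> dict:
    """Implementation-vs-oracle deviations for the statistics layer.

    Pearson r, OLS, median/IQR and Bland-Altman limits are compared with
    brute-force oracles on seeded bivariate datasets; ICC(2,1) against an
    exact-rational ANOVA on the fixed 6-pair table; the Kruskal-Wallis H
    against a first-principles rank oracle on all 20 arrangements of two
    3-element groups, together with the exact permutation P of the extreme
    split.
    """
    rng = np.random.default_rng(seed)
    d_pearson = d_ols = d_quant = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(8, 40))
        x = rng.normal(50.0, 30.0, n)
        y = 0.8 * x + rng.normal(0.0, 20.0, n)
        r, _, _ = pearson_ci(x, y)
        d_pearson = max(d_pearson, abs(r - pearson_oracle(x, y)))
        slope, intercept = ols_fit(x, y)
        so, io_ = ols_oracle(x, y)
        d_ols = max(d_ols, abs(slope - so), abs(intercept - io_))
        med, (q1, q3) = median_iqr(x)
        d_quant = max(
            d_quant,
            abs(med - quantile_oracle(x, 0.5)),
            abs(q1 - quantile_oracle(x, 0.25)),
            abs(q3 - quantile_oracle(x, 0.75)),
        )
        ba = bland_altman(x, y)
        d = x - y
        d_quant = max(
            d_quant,
            abs(ba.lo - quantile_oracle(d, 0.025)),
            abs(ba.hi - quantile_oracle(d, 0.975)),
            abs(ba.mean_diff - sum(d) / len(d)),
        )

    xs = [row[0] for row in ICC_FIXED_TABLE]
    ys = [row[1] for row in ICC_FIXED_TABLE]
    icc, _, _ = icc_ci(xs, ys)
    d_icc = abs(icc - icc_anova_oracle(ICC_FIXED_TABLE))

    # All arrangements of two 3-element groups of six distinct values.
    values = (1.0, 2.0, 3.0, 101.0, 102.0, 103.0)
    d_kw = 0.0
    pairs = []
    for idx in itertools.combinations(range(6), 3):
        a = [values[i] for i in idx]
        b = [values[i] for i in range(6) if i not in idx]
        h, p = kruskal_wallis([a, b])
        pairs.append((h, p))
        d_kw = max(d_kw, abs(h - kruskal_h_oracle([a, b])))
    # chi-square P must be strictly decreasing in H
    pairs.sort(key=lambda t: t[0])
    p_monotone = all(
        p2 <= p1 + 1e-12 for (h1, p1), (h2, p2) in zip(pairs, pairs[1:])
    )
    perm_p_extreme = kruskal_permutation_p([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
    h_extreme, chi2_p_extreme = kruskal_wallis([[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]])
    h_all = [h for h, _ in pairs]
    return {
        "max_abs_diff_pearson": float(d_pearson),
        "max_abs_diff_ols": float(d_ols),
        "max_abs_diff_percentiles": float(d_quant),
        "abs_diff_icc": float(d_icc),
        "max_abs_diff_kw_h": float(d_kw),
        "kw_p_monotone_in_h": bool(p_monotone),
        "kw_h_extreme": float(h_extreme),
        "kw_h_is_max": bool(abs(h_extreme - max(h_all)) < 1e-12),
        "kw_chi2_p_extreme": float(chi2_p_extreme),
        "kw_perm_p_extreme": float(perm_p_extreme),
        "n": n_datasets,
    }


def kruskal_type1_experiment(
    n_reps: int = 2000, k: int = 3, n_per_group: int = 20, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Type-I error of the Kruskal-Wallis test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        groups = [rng.normal(0.0, 1.0, n_per_group) for _ in range(k)]
        _, p = kruskal_wallis(groups)
        rejections += p < alpha
    return {"rejection_rate": rejections / n_reps, "n": n_reps}


def pearson_ci_coverage_experiment(
    n_reps: int = 1000, n: int = 30, rho: float = 0.5, seed: int = 0
) -> dict:
    """Coverage of the Fisher-z 95% CI at a fixed true correlation."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    covered = 0
    for _ in range(n_reps):
        z = rng.standard_normal((n, 2)) @ chol.T
        _, (lo, hi), _ = pearson_ci(z[:, 0], z[:, 1])
        covered += lo <= rho <= hi
    return {"coverage": covered / n_reps, "true_rho": rho, "n": n_reps}


def brute_force_volume(map_3d, predicate, spacing) -> float:
    """Voxel-by-voxel loop volume computation (oracle)."""
    arr = np.asarray(map_3d, dtype=float)
    count = 0
    flat = arr.ravel()
    for v in flat:
        if predicate(v):
            count += 1
    return count * spacing[0] * spacing[1] * spacing[2] / 1000.0


def volumetry_exactness_experiment(n_maps: int = 50, seed: int = 0) -> dict:
    """Thresholded volumes vs a brute-force voxel loop, plus decoy filtering.

    Random Tmax/rCBF maps on random small grids are thresholded both ways;
    a constructed probability map with one genuine ipsilateral lesion, one
    sub-0.1 mL ipsilateral speck, one contralateral decoy and one cerebellar
    decoy must keep exactly the genuine lesion.
    """
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_maps):
        shape = tuple(int(rng.integers(6, 14)) for _ in range(3))
        spacing = tuple(float(rng.uniform(0.5, 3.0)) for _ in range(3))
        tmax = rng.uniform(0.0, 15.0, shape)
        rcbf = rng.uniform(0.0, 1.5, shape)
        v1 = thresholded_volume(tmax, lambda m: m > 6.0, spacing)
        v2 = thresholded_volume(rcbf, lambda m: m < 0.3, spacing)
        o1 = brute_force_volume(tmax, lambda v: v > 6.0, spacing)
        o2 = brute_force_volume(rcbf, lambda v: v < 0.3, spacing)
        max_diff = max(max_diff, abs(v1 - o1), abs(v2 - o2))

    geometry = PhantomGeometry(shape=(24, 24, 12), spacing=(1.0, 1.0, 1.0))
    lesions = [
        {"center": (6.0, 12.0, 7.0), "radius": 4.0, "p": 0.9},  # genuine, ipsilateral
        {"center": (3.0, 3.0, 9.0), "radius": 1.0, "p": 0.9},  # speck <= 0.1 mL
        {"center": (19.0, 12.0, 7.0), "radius": 3.0, "p": 0.9},  # contralateral decoy
        {"center": (6.0, 20.0, 0.0), "radius": 2.0, "p": 0.9},  # cerebellar decoy
    ]
    pmap = simulate_probability_map(lesions, geometry)
    result = lesion_volume_from_probability(pmap)
    # the genuine lesion sphere is disjoint from every decoy, so the expected
    # kept volume is exactly its voxel count times the voxel volume
    vv = voxel_volume_mL(geometry.spacing)
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in geometry.shape), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, lesions[0]["center"]))
    expected = int(np.sum(d2 <= lesions[0]["radius"] ** 2)) * vv
    decoy_ok = (
        result.n_components_kept == 1
        and result.n_components_rejected == 3
        and abs(result.volume_mL - expected) < 1e-12
    )
    return {
        "max_abs_volume_diff_mL": float(max_diff),
        "decoy_filter_correct": bool(decoy_ok),
        "kept_volume_mL": float(result.volume_mL),
        "expected_volume_mL": float(expected),
        "n": n_maps,
    }


def cohort_direction_experiment(n_patients: int = 500, seed: int = 0) -> dict:
    """Directional recovery on a generated-then-analyzed cohort.

    With half the at-risk tissue included in the CTA-based estimate and a
    collateral effect > 1, the stratified report must show overestimation in
    reperfused patients and larger final infarcts with poor collaterals
    under both the Miteff and HIR stratifications.
    """
    params = CohortParams(
        n_patients=n_patients, lambda_penumbra=0.5, collateral_effect=2.0, seed=seed
    )
    records = simulate_cohort(params)
    report = build_report(records)
    succ = report.stratum("TICI", "all", "successful")
    miteff_poor = report.stratum("Miteff", "all", "1")
    miteff_good = report.stratum("Miteff", "all", "3")
    hir_poor = report.stratum("HIR", "all", ">=0.5")
    hir_good = report.stratum("HIR", "all", "<0.5")
    hirs = [r.hir for r in records]
    return {
        "cnn_median_reperfused_mL": succ.cnn_median,
        "fiv_median_reperfused_mL": succ.fiv_median,
        "fiv_median_miteff_poor_mL": miteff_poor.fiv_median,
        "fiv_median_miteff_good_mL": miteff_good.fiv_median,
        "fiv_median_hir_poor_mL": hir_poor.fiv_median,
        "fiv_median_hir_good_mL": hir_good.fiv_median,
        "hir_min": float(min(hirs)),
        "hir_max": float(max(hirs)),
        "n": n_patients,
    }
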