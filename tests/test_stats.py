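"""Agreement statistics against independent oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctaphase.stats import (
    agreement,
    bland_altman,
    icc_ci,
    kruskal_wallis,
    median_iqr,
    ols_fit,
    pearson_ci,
    shapiro_wilk_gate,
)
from ctaphase.validation import (
    ICC_FIXED_TABLE,
    icc_anova_oracle,
    kruskal_h_oracle,
    ols_oracle,
    pearson_oracle,
    quantile_oracle,
)


class TestPearson:
    def test_perfect_positive_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, (lo, hi), p = pearson_ci(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert hi == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_negative_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, _, _ = pearson_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_product_moment_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(50, 20, 20)
            y = 0.5 * x + rng.normal(0, 15, 20)
            r, _, _ = pearson_ci(x, y)
            assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_ci_contains_r_and_is_ordered(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        r, (lo, hi), _ = pearson_ci(x, y)
        assert lo <= r <= hi

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_invariant_to_joint_reordering_and_affine_rescaling(self, rng):
        x = rng.normal(30, 10, 25)
        y = x + rng.normal(0, 8, 25)
        r0, _, _ = pearson_ci(x, y)
        perm = rng.permutation(25)
        r1, _, _ = pearson_ci(x[perm], y[perm])
        r2, _, _ = pearson_ci(3.0 * x + 7.0, y)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert r2 == pytest.approx(r0, abs=1e-12)


class TestIcc:
    def test_identity_gives_one(self):
        x = np.array([10.0, 20.0, 35.0, 50.0, 80.0])
        icc, _, _ = icc_ci(x, x.copy())
        assert icc == pytest.approx(1.0)

    def test_systematic_offset_penalized_below_pearson(self, rng):
        x = rng.normal(50, 15, 20)
        y = x + 100.0
        icc, _, _ = icc_ci(x, y)
        r, _, _ = pearson_ci(x, y)
        assert icc < r - 0.5  # absolute agreement punishes the offset

    def test_fixed_table_matches_exact_rational_anova(self):
        xs = [row[0] for row in ICC_FIXED_TABLE]
        ys = [row[1] for row in ICC_FIXED_TABLE]
        icc, _, _ = icc_ci(xs, ys)
        # frozen: exact-rational two-way ANOVA of the 6-pair table
        assert icc == pytest.approx(0.9798241942235245, abs=1e-12)
        assert icc == pytest.approx(icc_anova_oracle(ICC_FIXED_TABLE), abs=1e-12)

    def test_matches_pingouin_two_way_random_absolute(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n = 15
        x = rng.normal(40, 20, n)
        y = 0.9 * x + rng.normal(0, 10, n) + 5
        icc, (lo, hi), p = icc_ci(x, y)
        df = pd.DataFrame(
            {"t": list(range(n)) * 2, "r": ["a"] * n + ["b"] * n, "s": np.concatenate([x, y])}
        )
        row = (
            pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
            .set_index("Type")
            .loc["ICC(A,1)"]
        )
        assert icc == pytest.approx(row["ICC"], abs=1e-10)
        assert p == pytest.approx(row["pval"], abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert lo == pytest.approx(row["CI95"][0], abs=0.01)
        assert hi == pytest.approx(row["CI95"][1], abs=0.01)

    def test_not_affine_invariant_unlike_pearson(self, rng):
        x = rng.normal(30, 10, 25)
        y = x + rng.normal(0, 5, 25)
        icc0, _, _ = icc_ci(x, y)
        icc_shifted, _, _ = icc_ci(x + 50.0, y)
        assert abs(icc_shifted - icc0) > 0.05

    def test_degenerate_identical_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_ci([5.0, 5.0, 5.0, 5.0], [5.0, 5.0, 5.0, 5.0])


class TestOls:
    def test_two_points(self):
        slope, intercept = ols_fit([0.0, 1.0], [1.0, 3.0])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept = ols_fit(x, x)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(0, 50, 40)
        y = 1.4 * x + rng.normal(0, 10, 40) + 3
        slope, intercept = ols_fit(x, y)
        s0, i0 = ols_oracle(x, y)
        assert slope == pytest.approx(s0, abs=1e-10)
        assert intercept == pytest.approx(i0, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 5.0, 9.0])
        ba = bland_altman(x, x.copy())
        assert ba.mean_diff == 0.0
        assert ba.lo == 0.0 and ba.hi == 0.0

    def test_three_point_percentiles(self):
        # d = (-1, 0, 1); 2.5th/97.5th by linear interpolation of order stats
        ba = bland_altman(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.lo == pytest.approx(-0.95)
        assert ba.hi == pytest.approx(0.95)

    def test_translation_equivariance(self, rng):
        x = rng.normal(40, 20, 30)
        y = rng.normal(40, 20, 30)
        b0 = bland_altman(x, y)
        b1 = bland_altman(x + 13.0, y)
        assert b1.mean_diff == pytest.approx(b0.mean_diff + 13.0, abs=1e-10)
        assert b1.lo == pytest.approx(b0.lo + 13.0, abs=1e-10)
        assert b1.hi == pytest.approx(b0.hi + 13.0, abs=1e-10)

    def test_limits_match_quantile_oracle(self, rng):
        x = rng.normal(50, 25, 41)
        y = rng.normal(45, 25, 41)
        ba = bland_altman(x, y)
        d = x - y
        assert ba.lo == pytest.approx(quantile_oracle(d, 0.025), abs=1e-12)
        assert ba.hi == pytest.approx(quantile_oracle(d, 0.975), abs=1e-12)


class TestShapiro:
    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk_gate([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk_gate(np.zeros(5001))

    def test_uniform_data_rejected_most_of_the_time(self, rng):
        rejected = 0
        for _ in range(50):
            p, gate = shapiro_wilk_gate(rng.uniform(0, 1, 200))
            rejected += not gate
        assert rejected >= 45

    def test_normal_data_usually_passes(self, rng):
        passed = 0
        for _ in range(50):
            _, gate = shapiro_wilk_gate(rng.normal(0, 1, 200))
            passed += gate
        assert passed >= 40


class TestKruskalWallis:
    def test_h_matches_rank_oracle_with_ties(self, rng):
        for _ in range(20):
            groups = [list(rng.integers(0, 8, rng.integers(3, 10)).astype(float)) for _ in range(3)]
            if len({v for g in groups for v in g}) < 2:
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_h_oracle(groups), abs=1e-10)

    def test_invariant_to_within_group_reordering(self, rng):
        g1 = list(rng.normal(0, 1, 8))
        g2 = list(rng.normal(0.5, 1, 6))
        h0, p0 = kruskal_wallis([g1, g2])
        h1, p1 = kruskal_wallis([g1[::-1], sorted(g2)])
        assert h1 == pytest.approx(h0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([[3.0, 3.0], [3.0, 3.0]])

    def test_extreme_separation_attains_max_h(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]])
        assert h == pytest.approx(3.857142857142857, abs=1e-12)


class TestMedianIqr:
    def test_odd_sample(self):
        med, (q1, q3) = median_iqr([1.0, 2.0, 3.0, 4.0, 5.0])
        assert med == 3.0

    def test_single_value(self):
        med, (q1, q3) = median_iqr([7.5])
        assert med == 7.5 and q1 == 7.5 and q3 == 7.5

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_matches_sort_based_oracle(self, values):
        med, (q1, q3) = median_iqr(values)
        assert med == pytest.approx(quantile_oracle(values, 0.5), abs=1e-9)
        assert q1 == pytest.approx(quantile_oracle(values, 0.25), abs=1e-9)
        assert q3 == pytest.approx(quantile_oracle(values, 0.75), abs=1e-9)


class TestAgreement:
    def test_composite_panel_consistency(self, rng):
        x = rng.normal(40, 20, 25)
        y = 0.8 * x + rng.normal(0, 10, 25)
        res = agreement(x, y)
        assert res.r_ci[0] <= res.r <= res.r_ci[1]
        assert res.n == 25
        slope, intercept = ols_fit(y, x)
        assert res.slope == pytest.approx(slope)
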