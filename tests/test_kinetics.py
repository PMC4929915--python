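"""Regression, decay-rate estimation, cohort table, ANCOVA."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from herbdna import SampleMeta, ancova, cohort_table, estimate_decay_rate, regress
from herbdna.fraglen import DecayFit


class TestRegress:
    def test_exact_line_through_origin(self):
        x = np.array([50.0, 150.0, 278.0])
        r = regress(x, 2e-4 * x, through_origin=True)
        assert r.slope == pytest.approx(2e-4)
        assert r.r_squared == pytest.approx(1.0)
        assert r.intercept is None

    def test_constant_y_no_signal(self):
        r = regress([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert r.slope == pytest.approx(0.0)
        assert r.r_squared == pytest.approx(0.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            regress([1.0, 2.0], [1.0, 2.0])
        assert regress([1.0, 2.0], [1.0, 2.0], through_origin=True).n == 2

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=3, max_size=100,
            unique_by=lambda t: round(t[0], 6),
        )
    )
    def test_matches_normal_equations_brute_force(self, pts):
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        if np.ptp(x) == 0:
            return
        r = regress(x, y)
        X = np.column_stack([np.ones_like(x), x])
        b0, b1 = np.linalg.solve(X.T @ X, X.T @ y)
        assert r.intercept == pytest.approx(b0, abs=1e-8)
        assert r.slope == pytest.approx(b1, abs=1e-8)
        rto = regress(x, y, through_origin=True)
        assert rto.slope == pytest.approx(float(x @ y) / float(x @ x), abs=1e-8)

    def test_p_value_matches_scipy_t_test(self):
        rng = np.random.default_rng(2)
        x = rng.random(30)
        y = 2 * x + rng.normal(0, 0.5, 30)
        r = regress(x, y)
        sp = stats.linregress(x, y)
        assert r.p_value == pytest.approx(sp.pvalue, rel=1e-9)
        assert r.slope_se == pytest.approx(sp.stderr, rel=1e-9)

    def test_null_p_values_uniform(self):
        # F-test calibration: p under the null is U(0,1)
        rng = np.random.default_rng(17)
        pvals = []
        x = np.arange(10.0)
        for _ in range(500):
            pvals.append(regress(x, rng.normal(size=10)).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestDecayRate:
    def test_exact_paper_rate_construction(self):
        # lambda exactly 1.66e-4 * age at the study's age span
        ages = [50.0, 150.0, 278.0]
        est = estimate_decay_rate([(a, 1.66e-4 * a) for a in ages])
        assert est.k == pytest.approx(1.66e-4)
        assert est.through_origin.r_squared == pytest.approx(1.0)

    def test_flagged_fits_excluded(self):
        good = [(a, DecayFit(1e-4 * a, 0.0, (40, 100), 0.9, 30)) for a in (50, 100, 200, 250)]
        bad = [(300.0, DecayFit(-0.01, 0.0, (40, 100), 0.1, 30, ok=False))]
        with pytest.warns(UserWarning, match="excluded 1"):
            est = estimate_decay_rate(good + bad)
        assert est.through_origin.n == 4
        assert est.k == pytest.approx(1e-4)

    def test_too_few_usable_samples(self):
        with pytest.raises(ValueError, match=">= 3"):
            with pytest.warns(UserWarning):
                estimate_decay_rate([(50.0, 0.01), (100.0, 0.02), (-1.0, 0.01)])

    def test_free_intercept_recovers_offset_where_through_origin_is_biased(self):
        # age-independent baseline fragmentation: lambda = b + k*age
        rng = np.random.default_rng(8)
        ages = np.linspace(20, 278, 40)
        lam = 0.005 + 1e-4 * ages + rng.normal(0, 2e-4, ages.size)
        est = estimate_decay_rate(list(zip(ages, lam)))
        assert est.free_intercept.intercept == pytest.approx(0.005, abs=5e-4)
        assert est.free_intercept.slope == pytest.approx(1e-4, rel=0.05)
        assert est.k > 1.1e-4  # through-origin absorbs the offset into the slope


class TestCohortTable:
    def _meta(self, sid, year):
        return SampleMeta(sample_id=sid, collection_year=year, age=2015 - year)

    def test_no_silent_drops(self):
        metas = [self._meta(f"s{i}", 1800 + i) for i in range(71)]
        stats_rows = [{"sample_id": f"s{i}", "lambda_hat": 1e-4 * i} for i in range(71)]
        table = cohort_table(stats_rows, metas)
        assert len(table) == 71
        assert (table["age"] == 2015 - table["collection_year"]).all()

    def test_missing_statistic_kept_as_nan(self):
        metas = [self._meta(f"s{i}", 1900) for i in range(3)]
        rows = [
            {"sample_id": "s0", "lambda_hat": 1e-3},
            {"sample_id": "s1", "lambda_hat": float("nan")},
            {"sample_id": "s2", "lambda_hat": 2e-3},
        ]
        table = cohort_table(rows, metas)
        assert len(table) == 3
        assert table["lambda_hat"].isna().sum() == 1

    def test_unmatched_sample_id_errors(self):
        with pytest.raises(KeyError, match="ghost"):
            cohort_table([{"sample_id": "ghost"}], [self._meta("s0", 1900)])

    def test_factor_columns_joined(self):
        m = self._meta("s0", 1900)
        m.factors["extraction_method"] = "CTAB"
        table = cohort_table([{"sample_id": "s0"}], [m])
        assert table.loc[0, "extraction_method"] == "CTAB"


def brute_force_sequential_ss(df):
    """Sequential (Type I) sums of squares by explicit projection.

    Independent oracle: build the design column-blocks in order
    (intercept, covariate, factor dummies, interaction), project y on each
    growing design, and report the RSS drops.
    """
    y = df["y"].to_numpy(float)
    n = len(y)
    g = pd.get_dummies(df["g"], drop_first=True).to_numpy(float)
    x = df["x"].to_numpy(float)[:, None]
    blocks = [np.ones((n, 1)), x, g, x * g]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    out = []
    prev = rss(blocks[0])
    X = blocks[0]
    for b in blocks[1:]:
        X = np.hstack([X, b])
        cur = rss(X)
        out.append(prev - cur)
        prev = cur
    return out, prev  # [SS_x, SS_g, SS_xg], RSS_full


class TestAncova:
    def make_table(self, rng=None, slope_b=1.0, shift=0.0, n=20, noise=1.0):
        rng = rng or np.random.default_rng(0)
        x = np.tile(np.linspace(0, 10, n // 2), 2)
        g = np.repeat(["a", "b"], n // 2)
        y = np.where(g == "a", 1.0 * x, slope_b * x + shift) + rng.normal(0, noise, n)
        return pd.DataFrame({"y": y, "x": x, "g": g})

    @pytest.mark.parametrize(
        "x_b",
        [
            [0.0, 1.0, 2.0, 3.0],  # balanced: same covariate values per group
            [1.0, 2.5, 4.0, 6.0],  # unbalanced: sequential order matters
        ],
    )
    def test_sequential_ss_match_projection_oracle(self, x_b):
        df = pd.DataFrame(
            {
                "y": [1.0, 3.0, 2.0, 5.0, 2.0, 4.0, 6.0, 9.0],
                "x": [0.0, 1.0, 2.0, 3.0] + x_b,
                "g": ["a", "a", "a", "a", "b", "b", "b", "b"],
            }
        )
        res = ancova(df, "y", "x", "g")
        (ss_x, ss_g, ss_xg), rss = brute_force_sequential_ss(df)
        assert res.table.loc["x", "sum_sq"] == pytest.approx(ss_x, abs=1e-10)
        assert res.table.loc["g", "sum_sq"] == pytest.approx(ss_g, abs=1e-10)
        assert res.table.loc["x:g", "sum_sq"] == pytest.approx(ss_xg, abs=1e-10)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(rss, abs=1e-10)

    def test_sequential_ss_sum_to_total(self):
        df = self.make_table(np.random.default_rng(3), slope_b=1.4, shift=2.0)
        res = ancova(df, "y", "x", "g")
        total = float(((df["y"] - df["y"].mean()) ** 2).sum())
        assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-10)
        # dfs (including residual) sum to n-1
        assert res.table["df"].sum() == pytest.approx(len(df) - 1)

    def test_slope_difference_detected_as_interaction(self):
        df = self.make_table(np.random.default_rng(4), slope_b=3.0, noise=0.5)
        res = ancova(df, "y", "x", "g")
        assert res.conclusion == "slopes differ"
        assert res.interaction_p < 0.05

    def test_intercept_shift_detected_without_interaction(self):
        df = self.make_table(np.random.default_rng(5), slope_b=1.0, shift=5.0, noise=1.0)
        res = ancova(df, "y", "x", "g")
        assert res.conclusion == "intercepts differ"
        assert res.interaction_p > 0.05
        assert res.factor_p_additive < 0.05

    def test_model_comparison_equals_interaction_test_for_two_levels(self):
        df = self.make_table(np.random.default_rng(6), slope_b=1.5, shift=1.0)
        res = ancova(df, "y", "x", "g")
        # with one interaction df, the full-vs-additive F-test IS the
        # sequential interaction test
        assert res.comparison_p == pytest.approx(res.interaction_p, rel=1e-8)

    def test_single_level_rejected(self):
        df = self.make_table()
        df["g"] = "a"
        with pytest.raises(ValueError, match="single level"):
            ancova(df, "y", "x", "g")

    def test_tiny_level_rejected(self):
        df = self.make_table()
        df = pd.concat([df[df.g == "a"], df[df.g == "b"].head(2)])
        with pytest.raises(ValueError, match="fewer than 3"):
            ancova(df, "y", "x", "g")

    def test_constant_covariate_within_level_rejected(self):
        df = self.make_table()
        df.loc[df.g == "b", "x"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            ancova(df, "y", "x", "g")
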