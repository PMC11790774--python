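"""Group statistics, regression and ROC machinery."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cardiodti as cd
from cardiodti.stats import CohortModel, SampleSizeError


class TestShapiroWilk:
    def test_sample_size_bounds(self):
        with pytest.raises(SampleSizeError):
            cd.shapiro_wilk([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            cd.shapiro_wilk([2.0] * 10)

    def test_null_calibration(self):
        """Normal samples are rejected at ~5%; tolerance 3 binomial SE."""
        rng = np.random.default_rng(11)
        n_rep = 200
        rej = sum(cd.shapiro_wilk(rng.normal(size=50))[1] < 0.05 for _ in range(n_rep))
        assert rej / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_power_against_exponential(self):
        rng = np.random.default_rng(12)
        rej = sum(cd.shapiro_wilk(rng.exponential(size=50))[1] < 0.05 for _ in range(100))
        assert rej / 100 > 0.5


class TestUnpairedT:
    def test_identical_groups(self):
        t, df, p = cd.unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_frozen_closed_form_example(self):
        """t = -sqrt(3/2), df = 4 for {1,2,3} vs {2,3,4} (hand-computed)."""
        t, df, p = cd.unpaired_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-np.sqrt(1.5), abs=1e-12)
        assert df == 4
        assert p == pytest.approx(0.28786, abs=5e-5)

    def test_zero_variance_unequal_means(self):
        t, _, p = cd.unpaired_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 2.5, 3.0, 4.2])
        y = np.array([2.0, 3.1, 5.0])
        t0, _, p0 = cd.unpaired_t(x, y)
        t1, _, p1 = cd.unpaired_t(a * x + b, a * y + b)
        assert abs(t1) == pytest.approx(abs(t0), rel=1e-9)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_type_one_error_calibrated(self):
        """Null rejection rate 5% +/- 2 pp over 2000 simulations."""
        rng = np.random.default_rng(2024)
        rej = 0
        n_sim = 2000
        for _ in range(n_sim):
            if cd.unpaired_t(rng.normal(size=8), rng.normal(size=7))[2] < 0.05:
                rej += 1
        assert abs(rej / n_sim - 0.05) < 0.02


class TestRegression:
    def test_exact_line(self):
        reg = cd.linear_regression_ci([0, 1, 2, 3], [1, 3, 5, 7])
        assert reg.slope == pytest.approx(2.0, abs=1e-12)
        assert reg.intercept == pytest.approx(1.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)
        assert reg.slope_ci[1] - reg.slope_ci[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 12)
        y = 1.7 * x - 0.4 + rng.normal(0, 0.5, 12)
        reg = cd.linear_regression_ci(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg.intercept == pytest.approx(beta[0], abs=1e-10)
        assert reg.slope == pytest.approx(beta[1], abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 5, 15)
        y = 2 * x + rng.normal(size=15)
        perm = rng.permutation(15)
        a = cd.linear_regression_ci(x, y)
        b = cd.linear_regression_ci(x[perm], y[perm])
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            cd.linear_regression_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_slope_recovery_unbiased(self):
        """Mean slope estimate over 500 noisy draws within 2 SE of truth."""
        rng = np.random.default_rng(99)
        x = np.linspace(0, 1, 15)
        slopes = []
        for _ in range(500):
            y = 1.0 + 2.0 * x + rng.normal(0, 0.5, x.size)
            slopes.append(cd.linear_regression_ci(x, y).slope)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 2.0) < 2 * se

    def test_prediction_band_contains_fit(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 20)
        y = 0.5 * x + rng.normal(size=20)
        reg = cd.linear_regression_ci(x, y)
        yhat, lo, hi = reg.prediction_band(np.linspace(0, 10, 5))
        assert (lo <= yhat).all() and (yhat <= hi).all()


class TestROC:
    def test_pairwise_count_example(self):
        r = cd.roc_analysis([3, 5, 7], [1, 2, 6])
        assert r.auc == pytest.approx(7 / 9, abs=1e-12)

    def test_label_swap_symmetry(self):
        a = cd.roc_analysis([3, 5, 7], [1, 2, 6]).auc
        b = cd.roc_analysis([1, 2, 6], [3, 5, 7]).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_complete_separation(self):
        r = cd.roc_analysis([10, 11, 12], [1, 2, 3])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_all_tied_scores(self):
        r = cd.roc_analysis([1.0, 1.0], [1.0, 1.0])
        assert r.auc == 0.5 and r.cutoff is None

    def test_lower_direction(self):
        hi = cd.roc_analysis([3, 5, 7], [1, 2, 6], positive_direction="higher")
        lo = cd.roc_analysis([-3, -5, -7], [-1, -2, -6], positive_direction="lower")
        assert lo.auc == pytest.approx(hi.auc, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 20, 2)
        pos = rng.integers(0, 10, m).astype(float)
        neg = rng.integers(0, 10, n).astype(float)
        auc = cd.roc_analysis(pos, neg).auc
        brute = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg) / (m * n)
        assert auc == brute

    def test_delong_ci_coverage(self):
        """95% DeLong interval covers the true AUC in >= 90% of cohorts."""
        from scipy.stats import norm

        mu = 1.0
        true_auc = norm.cdf(mu / np.sqrt(2.0))
        rng = np.random.default_rng(42)
        n_sim = 300
        cover = 0
        for _ in range(n_sim):
            r = cd.roc_analysis(rng.normal(mu, 1, 15), rng.normal(0, 1, 15))
            cover += r.auc_ci[0] <= true_auc <= r.auc_ci[1]
        assert cover / n_sim >= 0.90

    def test_youden_cutoff_example(self):
        r = cd.roc_analysis([3, 5, 7], [1, 2, 6])
        # J is maximized at threshold 3: sens 1, spec 2/3
        assert r.cutoff == 3.0
        assert r.sensitivity == pytest.approx(1.0)
        assert r.specificity == pytest.approx(2 / 3)


class TestCohortModel:
    @staticmethod
    def _toy_frame(delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, off in (("control", 0.0), ("disease", delta)):
            for _ in range(6):
                rows.append(
                    {
                        "group": g,
                        "fa": 0.15 + off + 0.01 * rng.standard_normal(),
                        "c_planar": 0.08 + off / 2 + 0.005 * rng.standard_normal(),
                        "lv_mass_index": 2.0 - off + 0.05 * rng.standard_normal(),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_are_null(self):
        df = self._toy_frame(delta=0.0, seed=3)
        # make groups literally identical
        df.loc[df.group == "disease", ["fa", "c_planar", "lv_mass_index"]] = df.loc[
            df.group == "control", ["fa", "c_planar", "lv_mass_index"]
        ].to_numpy()
        res = CohortModel(df).fit(roc_metrics=("fa",), regressions=())
        row = res.group_table.set_index("metric").loc["fa"]
        assert row["t"] == 0.0 and row["p_value"] == 1.0
        assert res.roc["fa"].auc == pytest.approx(0.5, abs=1e-12)

    def test_report_json_round_trip(self, tmp_path):
        res = CohortModel(self._toy_frame(delta=0.1, seed=4)).fit(
            roc_metrics=("fa", "c_planar"),
            regressions=(("lv_mass_index", "c_planar"),),
        )
        path = tmp_path / "report.json"
        res.to_json(path)
        loaded = cd.CohortResults.read_json(path)
        assert loaded == json.loads(json.dumps(res.to_dict()))
        assert loaded["roc"]["fa"]["auc"] == res.roc["fa"].auc

    def test_missing_metric_excluded_pairwise(self):
        df = self._toy_frame(delta=0.1, seed=5)
        df.loc[0, "fa"] = np.nan
        res = CohortModel(df).fit(roc_metrics=("fa",), regressions=())
        row = res.group_table.set_index("metric").loc["fa"]
        assert row["n_control"] == 5 and row["n_disease"] == 6
        assert res.excluded and res.excluded[0]["metric"] == "fa"

    def test_small_group_rejected(self):
        df = self._toy_frame().iloc[[0, 1, 2, 6]]  # one disease subject only
        with pytest.raises(SampleSizeError):
            CohortModel(df.reset_index(drop=True))
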