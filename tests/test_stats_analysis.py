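"""Binning, rank tests, BH correction, robust fits, fold change, VIF, f²."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fnirsinc import stats_analysis as sa


def permutation_mw_p(g1, g2):
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments (symmetric-tail definition; valid for tie-free data)."""
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    mu = n1 * len(g2) / 2.0

    def u_stat(idx):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

    u_obs = u_stat(range(n1))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestEqualWidthBins:
    @pytest.mark.parametrize("value,expected", [(0.5, 1), (4.0, 4), (1.0, 2)])
    def test_half_open_convention(self, value, expected):
        x = np.array([0.0, value, 4.0])
        assert sa.equal_width_bins(x)[1] == expected

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sa.equal_width_bins(np.ones(5))

    def test_partition(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-3, 7, 500)
        ids = sa.equal_width_bins(x, k=4)
        assert set(ids) <= {1, 2, 3, 4}
        assert len(ids) == 500


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        y = np.concatenate([np.arange(8.0), np.arange(8.0)])
        bins = np.array([1] * 8 + [4] * 8)
        # full ties: asymptotic path
        res = sa.mann_whitney_first_last(y, bins)
        assert res["p"] == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_exact_p(self):
        y = np.concatenate([np.arange(10.0), np.arange(100.0, 110.0)])
        bins = np.array([1] * 10 + [4] * 10)
        res = sa.mann_whitney_first_last(y, bins)
        assert res["method"] == "exact"
        assert res["U"] in (0.0, 100.0)
        assert res["p"] == pytest.approx(1.083e-5, rel=1e-3)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 4), (8, 8)])
    def test_matches_permutation_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            vals = rng.permutation(np.arange(n1 + n2, dtype=float))
            y = vals
            bins = np.array([1] * n1 + [4] * n2)
            res = sa.mann_whitney_first_last(y, bins)
            assert res["p"] == pytest.approx(
                permutation_mw_p(y[:n1], y[n1:]), abs=1e-12)


class TestBhAdjust:
    def test_hand_step_up_example(self):
        adj = sa.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert sa.bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(sa.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_not_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 40)
        adj = sa.bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            sa.bh_adjust([0.5, 1.5])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert sa.spearman(x, np.exp(x))["rho"] == pytest.approx(1.0)
        assert sa.spearman(x, -x ** 3)["rho"] == pytest.approx(-1.0)

    def test_hand_rank_case(self):
        # sum of squared rank differences is 4: rho = 1 - 6*4/(5*24) = 0.8
        res = sa.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res["rho"] == pytest.approx(0.8)

    def test_constant_flagged(self):
        assert np.isnan(sa.spearman([1, 1, 1, 1], [1, 2, 3, 4])["rho"])


class TestRobustLinfit:
    def test_exact_line(self):
        x = np.linspace(0, 5, 20)
        fit = sa.robust_linfit(x, 2 * x + 1)
        assert fit["slope"] == pytest.approx(2.0, abs=1e-8)
        assert fit["intercept"] == pytest.approx(1.0, abs=1e-8)

    def test_resists_gross_outlier_where_ols_fails(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 20)
        y = 2 * x + 1 + 0.01 * rng.standard_normal(20)
        y[7] = 300.0
        fit = sa.robust_linfit(x, y)
        assert fit["slope"] == pytest.approx(2.0, abs=0.05)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(ols_slope - 2.0) > 0.05   # the outlier breaks plain OLS

    def test_constant_response(self):
        fit = sa.robust_linfit(np.arange(10.0), np.full(10, 3.3))
        assert fit["slope"] == pytest.approx(0.0, abs=1e-10)


class TestFoldChange:
    def test_sign_rule_simple_cases(self):
        # log10 fit predicting 0 -> L=1 at x=0; slope 1 per unit
        x = np.array([0.0] * 50 + [1.0] * 50)
        up = sa.fold_change({"slope": 1.0, "intercept": 0.0}, x)
        assert up.fold_change == pytest.approx(10.0)
        down = sa.fold_change({"slope": -1.0, "intercept": 1.0}, x)
        assert down.fold_change == pytest.approx(-10.0)
        assert down.L == pytest.approx(10.0)
        assert down.U == pytest.approx(1.0)

    def test_observed_coefficient_case(self):
        # shallow negative slope over a wide pigment-like range
        x = np.array([5.0] * 50 + [85.0] * 50)
        res = sa.fold_change({"slope": -0.010, "intercept": 0.86}, x)
        assert res.L == pytest.approx(10 ** 0.81, rel=1e-6)
        assert res.U == pytest.approx(10 ** 0.01, rel=1e-6)
        assert res.fold_change == pytest.approx(-6.31, abs=0.005)

    def test_magnitude_at_least_one_and_sign_matches_direction(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            fit = {"slope": rng.normal(), "intercept": rng.normal()}
            x = rng.normal(size=30)
            res = sa.fold_change(fit, x)
            assert abs(res.fold_change) >= 1.0
            assert np.sign(res.fold_change) == (1 if res.U >= res.L else -1)


class TestMulticollinearityScreen:
    @staticmethod
    def _frame(corr_ab=0.9, n=400, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n)
        b = corr_ab * a + np.sqrt(1 - corr_ab ** 2) * rng.standard_normal(n)
        c = rng.standard_normal(n)
        return pd.DataFrame({"a": a, "b": b, "c": c})

    def test_keeps_priority_member(self):
        X = self._frame()
        kept = sa.multicollinearity_screen(X[["a", "b"]], priority=["a", "b"])
        assert kept == ["a"]

    def test_orthogonal_kept(self):
        X = self._frame(corr_ab=0.1)
        assert sa.multicollinearity_screen(X) == ["a", "b", "c"]

    def test_chain_resolution(self):
        # a~b 0.8, b~c 0.6, a~c 0.3: dropping b breaks the chain, c stays
        rng = np.random.default_rng(4)
        n = 2000
        a = rng.standard_normal(n)
        u = rng.standard_normal(n)
        w = rng.standard_normal(n)
        b = 0.8 * a + 0.6 * u
        c = 0.3 * a + 0.6 * u + np.sqrt(1 - 0.09 - 0.36) * w
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        assert abs(X.corr().loc["a", "c"]) < 0.5 < X.corr().loc["a", "b"]
        kept = sa.multicollinearity_screen(X, priority=["a", "b", "c"])
        assert kept == ["a", "c"]


class TestVif:
    def test_orthogonal_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        assert np.allclose(sa.vif(X), 1.0)

    def test_closed_form_at_r_08(self):
        a = np.array([1.0, 1.0, -1.0, -1.0])
        z = np.array([1.0, -1.0, 1.0, -1.0])
        b = 0.8 * a + 0.6 * z          # corr(a, b) = 0.8 exactly
        X = pd.DataFrame({"a": a, "b": b})
        assert sa.vif(X)["a"] == pytest.approx(1 / (1 - 0.64), abs=1e-9)

    def test_duplicate_predictor_infinite(self):
        a = np.random.default_rng(0).standard_normal(20)
        X = pd.DataFrame({"a": a, "b": a})
        assert np.isinf(sa.vif(X)["a"])


class TestRobustMultipleRegression:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = 1.5 * X["a"] - 2.0 * X["b"] + 0.0 * X["c"] + 4.0
        rep = sa.robust_multiple_regression(X, y)
        assert rep.table.loc["a", "estimate"] == pytest.approx(1.5, abs=1e-8)
        assert rep.table.loc["b", "estimate"] == pytest.approx(-2.0, abs=1e-8)
        assert rep.table.loc["a", "p"] < 1e-12

    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(6)
        beta = np.array([1.0, -0.5, 0.3])
        errs = []
        for _ in range(40):
            X = pd.DataFrame(rng.standard_normal((115, 3)),
                             columns=list("abc"))
            y = X.to_numpy() @ beta + rng.standard_normal(115) * 0.5
            rep = sa.robust_multiple_regression(X, y, compute_f2=False)
            errs.append(rep.table["estimate"].to_numpy() - beta)
        bias = np.abs(np.mean(errs, axis=0))
        assert np.all(bias < 0.05 * np.abs(beta))

    def test_report_invariants(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.standard_normal(80)
        rep = sa.robust_multiple_regression(X, y)
        assert np.all(rep.table["vif"] >= 1.0)
        assert np.all(rep.table["f2"] >= 0.0)
        assert np.all(rep.table["se"] > 0.0)
        assert rep.effect_band("a") in ("small", "medium", "large")

    def test_rank_deficiency_rejected(self):
        a = np.random.default_rng(8).standard_normal(30)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError):
            sa.robust_multiple_regression(X, a)


class TestCohensF2:
    def test_single_predictor_closed_form(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        f2 = sa.cohens_f2(X, np.arange(10.0), "a", r2_full=0.5)
        assert f2 == pytest.approx(1.0)

    def test_null_predictor_near_zero(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((400, 2)), columns=["a", "b"])
        y = 2.0 * X["a"].to_numpy() + 0.3 * rng.standard_normal(400)
        assert sa.cohens_f2(X, y, "b") < 0.02
        assert sa.cohens_f2(X, y, "a") > 0.35
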