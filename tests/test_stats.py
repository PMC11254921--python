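"""Transforms, VIF, mixed models, bootstrap CIs, rank tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

import herbflux.stats as st


class TestTransform:
    def test_none_identity(self):
        np.testing.assert_array_equal(st.transform([1.0, 2.0], "none"), [1.0, 2.0])

    def test_logit_midpoint(self):
        assert st.transform([0.5], "logit")[0] == pytest.approx(0.0)

    def test_log_closed_form(self):
        np.testing.assert_allclose(
            st.transform([1.0, np.e, np.e ** 2], "log"), [0.0, 1.0, 2.0])

    def test_log_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            st.transform([1.0, 0.0], "log")

    def test_logit_shifts_boundaries_with_warning(self):
        with pytest.warns(UserWarning, match="eps"):
            out = st.transform([0.0, 0.5, 1.0], "logit")
        assert np.isfinite(out).all()


class TestZscore:
    def test_closed_form(self):
        np.testing.assert_allclose(st.zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(7)
        z = st.zscore(rng.normal(5, 3, 100))
        assert abs(z.mean()) < 1e-12
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        x = np.array([0.3, 1.7, 2.2, 5.0])
        np.testing.assert_allclose(st.zscore(3.0 * x + 7.0), st.zscore(x))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            st.zscore([2.0, 2.0, 2.0])


class TestVif:
    def test_orthogonal_predictors(self):
        x = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        np.testing.assert_allclose(st.vif(x), [1.0, 1.0])

    def test_duplicated_predictor_is_infinite(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4],
                          "c": [0.0, 1, 0, 1]})
        assert np.isinf(st.vif(x)["a"])
        with pytest.raises(st.CollinearityError):
            st.screen_collinearity(x)

    def test_known_correlation_closed_form(self):
        # predictors with sample correlation exactly 0.6 -> VIF 1/(1-0.36)
        z = st.zscore([1.0, 2, 3, 4, 5])
        w = st.zscore([1.0, -1, 0, 1, -1])
        w = st.zscore(w - np.dot(w, z) / np.dot(z, z) * z)  # orthogonalize
        x = pd.DataFrame({"a": z, "b": 0.6 * z + np.sqrt(1 - 0.36) * w})
        np.testing.assert_allclose(st.vif(x), [1.5625, 1.5625], rtol=1e-9)


class TestProfileREML:
    def test_matches_statsmodels_mixedlm(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n_g = int(rng.integers(12, 30))
            reps = rng.integers(1, 4, n_g)
            codes = np.repeat(np.arange(n_g), reps)
            n = len(codes)
            x = rng.normal(size=n)
            y = (0.3 + 0.6 * x + rng.normal(0, 0.7, n_g)[codes]
                 + rng.normal(0, 0.8, n))
            X = np.column_stack([np.ones(n), x])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = sm.MixedLM(y, X, groups=codes).fit(reml=True)
            beta, vu, ve = st.profile_reml_intercept(y, X, codes)
            np.testing.assert_allclose(beta, ref.fe_params, atol=1e-4)
            assert vu == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-3)
            assert ve == pytest.approx(float(ref.scale), abs=1e-3)


class TestFitLmm:
    def test_noiseless_slope_one(self):
        x = st.zscore(np.arange(12, dtype=float))
        table = pd.DataFrame({"y": x, "x": x,
                              "site_id": np.repeat(list("abcd"), 3)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = st.fit_lmm(table, "y", ["x"])
        assert fit.params[1] == pytest.approx(1.0, abs=1e-6)
        assert fit.resid_var < 1e-8

    def test_simulation_recovery_within_3_se(self):
        rng = np.random.default_rng(11)
        n_g, reps, slope = 50, 2, 0.6
        codes = np.repeat(np.arange(n_g), reps)
        x = st.zscore(rng.normal(size=n_g * reps))
        y = (slope * x + rng.normal(0, 0.5, n_g)[codes]
             + rng.normal(0, 0.5, n_g * reps))
        table = pd.DataFrame({"y": y, "x": x, "site_id": codes})
        fit = st.fit_lmm(table, "y", ["x"])
        se = float(np.asarray(fit.result.bse_fe)[1])
        assert abs(fit.params[1] - slope) < 3 * se


class TestR2:
    def test_closed_form_components(self):
        assert st.r2_components(1.0, 1.0, 2.0) == pytest.approx((0.25, 0.50))

    def test_zero_group_variance_makes_marginal_equal_conditional(self):
        r2m, r2c = st.r2_components(0.7, 0.0, 0.3)
        assert r2m == r2c

    def test_intercept_only_marginal_zero(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"y": rng.normal(size=30),
                              "site_id": np.repeat(np.arange(10), 3)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = st.fit_lmm(table, "y", [])
        r2m, r2c = st.r2_glmm(fit)
        assert r2m == 0.0
        assert 0.0 <= r2c <= 1.0

    def test_sum_rule_against_fitted_components(self):
        rng = np.random.default_rng(9)
        codes = np.repeat(np.arange(25), 3)
        x = st.zscore(rng.normal(size=75))
        y = 0.5 * x + rng.normal(0, 0.6, 25)[codes] + rng.normal(0, 0.7, 75)
        table = pd.DataFrame({"y": st.zscore(y), "x": x, "site_id": codes})
        fit = st.fit_lmm(table, "y", ["x"])
        r2m, r2c = st.r2_glmm(fit)
        eta = fit.exog[:, 1:] @ fit.params[1:]
        total = np.var(eta, ddof=1) + fit.re_var + fit.resid_var
        assert r2c - r2m == pytest.approx(fit.re_var / total, rel=1e-9)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        res = st.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.chi_square == pytest.approx(7.2)
        assert res.df == 2

    def test_all_identical_values(self):
        res = st.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.chi_square == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            groups = [rng.integers(0, 6, size=rng.integers(2, 12)).astype(float)
                      for _ in range(rng.integers(2, 5))]
            if all((g == groups[0][0]).all() for g in groups):
                continue
            mine = st.kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert mine.chi_square == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_rank_invariance_under_monotone_transform(self):
        groups = [[0.1, 0.7, 0.3], [0.5, 0.9], [0.2, 0.8, 0.6]]
        a = st.kruskal_wallis(groups).chi_square
        b = st.kruskal_wallis([[np.exp(5 * v) for v in g] for g in groups]).chi_square
        assert a == pytest.approx(b, rel=1e-12)

    def test_two_groups_match_squared_ranksum_z(self):
        rng = np.random.default_rng(5)
        x = rng.permutation(np.arange(20.0))
        groups = [x[:8], x[8:]]
        h, _ = st.kruskal_h(groups)
        z = sps.ranksums(groups[0], groups[1]).statistic
        assert h == pytest.approx(z ** 2, rel=1e-9)


class TestDunn:
    def test_identical_groups_all_adjusted_p_one(self):
        out = st.dunn_posthoc([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])
        assert (out["p_adjusted"] == 1.0).all()

    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 15), rng.normal(10, 1, 15),
                  rng.normal(20, 1, 15)]
        out = st.dunn_posthoc(groups)
        assert (out["p_adjusted"] < 0.05).all()

    def test_adjustment_monotone(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(0, 1, 8), rng.normal(0.5, 1, 8), rng.normal(1, 1, 8)]
        for method in ("holm", "bonferroni"):
            out = st.dunn_posthoc(groups, adjustment=method)
            assert (out["p_adjusted"] >= out["p_raw"] - 1e-15).all()

    def test_compact_letters_separate_distinct_groups(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 15), rng.normal(10, 1, 15),
                  rng.normal(20, 1, 15)]
        labels = ["low", "mid", "high"]
        letters = st.compact_letters(
            labels, st.dunn_posthoc(groups, labels=labels))
        assert len({letters[l] for l in labels}) == 3


class TestBootstrap:
    def _table(self, slope=0.8, seed=4, n_g=30):
        rng = np.random.default_rng(seed)
        codes = np.repeat(np.arange(n_g), 2)
        x = st.zscore(rng.normal(size=2 * n_g))
        y = (slope * x + rng.normal(0, 0.4, n_g)[codes]
             + rng.normal(0, 0.5, 2 * n_g))
        return pd.DataFrame({"y": st.zscore(y), "x": x, "site_id": codes})

    def test_deterministic_under_seed(self):
        fit = st.fit_lmm(self._table(), "y", ["x"])
        a = st.bootstrap_ci(fit, n_sim=50, seed=99)
        b = st.bootstrap_ci(fit, n_sim=50, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_strong_effect_excludes_zero(self):
        fit = st.fit_lmm(self._table(slope=0.8), "y", ["x"])
        ci = st.bootstrap_ci(fit, n_sim=200, seed=17)
        row = ci[ci["predictor"] == "x"].iloc[0]
        assert row["ci_low"] > 0
        assert bool(row["significant"])


def test_standardized_lmm_rejects_duplicated_predictor():
    rng = np.random.default_rng(0)
    table = pd.DataFrame({
        "y": rng.normal(size=30) + 2.0,
        "a": rng.normal(size=30),
        "site_id": np.repeat(np.arange(10), 3),
    })
    table["b"] = table["a"]
    with pytest.raises(st.CollinearityError):
        st.fit_standardized_lmm(table, "y", ["a", "b"], bootstrap_n=10,
                                transforms={"y": "none"})
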