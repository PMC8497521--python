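"""Statistical kernel: OLS, ANOVA, REML, Wilson interval, LOESS."""

import numpy as np
import pytest
from scipy import stats as sps

from plasmidquant import stats


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

class TestOLS:
    def test_exact_linear_data_gives_exact_coefficients(self, rng):
        x = rng.normal(size=30)
        y = 2.0 + 3.0 * x
        fit = stats.ols(y, np.column_stack([np.ones_like(x), x]))
        assert np.allclose(fit.coef, [2.0, 3.0], atol=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_model_estimates_the_mean(self, rng):
        y = rng.normal(5.0, 1.0, size=40)
        fit = stats.ols(y, np.ones((40, 1)))
        assert fit.coef[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_normal_equations_at_extended_precision(self, rng):
        """Independent oracle: solve X'X b = X'y in float128."""
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        fit = stats.ols(y, X)
        Xl = X.astype(np.longdouble)
        yl = y.astype(np.longdouble)
        beta = np.linalg.solve((Xl.T @ Xl).astype(float),
                               (Xl.T @ yl).astype(float))
        assert np.allclose(fit.coef, beta, rtol=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        fit = stats.ols(y, sm.add_constant(X))
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.coef, ref.params)
        assert np.allclose(fit.se, ref.bse)

    def test_rank_deficiency_names_offending_column(self):
        X = np.column_stack([np.ones(10), np.arange(10), 2 * np.arange(10)])
        with pytest.raises(ValueError, match="rank deficient"):
            stats.ols(np.arange(10.0), X, names=["c", "x", "x2"])

    def test_affine_rescaling_of_predictor_rescales_coefficient(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        X1 = np.column_stack([np.ones_like(x), x])
        X2 = np.column_stack([np.ones_like(x), 10.0 * x])
        f1 = stats.ols(y, X1)
        f2 = stats.ols(y, X2)
        assert f2.coef[1] == pytest.approx(f1.coef[1] / 10.0)


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

def _hand_balanced_anova(y, a, b):
    """Textbook sums-of-squares decomposition for a balanced design."""
    y = np.asarray(y, dtype=float)
    gm = y.mean()
    ss_a = sum((y[a == lv].mean() - gm) ** 2 * (a == lv).sum()
               for lv in np.unique(a))
    ss_b = sum((y[b == lv].mean() - gm) ** 2 * (b == lv).sum()
               for lv in np.unique(b))
    return ss_a, ss_b


class TestTwoWayAnova:
    def test_all_values_equal_gives_f_zero_p_one(self):
        y = np.full(8, 3.0)
        a = np.repeat(["x", "y"], 4)
        b = np.tile(["u", "v"], 4)
        tab = stats.two_way_anova(y, a, b)
        for _, row in tab[tab["factor"] != "residual"].iterrows():
            assert row["F"] == 0.0
            assert row["p"] == 1.0

    def test_balanced_design_matches_hand_computed_sums_of_squares(self, rng):
        a = np.repeat(["a1", "a2"], 8)
        b = np.tile(np.repeat(["b1", "b2"], 4), 2)
        y = (1.0 * (a == "a2") + 0.5 * (b == "b2")
             + rng.normal(0, 0.3, size=16))
        tab = stats.two_way_anova(y, a, b, names=("A", "B"))
        ss_a, ss_b = _hand_balanced_anova(y, a, b)
        assert tab.loc[tab["factor"] == "A", "sum_sq"].iloc[0] == \
            pytest.approx(ss_a, rel=1e-9)
        assert tab.loc[tab["factor"] == "B", "sum_sq"].iloc[0] == \
            pytest.approx(ss_b, rel=1e-9)

    def test_matches_statsmodels_type2_on_unbalanced_data(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols as sm_ols

        n = 23  # deliberately unbalanced
        df = pd.DataFrame({
            "y": rng.normal(size=n),
            "a": rng.choice(["a1", "a2"], size=n),
            "b": rng.choice(["b1", "b2", "b3"], size=n),
        })
        tab = stats.two_way_anova(df["y"], df["a"], df["b"], names=("a", "b"))
        ref = sm.stats.anova_lm(sm_ols("y ~ a + b", data=df).fit(), typ=2)
        for fac in ("a", "b"):
            mine = tab.loc[tab["factor"] == fac].iloc[0]
            theirs = ref.loc[fac]
            assert mine["F"] == pytest.approx(theirs["F"], rel=1e-8)
            assert mine["p"] == pytest.approx(theirs["PR(>F)"], rel=1e-8)

    def test_single_level_factor_degrades_to_one_way(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 1.5, 2.5])
        a = np.array(["g1", "g1", "g2", "g2", "g1", "g2"])
        b = np.array(["only"] * 6)
        tab = stats.two_way_anova(y, a, b, names=("A", "B"))
        assert np.isnan(tab.loc[tab["factor"] == "B", "F"].iloc[0])
        f_a = tab.loc[tab["factor"] == "A", "F"].iloc[0]
        ref = sps.f_oneway(y[a == "g1"], y[a == "g2"])
        assert f_a == pytest.approx(ref.statistic, rel=1e-9)


# ---------------------------------------------------------------------------
# REML random intercept
# ---------------------------------------------------------------------------

class TestREML:
    def test_balanced_oneway_matches_closed_form_moments(self, rng):
        """Balanced one-way layout: REML variance components equal the
        classical ANOVA estimators sigma_e^2 = MS_within and
        sigma_b^2 = (MS_between - MS_within) / m."""
        k, m = 12, 6
        sigma_b, sigma_e = 0.8, 0.5
        groups = np.repeat(np.arange(k), m)
        y = (np.repeat(rng.normal(0, sigma_b, k), m)
             + rng.normal(0, sigma_e, k * m))
        X = np.ones((k * m, 1))
        fit = stats.reml_random_intercept(y, X, groups)
        gmeans = y.reshape(k, m).mean(axis=1)
        ms_within = ((y.reshape(k, m) - gmeans[:, None]) ** 2).sum() \
            / (k * (m - 1))
        ms_between = m * ((gmeans - gmeans.mean()) ** 2).sum() / (k - 1)
        assert fit.sigma_e2 == pytest.approx(ms_within, rel=1e-5)
        assert fit.sigma_b2 == pytest.approx(
            (ms_between - ms_within) / m, rel=1e-4)

    def test_no_between_group_variance_collapses_to_ols(self, rng):
        y = rng.normal(size=40)  # iid: no group structure
        groups = np.repeat(np.arange(8), 5)
        rng.shuffle(groups)
        X = np.ones((40, 1))
        fit = stats.reml_random_intercept(y, X, groups)
        ref = stats.ols(y, X)
        if fit.sigma_b2 == 0.0:
            assert np.allclose(fit.coef, ref.coef)
        else:  # tiny estimated variance: estimates still near OLS
            assert fit.sigma_b2 < 0.2 * fit.sigma_e2
            assert np.allclose(fit.coef, ref.coef, atol=0.1)

    def test_optimum_beats_every_grid_point(self, rng):
        k, m = 8, 5
        groups = np.repeat(np.arange(k), m)
        y = np.repeat(rng.normal(0, 1.0, k), m) + rng.normal(0, 0.7, k * m)
        X = np.column_stack([np.ones(k * m), rng.normal(size=k * m)])
        fit = stats.reml_random_intercept(y, X, groups)
        lam_hat = fit.sigma_b2 / fit.sigma_e2
        best = stats.reml_criterion(y, X, groups, lam_hat)
        for lam in [0.0, 0.01, 0.1, 0.5, 1.0, 2.0, 5.0, 20.0]:
            assert best <= stats.reml_criterion(y, X, groups, lam) + 1e-6

    def test_matches_statsmodels_mixedlm(self, rng):
        import pandas as pd
        import statsmodels.formula.api as smf

        k, m = 10, 6
        groups = np.repeat(np.arange(k), m)
        x = rng.normal(size=k * m)
        y = (np.repeat(rng.normal(0, 0.7, k), m) + 0.5 * x
             + rng.normal(0, 0.5, k * m))
        fit = stats.reml_random_intercept(
            y, np.column_stack([np.ones(k * m), x]), groups)
        df = pd.DataFrame({"y": y, "x": x, "g": groups})
        ref = smf.mixedlm("y ~ x", df, groups="g").fit(reml=True)
        assert fit.coef[1] == pytest.approx(ref.params["x"], rel=1e-4)
        # plug-in SEs differ slightly between variance-ratio estimators
        assert fit.se[1] == pytest.approx(ref.bse["x"], rel=2e-2)
        assert fit.sigma_e2 == pytest.approx(ref.scale, rel=1e-2)

    def test_single_group_falls_back_to_ols(self, rng):
        y = rng.normal(size=10)
        fit = stats.reml_random_intercept(y, np.ones((10, 1)),
                                          np.zeros(10, dtype=int))
        assert fit.method == "ols_fallback"
        assert fit.coef[0] == pytest.approx(y.mean())


# ---------------------------------------------------------------------------
# Wilson interval
# ---------------------------------------------------------------------------

class TestWilson:
    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = stats.wilson_interval(0, 20)
        assert lo == 0.0
        assert 0 < hi < 0.25

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = stats.wilson_interval(20, 20)
        assert hi == 1.0
        assert 0.75 < lo < 1.0

    def test_matches_direct_formula_evaluation(self):
        k, n, z = 5, 10, sps.norm.ppf(0.975)
        p = k / n
        center = (p + z ** 2 / (2 * n)) / (1 + z ** 2 / n)
        half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) \
            / (1 + z ** 2 / n)
        lo, hi = stats.wilson_interval(k, n, 0.95)
        assert lo == pytest.approx(center - half, abs=1e-12)
        assert hi == pytest.approx(center + half, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = stats.wilson_interval(7, 30)
        ref = proportion_confint(7, 30, method="wilson")
        assert (lo, hi) == pytest.approx(ref, abs=1e-12)


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

class TestLoess:
    def test_constant_y_reproduced_at_any_span(self, rng):
        x = np.sort(rng.uniform(0, 10, 25))
        y = np.full_like(x, 0.2)
        for span in (0.2, 0.5, 1.0):
            fitted = stats.loess(x, y, span=span)
            assert np.allclose(fitted, 0.2, atol=1e-12)

    def test_exactly_linear_y_recovered_with_full_span(self, rng):
        x = np.sort(rng.uniform(0, 10, 30))
        y = 1.0 + 0.5 * x
        fitted = stats.loess(x, y, span=1.0, degree=1)
        assert np.allclose(fitted, y, atol=1e-9)

    def test_zero_weight_points_are_irrelevant(self, rng):
        x = np.sort(rng.uniform(0, 10, 20))
        y = np.sin(x)
        w = np.ones_like(x)
        w[[3, 11]] = 0.0
        base = stats.loess(x, y, weights=w, span=0.6, xout=x)
        x2, y2 = x.copy(), y.copy()
        x2[[3, 11]] = [99.0, -50.0]  # move them anywhere
        y2[[3, 11]] = [1e6, -1e6]
        moved = stats.loess(x2, y2, weights=w, span=0.6, xout=x)
        assert np.allclose(base, moved, atol=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="too few"):
            stats.loess([0.0, 1.0], [0.0, 1.0], span=0.5)
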