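"""Conditional-survival (MICS) and restricted-mean (MIRM) imputation."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import kstest

import linksurv as ls
from linksurv.cohort import LinkedCohort
from linksurv.estimate import AftFit
from linksurv.impute import RestrictedMeanFit


def _fit(alpha=(4.5, -0.2, -0.2), p=6.0):
    k = len(alpha)
    return AftFit(alpha=np.array(alpha), shape_p=p, vcov=np.zeros((k + 1, k + 1)),
                  loglik=0.0, n_effective=100.0,
                  names=("intercept", "x", "z")[:k])


def _all_matched_cohort(n, seed, alpha=(4.4, -0.2, 0.0), p=6.0, p_match=0.95):
    """Every record an unequivocal match with the exact event age."""
    g = np.random.default_rng(seed)
    x = g.integers(0, 2, n)
    z = g.integers(0, 2, n)
    mu = alpha[0] + alpha[1] * x + alpha[2] * z
    t = np.exp(mu) * g.exponential(size=n) ** (1.0 / p)
    df = pd.DataFrame({"id": np.arange(n), "x": x, "z": z, "w": t / 2,
                       "v": t + 60.0, "r": 1, "p_match": p_match, "t_star": t})
    return LinkedCohort(df)


class TestMicsInvert:
    def test_zero_percentile_returns_census_age(self):
        fit = _fit()
        assert ls.mics_invert(0.0, 60.0, 1, 0, fit) == pytest.approx(60.0)

    def test_against_bisection_of_conditional_cdf(self):
        fit = _fit(alpha=(4.5, -0.2, -0.2), p=6.0)
        w, x, z, q = 60.0, 1, 0, 0.5
        gamma = math.exp(-6.0 * (4.5 - 0.2))
        def cond_cdf(t):
            return 1.0 - math.exp(-gamma * t ** 6) / math.exp(-gamma * w ** 6)
        oracle = brentq(lambda t: cond_cdf(t) - q, w, w + 200, xtol=1e-10)
        assert ls.mics_invert(q, w, x, z, fit) == pytest.approx(oracle, abs=1e-8)

    def test_strictly_increasing_in_q(self):
        fit = _fit()
        qs = np.linspace(0.0, 0.99, 50)
        ts = ls.mics_invert(qs, 55.0, 0, 1, fit)
        assert np.all(np.diff(ts) > 0)

    def test_roundtrip_through_conditional_cdf(self):
        """F(T_imp | survived to w) returns q to 1e-10 over a random grid."""
        g = np.random.default_rng(77)
        for _ in range(200):
            alpha = (g.uniform(3.5, 5.0), g.uniform(-0.5, 0.5), g.uniform(-0.5, 0.5))
            p = g.uniform(2.0, 8.0)
            fit = _fit(alpha, p)
            w = g.uniform(1.0, 90.0)
            x, z = g.integers(0, 2), g.integers(0, 2)
            q = g.uniform(0.0, 0.99)
            t = float(ls.mics_invert(q, w, x, z, fit))
            gamma = math.exp(-p * (alpha[0] + alpha[1] * x + alpha[2] * z))
            back = -np.expm1(-gamma * (t ** p - w ** p))
            assert abs(back - q) < 1e-10

    def test_invalid_percentiles_rejected(self):
        fit = _fit()
        with pytest.raises(ValueError):
            ls.mics_invert(1.0, 60.0, 0, 0, fit)
        with pytest.raises(ValueError):
            ls.mics_invert(0.5, -1.0, 0, 0, fit)


class TestCompleteCaseAft:
    def test_recovers_generative_parameters(self):
        cohort = _all_matched_cohort(20_000, seed=6)
        fit = ls.fit_complete_case_aft(cohort, threshold=0.8)
        for est, true, se in zip(
                list(fit.alpha) + [math.log(fit.shape_p)],
                [4.4, -0.2, 0.0, math.log(6.0)], fit.se):
            assert abs(est - true) < 3 * se

    def test_too_few_unequivocal_matches(self):
        cohort = _all_matched_cohort(10, seed=1)
        with pytest.raises(ValueError, match="unstable|no unequivocal"):
            ls.fit_complete_case_aft(cohort)
        with pytest.raises(ValueError):
            ls.fit_complete_case_aft(_all_matched_cohort(100, 2, p_match=0.5))

    def test_identical_records_degenerate(self):
        df = pd.DataFrame({"id": range(10), "x": 1, "z": 0, "w": 30.0,
                           "v": 80.0, "r": 1, "p_match": 0.9, "t_star": 60.0})
        with pytest.raises(Exception):
            ls.fit_complete_case_aft(LinkedCohort(df), min_rows=5)


def _mixed_cohort(n=400, seed=9):
    c = ls.draw_cohort(ls.load_setting(4, seed=seed, n=n))
    return c


class TestMicsImpute:
    def test_nothing_to_impute_gives_identical_copies(self):
        cohort = _all_matched_cohort(200, seed=3)
        imp = ls.mics_impute(cohort, threshold=0.8, B=4, rng=0)
        assert imp.B == 4 and len(imp.imputed_ids) == 0
        for d in imp.datasets[1:]:
            pd.testing.assert_frame_equal(d, imp.datasets[0])
        assert (imp.datasets[0]["source"] == "unequivocal").all()

    def test_imputed_times_respect_census_and_analysis_ages(self):
        cohort = _mixed_cohort()
        imp = ls.mics_impute(cohort, B=5, rng=2)
        base = cohort.data.set_index("id")
        for d in imp.datasets:
            rows = d[d["source"].isin(["equivocal_imputed", "nonmatch_imputed"])]
            w = base.loc[rows["id"], "w"].to_numpy()
            v = base.loc[rows["id"], "v"].to_numpy()
            assert (rows["time"].to_numpy() >= w - 1e-9).all()
            ev = rows["event"].to_numpy() == 1
            assert np.allclose(rows.loc[~pd.Series(ev, index=rows.index), "time"],
                               v[~ev])
            assert (rows.loc[pd.Series(ev, index=rows.index), "time"]
                    <= v[ev] + 1e-9).all()

    def test_per_record_weight_mass(self):
        cohort = _mixed_cohort()
        imp = ls.mics_impute(cohort, B=3, rng=4)
        d = imp.datasets[0]
        mass = d.groupby("id")["weight"].sum()
        assert np.allclose(mass, 1.0)
        equiv = d[d["source"] == "equivocal_matched"].set_index("id")
        comp = d[d["source"] == "equivocal_imputed"].set_index("id")
        assert np.allclose(equiv["weight"] + comp.loc[equiv.index, "weight"], 1.0)

    def test_threshold_zero_reduces_to_complete_case(self):
        cohort = _all_matched_cohort(150, seed=5, p_match=0.4)
        imp = ls.mics_impute(cohort, threshold=0.0, B=3, rng=1)
        cc = ls.build_analysis_set(cohort, "cc", threshold=0.0)
        for d in imp.datasets:
            np.testing.assert_allclose(d["time"], cc["time"])
            assert (d["weight"] == 1).all()

    def test_unconditional_distribution_at_small_census_age(self):
        """Conditioning on survival to w ~ 0 is vacuous: imputed times follow
        the fitted marginal Weibull."""
        n = 10_000
        df = pd.DataFrame({"id": range(n), "x": 0, "z": 0, "w": 1e-3,
                           "v": 1e6, "r": 0, "p_match": 0.0, "t_star": np.nan})
        cohort = LinkedCohort(df)
        fit = _fit(alpha=(4.4, -0.2, 0.0), p=6.0)
        imp = ls.mics_impute(cohort, B=2, rng=8, proper=False, fit=fit)
        times = imp.datasets[0].query("source == 'nonmatch_imputed'")["time"]
        gamma = math.exp(-6.0 * 4.4)
        res = kstest(times, lambda t: 1 - np.exp(-gamma * np.asarray(t) ** 6.0))
        assert res.pvalue > 0.01

    def test_b_below_two_rejected(self):
        with pytest.raises(ValueError):
            ls.mics_impute(_all_matched_cohort(100, 1), B=1)

    def test_proper_draws_vary_parameters(self):
        cohort = _mixed_cohort()
        imp = ls.mics_impute(cohort, B=4, rng=3, proper=True)
        assert np.ptp(imp.parameter_draws, axis=0).max() > 0
        imp2 = ls.mics_impute(cohort, B=4, rng=3, proper=False)
        assert np.ptp(imp2.parameter_draws, axis=0).max() == 0


class TestRestrictedMean:
    def test_inactive_restriction_equals_plain_ols(self):
        cohort = _all_matched_cohort(500, seed=10)
        fit = ls.fit_restricted_mean(cohort, tau=1e9)
        sub = cohort.matched(0.8)
        A = sm.add_constant(sub[["x", "z"]].to_numpy(float))
        ref = sm.OLS(np.log(sub["t_star"]), A).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.coef_cov, ref.cov_params(), rtol=1e-6)

    def test_restriction_shrinks_the_intercept(self):
        cohort = _all_matched_cohort(20_000, seed=12)
        unrestricted = ls.fit_restricted_mean(cohort, tau=1e9)
        restricted = ls.fit_restricted_mean(cohort, tau=80.0)
        assert restricted.coef[0] < unrestricted.coef[0]

    def test_degenerate_constant_times(self):
        df = pd.DataFrame({"id": range(20), "x": [0, 1] * 10, "z": [0, 0, 1, 1] * 5,
                           "w": 30.0, "v": 80.0, "r": 1, "p_match": 0.9,
                           "t_star": 60.0})
        fit = ls.fit_restricted_mean(LinkedCohort(df), tau=100.0)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(fit.coef, [math.log(60.0), 0.0, 0.0],
                                   atol=1e-10)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            ls.fit_restricted_mean(_all_matched_cohort(100, 1), tau=0.0)


class TestMirmImpute:
    def test_noise_free_limit_is_deterministic(self):
        cohort = _mixed_cohort()
        coef = np.array([4.2, -0.1, 0.05])
        fit = RestrictedMeanFit(coef=coef, resid_var=0.0,
                                coef_cov=np.zeros((3, 3)), tau=80.0,
                                names=("intercept", "x", "z"), n=100)
        imp = ls.mirm_impute(cohort, fit, B=3, rng=1)
        first = imp.datasets[0]
        for d in imp.datasets[1:]:
            pd.testing.assert_frame_equal(d, first)
        rows = first[first["source"] == "nonmatch_imputed"].set_index("id")
        base = cohort.data.set_index("id")
        pred = np.minimum(
            np.exp(coef[0] + coef[1] * rows["x"] + coef[2] * rows["z"]), 80.0)
        ev = rows["event"] == 1
        np.testing.assert_allclose(rows.loc[ev, "time"], pred[ev])
        np.testing.assert_allclose(rows.loc[~ev, "time"],
                                   base.loc[rows.index[~ev], "v"])

    def test_no_imputed_event_time_exceeds_tau(self):
        cohort = _mixed_cohort()
        fit = ls.fit_restricted_mean(cohort, tau=80.0)
        imp = ls.mirm_impute(cohort, fit, B=5, rng=2)
        for d in imp.datasets:
            rows = d[d["source"].isin(["equivocal_imputed", "nonmatch_imputed"])]
            assert (rows.loc[rows["event"] == 1, "time"] <= 80.0 + 1e-9).all()

    def test_mean_of_imputed_log_times_matches_linear_predictor(self):
        n = 200
        df = pd.DataFrame({"id": range(n), "x": 1, "z": 0, "w": 30.0,
                           "v": 1e6, "r": 0, "p_match": 0.0, "t_star": np.nan})
        # one matched record so x varies? not needed: imputation only
        cohort = LinkedCohort(df)
        coef = np.array([4.0, -0.2, 0.0])
        cov = 0.0004 * np.eye(3)
        s2 = 0.04
        fit = RestrictedMeanFit(coef=coef, resid_var=s2, coef_cov=cov,
                                tau=1e9, names=("intercept", "x", "z"), n=999)
        B = 200
        imp = ls.mirm_impute(cohort, fit, B=B, rng=5)
        logs = np.concatenate(
            [np.log(d.query("source == 'nonmatch_imputed'")["time"]) for d in imp.datasets])
        pred = coef[0] + coef[1]
        var_per_draw = s2 + cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]
        se = math.sqrt(var_per_draw / (B * n))
        # coefficient draws are shared within an imputation -> inflate se
        se_cluster = math.sqrt(s2 / (B * n) + (cov[0, 0] + cov[1, 1]) / B)
        assert abs(logs.mean() - pred) < 3 * max(se, se_cluster)

    def test_b_below_two_rejected(self):
        fit = RestrictedMeanFit(coef=np.zeros(3), resid_var=0.1,
                                coef_cov=np.eye(3), tau=80.0,
                                names=("intercept", "x", "z"), n=10)
        with pytest.raises(ValueError):
            ls.mirm_impute(_mixed_cohort(), fit, B=1)


@pytest.mark.parametrize("formula,cols", [("x+z", ("intercept", "x", "z")),
                                          ("x", ("intercept", "x")),
                                          ("x*z", ("intercept", "x", "z", "xz"))])
def test_imputation_formula_designs(formula, cols):
    cohort = _all_matched_cohort(2000, seed=20)
    fit = ls.fit_complete_case_aft(cohort, formula=formula)
    assert fit.names == cols
    rm = ls.fit_restricted_mean(cohort, tau=90.0, formula=formula)
    assert rm.names == cols


def test_unknown_formula_rejected():
    with pytest.raises(ValueError):
        ls.fit_complete_case_aft(_all_matched_cohort(100, 2), formula="z")
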