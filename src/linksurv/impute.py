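"""Multiple imputation of missing event ages.

Two engines complete the cohort B times:

* **MICS** — conditional-survival imputation.  A Weibull AFT working
  model is fitted to the unequivocal matches; for each record needing an
  imputed age the Weibull CDF *conditional on survival to the census age
  w* is inverted at a uniform draw q:

      T_imp = [w**p - log(1 - q) / gamma]**(1/p),
      gamma = exp(-(a0 + a1 x + a2 z))**p,

  so every imputed age is at least w.  Imputed ages beyond the analysis
  age v are stored right-censored at v, mimicking the fully-observed
  analysis.

* **MIRM** — restricted-mean imputation.  A linear model for
  log(min(T, tau)) on (1, x, z) is fitted to the unequivocal matches;
  imputed log-ages are drawn from its normal predictive distribution
  (coefficients redrawn per imputation — proper MI), exponentiated,
  capped at tau and censored at v where applicable.

Both engines impute for nonmatches (weight 1) and for equivocal matches
(weight 1 - p_match, alongside the matched age with weight p_match), so
an equivocal record appears twice in each completed analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import LinkedCohort
from .estimate import AftFit, fit_weibull_aft, make_analysis_set

__all__ = [
    "FORMULAS",
    "fit_complete_case_aft",
    "mics_invert",
    "mics_impute",
    "RestrictedMeanFit",
    "fit_restricted_mean",
    "mirm_impute",
    "ImputedSet",
]

#: supported imputation-model formulas: the default, a covariate-omitting
#: misspecification, and an interaction misspecification
FORMULAS = ("x+z", "x", "x*z")


def _design_cols(formula: str) -> list[str]:
    if formula not in FORMULAS:
        raise ValueError(f"unknown imputation formula {formula!r}; "
                         f"expected one of {FORMULAS}")
    return {"x+z": ["x", "z"], "x": ["x"], "x*z": ["x", "z", "xz"]}[formula]


def _design(x, z, names) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    cols = {"intercept": np.ones_like(x), "x": x, "z": z, "xz": x * z}
    return np.column_stack([cols[n] for n in names])


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


@dataclass
class ImputedSet:
    """B completed, weighted analysis sets plus an audit trail.

    ``datasets[b]`` is an analysis-set DataFrame; ``q_draws`` /
    ``parameter_draws`` record the uniforms and per-imputation parameter
    vectors actually used (MICS), or the coefficient draws (MIRM).
    """

    datasets: list
    B: int
    method: str
    imputed_ids: np.ndarray
    q_draws: np.ndarray | None = None
    parameter_draws: np.ndarray | None = field(default=None, repr=False)


def fit_complete_case_aft(cohort: LinkedCohort, threshold: float = 0.8,
                          formula: str = "x+z", min_rows: int = 20) -> AftFit:
    """Weibull AFT ML fit on unequivocal matches, all treated as events.

    This is the working model from which MICS draws conditional
    survival; ``formula`` selects the imputation design (``"x"`` omits
    the covariate, ``"x*z"`` adds the interaction).
    """
    sub = cohort.matched(threshold).copy()
    if len(sub) == 0:
        raise ValueError("threshold leaves no unequivocal matches")
    if len(sub) < min_rows:
        raise ValueError(
            f"only {len(sub)} unequivocal matches (< {min_rows}); "
            "the Weibull working model would be unstable"
        )
    cols = _design_cols(formula)
    if "xz" in cols:
        sub["xz"] = sub["x"] * sub["z"]
    data = make_analysis_set(
        time=sub["t_star"], event=np.ones(len(sub), dtype=int),
        weight=np.ones(len(sub)), x=sub["x"], z=sub["z"],
        source="unequivocal", id=sub["id"],
    )
    if "xz" in cols:
        data["xz"] = sub["xz"].to_numpy()
    return fit_weibull_aft(data, design=cols)


def mics_invert(q, w, x, z, fit: AftFit):
    """Invert the Weibull CDF conditional on survival to w.

    Returns T_imp = [w**p - log(1-q)/gamma]**(1/p); q = 0 gives w
    exactly and T_imp is strictly increasing in q.
    """
    scalar = np.ndim(q) == 0 and np.ndim(w) == 0
    q = np.atleast_1d(np.asarray(q, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    if np.any(q < 0) or np.any(q >= 1):
        raise ValueError("q must lie in [0, 1); q = 1 maps to an infinite time")
    if np.any(w <= 0):
        raise ValueError("census age w must be positive")
    A = _design(x, z, fit.names)
    gamma = fit.gamma(A)
    if not np.all(np.isfinite(gamma)):
        raise ValueError("non-finite Weibull scale gamma")
    p = fit.shape_p
    out = (w ** p - np.log1p(-q) / gamma) ** (1.0 / p)
    return float(out[0]) if scalar else out


def _needs_imputation(df: pd.DataFrame, threshold: float):
    matched = df["r"] == 1
    uneq = matched & (df["p_match"] >= threshold)
    equiv = matched & ~uneq
    nonmatch = ~matched
    return uneq, equiv, nonmatch


def _matched_rows(df, uneq, equiv):
    """The observed (non-imputed) rows common to every completed dataset."""
    parts = []
    su = df[uneq]
    parts.append(make_analysis_set(
        time=su["t_star"], event=np.ones(len(su), dtype=int),
        weight=np.ones(len(su)), x=su["x"], z=su["z"],
        source="unequivocal", id=su["id"]))
    se = df[equiv]
    if len(se):
        parts.append(make_analysis_set(
            time=se["t_star"], event=np.ones(len(se), dtype=int),
            weight=se["p_match"].to_numpy(float), x=se["x"], z=se["z"],
            source="equivocal_matched", id=se["id"]))
    return parts


def _imputed_rows(imp_df, t_imp, censor_at_v):
    """Rows for the imputed ages: event at T_imp, or censored at v when
    the imputed age falls beyond the analysis date."""
    v = imp_df["v"].to_numpy(float)
    over = t_imp > v
    time = np.where(censor_at_v & over, v, t_imp)
    event = np.where(censor_at_v & over, 0, 1)
    wts = np.where(imp_df["r"].to_numpy() == 1,
                   1.0 - imp_df["p_match"].to_numpy(float), 1.0)
    src = np.where(imp_df["r"].to_numpy() == 1,
                   "equivocal_imputed", "nonmatch_imputed")
    return make_analysis_set(time=time, event=event, weight=wts,
                             x=imp_df["x"], z=imp_df["z"], source=src,
                             id=imp_df["id"])


def mics_impute(cohort: LinkedCohort, threshold: float = 0.8, B: int = 10,
                rng=0, proper: bool = True, formula: str = "x+z",
                censor_at_v: bool = True,
                fit: AftFit | None = None) -> ImputedSet:
    """Conditional-survival multiple imputation.

    Per imputation, each nonmatch and each equivocal match receives
    T_imp from :func:`mics_invert` at a fresh uniform q; under ``proper``
    (default) the Weibull parameters (alpha, log p) are first redrawn
    from the asymptotic normal of the complete-case fit, so Rubin's
    pooled variance is valid.
    """
    if B < 2:
        raise ValueError("multiple imputation needs B >= 2")
    rng = _as_rng(rng)
    if fit is None:
        fit = fit_complete_case_aft(cohort, threshold, formula)
    df = cohort.data
    uneq, equiv, nonmatch = _needs_imputation(df, threshold)
    needs = equiv | nonmatch
    imp_df = df[needs]
    base_parts = _matched_rows(df, uneq, equiv)

    k = len(fit.alpha)
    theta_hat = np.concatenate([fit.alpha, [np.log(fit.shape_p)]])
    datasets, qs, thetas = [], [], []
    for _ in range(B):
        if proper and len(imp_df):
            theta = rng.multivariate_normal(theta_hat, fit.vcov,
                                            method="cholesky")
        else:
            theta = theta_hat
        fit_b = AftFit(alpha=theta[:k], shape_p=float(np.exp(theta[k])),
                       vcov=fit.vcov, loglik=fit.loglik,
                       n_effective=fit.n_effective, names=fit.names)
        q = rng.uniform(size=len(imp_df))
        t_imp = mics_invert(q, imp_df["w"], imp_df["x"], imp_df["z"], fit_b)
        parts = base_parts + ([_imputed_rows(imp_df, t_imp, censor_at_v)]
                              if len(imp_df) else [])
        datasets.append(pd.concat(parts, ignore_index=True))
        qs.append(q)
        thetas.append(theta)
    return ImputedSet(datasets=datasets, B=B, method="mics",
                      imputed_ids=imp_df["id"].to_numpy(),
                      q_draws=np.array(qs), parameter_draws=np.array(thetas))


# ---------------------------------------------------------------------------
# Restricted-mean engine
# ---------------------------------------------------------------------------

@dataclass
class RestrictedMeanFit:
    """Least-squares model for E[log(min(T, tau))] on the imputation design."""

    coef: np.ndarray
    resid_var: float
    coef_cov: np.ndarray
    tau: float
    names: tuple
    n: int


def fit_restricted_mean(cohort: LinkedCohort, threshold: float = 0.8,
                        tau: float = 120.0,
                        formula: str = "x+z") -> RestrictedMeanFit:
    """Fit log(min(t_star, tau)) ~ design by ordinary least squares over
    the unequivocal matches."""
    if not tau > 0:
        raise ValueError("tau must be positive")
    sub = cohort.matched(threshold)
    if len(sub) == 0:
        raise ValueError("threshold leaves no unequivocal matches")
    names = tuple(["intercept"] + _design_cols(formula))
    A = _design(sub["x"], sub["z"], names)
    y = np.log(np.minimum(sub["t_star"].to_numpy(float), tau))
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = max(len(y) - A.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(A.T @ A)
    return RestrictedMeanFit(coef=coef, resid_var=s2, coef_cov=cov, tau=tau,
                             names=names, n=len(y))


def mirm_impute(cohort: LinkedCohort, fit: RestrictedMeanFit, B: int = 10,
                rng=0, threshold: float = 0.8,
                censor_at_v: bool = True) -> ImputedSet:
    """Restricted-mean multiple imputation.

    Per imputation: coefficients ~ N(fitted, coefficient covariance),
    imputed log-ages ~ N(design @ coefficients, residual variance),
    exponentiated, capped at tau, then right-censored at v when beyond
    the analysis date.
    """
    if B < 2:
        raise ValueError("multiple imputation needs B >= 2")
    rng = _as_rng(rng)
    df = cohort.data
    uneq, equiv, nonmatch = _needs_imputation(df, threshold)
    imp_df = df[equiv | nonmatch]
    base_parts = _matched_rows(df, uneq, equiv)
    A = _design(imp_df["x"], imp_df["z"], fit.names)

    datasets, coefs = [], []
    for _ in range(B):
        if len(imp_df):
            beta = (rng.multivariate_normal(fit.coef, fit.coef_cov,
                                            method="cholesky")
                    if np.any(fit.coef_cov) else fit.coef)
            mean = A @ beta
            logt = mean + (rng.normal(size=len(imp_df)) * np.sqrt(fit.resid_var)
                           if fit.resid_var > 0 else 0.0)
            t_imp = np.minimum(np.exp(logt), fit.tau)
            parts = base_parts + [_imputed_rows(imp_df, t_imp, censor_at_v)]
            coefs.append(beta)
        else:
            parts = base_parts
        datasets.append(pd.concat(parts, ignore_index=True))
    return ImputedSet(datasets=datasets, B=B, method="mirm",
                      imputed_ids=imp_df["id"].to_numpy(),
                      parameter_draws=np.array(coefs) if coefs else None)
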