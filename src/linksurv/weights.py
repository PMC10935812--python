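"""Weighted analysis sets for the non-imputation methods.

Builds the complete-case (CC), inverse-probability-weighted (IPW) and
censor-at-census (CENS) analysis sets from a linked cohort, following the
weighting scheme:

=====================  ===========  ======================  ==========
method                 unequivocal  equivocal               nonmatch
=====================  ===========  ======================  ==========
CC                     1            0                       0
IPW                    1 / Phat     p_match / Phat          0
CENS                   1            p_match                 1 (at w)
=====================  ===========  ======================  ==========

where Phat = P(r=1 | x, z) is the fitted matching propensity from a
logistic regression with both covariates, and "unequivocal" means
p_match >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import LinkedCohort
from .estimate import make_analysis_set

__all__ = ["PropensityFit", "fit_propensity", "build_analysis_set", "METHODS"]

METHODS = ("cc", "ipw", "cens")


@dataclass
class PropensityFit:
    """Logistic model for P(matched | x, z)."""

    coef: np.ndarray                 # (intercept, x, z) on the logit scale
    fitted: pd.Series                # per-record P(r=1 | x, z), indexed by id
    converged: bool

    def prob(self, ids) -> np.ndarray:
        return self.fitted.loc[ids].to_numpy()


def fit_propensity(cohort: LinkedCohort) -> PropensityFit:
    """Maximum-likelihood logistic regression of the match indicator on
    (x, z) with intercept.

    The analyst never knows the generative missingness link, so the
    working model is always logistic.
    """
    df = cohort.data
    r = df["r"].to_numpy()
    if r.min() == r.max():
        raise ValueError("all records share the same match indicator; "
                         "the propensity model is not identifiable")
    A = sm.add_constant(df[["x", "z"]].to_numpy(float))
    try:
        res = sm.GLM(r, A, family=sm.families.Binomial()).fit()
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise ValueError(
            f"propensity model failed ({exc}); pool sparse cells or regularize"
        ) from exc
    fitted = np.asarray(res.fittedvalues, dtype=float)
    if np.any(fitted <= 1e-10) or np.any(fitted >= 1 - 1e-10):
        raise ValueError("fitted match probabilities hit 0/1 (perfect "
                         "separation); pool sparse cells or regularize")
    return PropensityFit(
        coef=np.asarray(res.params, dtype=float),
        fitted=pd.Series(fitted, index=df["id"].to_numpy()),
        converged=bool(res.converged),
    )


def build_analysis_set(cohort: LinkedCohort, method: str,
                       threshold: float = 0.8,
                       propensity: PropensityFit | None = None) -> pd.DataFrame:
    """Weighted (time, event, weight) rows for one non-imputation method.

    CC keeps only unequivocal matches (weight 1, event at t_star); IPW
    keeps all matches with weights 1/Phat (unequivocal) or p_match/Phat
    (equivocal); CENS keeps everyone, censoring nonmatches at the census
    age w and down-weighting equivocal matched times by p_match.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    df = cohort.data
    matched = df["r"] == 1
    uneq = matched & (df["p_match"] >= threshold)
    equiv = matched & ~uneq

    if method == "cc":
        sub = df[uneq]
        return make_analysis_set(
            time=sub["t_star"], event=np.ones(len(sub), dtype=int),
            weight=np.ones(len(sub)), x=sub["x"], z=sub["z"],
            source="unequivocal", id=sub["id"],
        )

    if method == "ipw":
        if propensity is None:
            raise ValueError("IPW requires a fitted propensity model")
        sub = df[matched]
        phat = propensity.prob(sub["id"].to_numpy())
        w = np.where(sub["p_match"] >= threshold, 1.0, sub["p_match"]) / phat
        src = np.where(sub["p_match"] >= threshold,
                       "unequivocal", "equivocal_matched")
        return make_analysis_set(
            time=sub["t_star"], event=np.ones(len(sub), dtype=int),
            weight=w, x=sub["x"], z=sub["z"], source=src, id=sub["id"],
        )

    # CENS
    parts = []
    for mask, t_col, ev, wts, src in (
        (uneq, "t_star", 1, None, "unequivocal"),
        (equiv, "t_star", 1, "p_match", "equivocal_matched"),
        (~matched, "w", 0, None, "censored_at_w"),
    ):
        sub = df[mask]
        parts.append(make_analysis_set(
            time=sub[t_col], event=np.full(len(sub), ev, dtype=int),
            weight=(sub[wts].to_numpy(float) if wts else np.ones(len(sub))),
            x=sub["x"], z=sub["z"], source=src, id=sub["id"],
        ))
    out = pd.concat(parts, ignore_index=True)
    return out
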