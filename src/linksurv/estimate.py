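"""Weighted survival estimators and pooling.

Provides the estimation layer shared by every missing-data method:

* a weighted Kaplan–Meier product-limit curve and the median rule
  ``min t : S(t) <= 0.5``;
* weighted Cox proportional-hazards regression (Newton–Raphson on the
  partial likelihood, Efron ties, optional clustered sandwich variance);
* weighted Weibull accelerated failure-time regression by maximum
  likelihood with right censoring;
* the Weibull AFT <-> Cox PH coefficient conversion ``beta1 = -alpha1 * p``;
* Rubin's rules for pooling multiply-imputed estimates.

The Cox and AFT solvers are implemented directly in numpy: a Monte Carlo
study re-fits both models tens of thousands of times, and a lean Newton
solver is two orders of magnitude faster than general-purpose fitters.
Their results are cross-checked against lifelines in the test suite.

Analysis sets are plain :class:`pandas.DataFrame` objects with columns
``time, event, weight, x, z, source, id`` (see :func:`make_analysis_set`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalCurve",
    "weighted_km",
    "km_median",
    "MedianEstimates",
    "median_estimates",
    "CoxFit",
    "fit_cox",
    "AftFit",
    "fit_weibull_aft",
    "aft_to_cox",
    "MiResult",
    "rubin_pool",
    "make_analysis_set",
]

ANALYSIS_COLUMNS = ["time", "event", "weight", "x", "z", "source", "id"]


def make_analysis_set(time, event, weight, x, z, source, id=None) -> pd.DataFrame:
    """Assemble and validate a weighted analysis set (one row per
    pseudo-observation; equivocal matches may contribute two rows with
    the same ``id``)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    weight = np.asarray(weight, dtype=float)
    if np.any(weight < 0):
        raise ValueError("analysis weights must be non-negative")
    if np.any(time <= 0):
        raise ValueError("analysis times must be positive")
    if id is None:
        id = np.arange(len(time))
    source = np.broadcast_to(np.asarray(source, dtype=object), (len(time),))
    return pd.DataFrame(
        {"time": time, "event": event, "weight": weight,
         "x": np.asarray(x, dtype=int), "z": np.asarray(z, dtype=int),
         "source": source, "id": np.asarray(id)}
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Left-continuous weighted product-limit step function, S(0) = 1.

    ``times`` are the distinct event times, ``survival`` the value of S
    just after each (i.e. ``S(t)`` for ``times[k] <= t < times[k+1]``).
    """

    times: np.ndarray
    survival: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """S(t): probability of surviving beyond t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]

    @property
    def median(self) -> float:
        return km_median(self)


def weighted_km(data: pd.DataFrame, x: int | None = None,
                z: int | None = None) -> SurvivalCurve:
    """Weighted Kaplan–Meier curve of an analysis set, optionally within
    the stratum ``x == x`` and/or ``z == z``.

    Events and at-risk counts are weight sums; the curve is invariant to
    rescaling all weights by a constant.
    """
    df = data
    if x is not None:
        df = df[df["x"] == x]
    if z is not None:
        df = df[df["z"] == z]
    if len(df) == 0:
        raise ValueError("empty stratum")
    return _km(df["time"].to_numpy(float), df["event"].to_numpy(int),
               df["weight"].to_numpy(float))


def _km(time, event, weight) -> SurvivalCurve:
    order = np.lexsort((1 - event, time))  # ascending time, events first at ties
    t, d, w = time[order], event[order], weight[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights are zero")
    # aggregate to distinct times
    ut, first = np.unique(t, return_index=True)
    gidx = np.searchsorted(ut, t)
    dw = np.bincount(gidx, weights=w * d, minlength=len(ut))   # weighted events
    aw = np.bincount(gidx, weights=w, minlength=len(ut))       # weight leaving at t
    at_risk = total - np.concatenate(([0.0], np.cumsum(aw)[:-1]))
    has_event = dw > 0
    frac = np.zeros_like(dw)
    frac[has_event] = dw[has_event] / at_risk[has_event]
    surv = np.cumprod(1.0 - frac)
    return SurvivalCurve(times=ut[has_event], survival=surv[has_event])


def km_median(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5 ("falls at or below 50%");
    NaN when the curve never reaches 0.5."""
    hit = curve.survival <= 0.5 + 1e-12
    if not hit.any():
        return float("nan")
    return float(curve.times[np.argmax(hit)])


@dataclass
class MedianEstimates:
    """Exposure-group and covariate-specific KM medians (years).

    ``m0, m1`` pool over z within each exposure group; ``m_xz`` are the
    four cell medians; undefined medians are NaN, never extrapolated.
    """

    m0: float
    m1: float
    m00: float
    m01: float
    m10: float
    m11: float

    @property
    def m_diff(self) -> float:
        return self.m1 - self.m0

    def as_dict(self) -> dict[str, float]:
        return {"m0": self.m0, "m1": self.m1, "m00": self.m00, "m01": self.m01,
                "m10": self.m10, "m11": self.m11, "m_diff": self.m_diff}


def median_estimates(data: pd.DataFrame) -> MedianEstimates:
    """All six stratum medians of a weighted analysis set."""
    def med(**kw):
        try:
            return km_median(weighted_km(data, **kw))
        except ValueError:
            return float("nan")

    return MedianEstimates(
        m0=med(x=0), m1=med(x=1),
        m00=med(x=0, z=0), m01=med(x=0, z=1),
        m10=med(x=1, z=0), m11=med(x=1, z=1),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (weighted, Efron ties)
# ---------------------------------------------------------------------------

class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoxFit:
    """Weighted Cox PH fit: log-hazard ratios for (x, z)."""

    beta: np.ndarray          # (beta1, beta2) for x, z
    vcov: np.ndarray
    loglik: float
    robust: bool
    ties: str = "efron"
    names: tuple = ("x", "z")

    @property
    def beta1(self) -> float:
        return float(self.beta[0])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def _cox_ll_grad_hess(t, d, w, X, beta, ev_count, first, gidx):
    """Log partial likelihood with Efron tie handling (weighted)."""
    n, p = X.shape
    eta = X @ beta
    c = eta.max() if n else 0.0
    r = w * np.exp(eta - c)
    rx = r[:, None] * X
    rxx = rx[:, :, None] * X[:, None, :]
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1]
    S2 = np.cumsum(rxx[::-1], axis=0)[::-1]
    S0g, S1g, S2g = S0[first], S1[first], S2[first]

    ll = float(np.sum(w * d * eta))
    grad = np.sum((w * d)[:, None] * X, axis=0)
    hess = np.zeros((p, p))

    row_ev = ev_count[gidx]
    single = (d == 1) & (row_ev == 1)
    if single.any():
        s0 = S0g[gidx[single]]
        M = S1g[gidx[single]] / s0[:, None]
        ws = w[single]
        ll -= float(np.sum(ws * (np.log(s0) + c)))
        grad -= np.sum(ws[:, None] * M, axis=0)
        hess -= np.einsum("i,ijk->jk", ws,
                          S2g[gidx[single]] / s0[:, None, None]
                          - M[:, :, None] * M[:, None, :])

    for g in np.nonzero(ev_count > 1)[0]:
        rows = np.nonzero((gidx == g) & (d == 1))[0]
        m = len(rows)
        wbar = w[rows].sum() / m
        s0e, s1e, s2e = r[rows].sum(), rx[rows].sum(0), rxx[rows].sum(0)
        for ell in range(m):
            f = ell / m
            D = S0g[g] - f * s0e
            M = (S1g[g] - f * s1e) / D
            ll -= wbar * (math.log(D) + c)
            grad -= wbar * M
            hess -= wbar * ((S2g[g] - f * s2e) / D - np.outer(M, M))
    return ll, grad, hess


def _cox_solve(time, event, weight, X, tol=1e-9, max_iter=100):
    order = np.argsort(time, kind="stable")
    t, d, w = time[order], event[order], weight[order]
    Xs = X[order]
    ut, first = np.unique(t, return_index=True)
    gidx = np.searchsorted(ut, t)
    ev_count = np.bincount(gidx, weights=(d == 1).astype(float),
                           minlength=len(ut)).astype(int)
    p = Xs.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_ll_grad_hess(t, d, w, Xs, beta, ev_count, first, gidx)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        if not np.all(np.isfinite(step)):
            raise ConvergenceError("non-finite Newton step (separation?)")
        new = beta + step
        ll_new, g_new, h_new = _cox_ll_grad_hess(t, d, w, Xs, new, ev_count, first, gidx)
        halv = 0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-12) and halv < 30:
            step /= 2.0
            new = beta + step
            ll_new, g_new, h_new = _cox_ll_grad_hess(t, d, w, Xs, new,
                                                     ev_count, first, gidx)
            halv += 1
        beta, ll, grad, hess = new, ll_new, g_new, h_new
        if np.max(np.abs(grad)) < tol or np.max(np.abs(step)) < 1e-12:
            break
    else:
        raise ConvergenceError("Cox Newton iterations did not converge")
    if np.max(np.abs(beta)) > 50:
        raise ConvergenceError("monotone likelihood / separation suspected")
    info = -hess
    vcov = np.linalg.inv(info)
    return beta, vcov, ll, (t, d, w, Xs, ut, first, gidx)


def _cox_score_residuals(t, d, w, Xs, beta, ut, first, gidx):
    """Per-row score residuals (Breslow form; exact when times are untied)."""
    eta = Xs @ beta
    c = eta.max()
    r = w * np.exp(eta - c)
    rx = r[:, None] * Xs
    S0 = np.cumsum(r[::-1])[::-1][first]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1][first]
    M = S1 / S0[:, None]
    dN = np.bincount(gidx, weights=w * d, minlength=len(ut))
    A0 = np.cumsum(dN / S0)
    A1 = np.cumsum((dN / S0)[:, None] * M, axis=0)
    g = gidx
    resid = (d[:, None] * (Xs - M[g])
             - np.exp(eta - c)[:, None] * (Xs * A0[g][:, None] - A1[g]))
    return resid


def fit_cox(data: pd.DataFrame, robust: bool | None = None) -> CoxFit:
    """Weighted Cox PH regression of time on (x, z).

    ``robust=None`` (default) applies the clustered sandwich variance
    automatically whenever any weight is not 0/1 or record ids repeat
    (equivocal matches contribute two correlated pseudo-rows).
    """
    time = data["time"].to_numpy(float)
    event = data["event"].to_numpy(int)
    weight = data["weight"].to_numpy(float)
    X = data[["x", "z"]].to_numpy(float)
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    for j, nm in enumerate(("x", "z")):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {nm!r} does not vary")
    keep = weight > 0
    time, event, weight, X = time[keep], event[keep], weight[keep], X[keep]
    ids = data.loc[keep, "id"].to_numpy()

    has_dup_ids = bool(pd.Series(ids).duplicated().any())
    if robust is None:
        robust = bool(np.any(~np.isin(weight, (0.0, 1.0))) or has_dup_ids)
    if has_dup_ids:
        # identical pseudo-rows of one record are a single observation;
        # merging their weights keeps Efron ties meaningful and makes the
        # fit invariant to splitting a row into fractional-weight copies
        agg = (pd.DataFrame({"id": ids, "time": time, "event": event,
                             "x": X[:, 0], "z": X[:, 1], "weight": weight})
               .groupby(["id", "time", "event", "x", "z"], sort=False,
                        as_index=False)["weight"].sum())
        time = agg["time"].to_numpy()
        event = agg["event"].to_numpy(int)
        weight = agg["weight"].to_numpy()
        X = agg[["x", "z"]].to_numpy(float)
        ids = agg["id"].to_numpy()

    beta, vcov, ll, packed = _cox_solve(time, event, weight, X)
    if robust:
        t, d, w, Xs, ut, first, gidx = packed
        order = np.argsort(time, kind="stable")
        cl = pd.factorize(ids[order])[0]
        resid = _cox_score_residuals(t, d, w, Xs, beta, ut, first, gidx)
        wres = w[:, None] * resid
        gsum = np.zeros((cl.max() + 1, Xs.shape[1]))
        np.add.at(gsum, cl, wres)
        meat = gsum.T @ gsum
        vcov = vcov @ meat @ vcov
    return CoxFit(beta=beta, vcov=vcov, loglik=ll, robust=robust)


# ---------------------------------------------------------------------------
# Weibull AFT (weighted maximum likelihood, right censoring)
# ---------------------------------------------------------------------------

@dataclass
class AftFit:
    """Weibull AFT fit: log t = a0 + a1 x + a2 z + eps/p, Gumbel-min eps.

    Equivalently S(t|x,z) = exp(-gamma t**p) with
    gamma = exp(-(a0 + a1 x + a2 z))**p.  ``vcov`` covers the
    coefficients plus log p (last index).
    """

    alpha: np.ndarray         # coefficients, intercept first
    shape_p: float
    vcov: np.ndarray          # for (alpha..., log p)
    loglik: float
    n_effective: float
    names: tuple = ("intercept", "x", "z")

    @property
    def alpha1(self) -> float:
        return float(self.alpha[1])

    @property
    def se(self) -> np.ndarray:
        """SEs of (alpha..., log p)."""
        return np.sqrt(np.diag(self.vcov))

    @property
    def event_time_ratio(self) -> float:
        return float(np.exp(self.alpha[1]))

    def gamma(self, A: np.ndarray) -> np.ndarray:
        """Weibull scale gamma_i = exp(-A @ alpha)**p for design rows A."""
        return np.exp(-self.shape_p * (A @ self.alpha))

    def linear_predictor(self, A: np.ndarray) -> np.ndarray:
        return A @ self.alpha


def _aft_ll_grad_hess(logt, d, w, A, theta):
    k = A.shape[1]
    alpha, logp = theta[:k], theta[k]
    p = math.exp(logp)
    mu = A @ alpha
    s = p * (logt - mu)
    e = np.exp(np.clip(s, -700, 700))
    ll = float(np.sum(w * (d * (logp + s - logt) - e)))
    de = d - e
    grad = np.empty(k + 1)
    grad[:k] = -p * (w * de) @ A
    grad[k] = float(np.sum(w * (d * (1 + s) - e * s)))
    hess = np.empty((k + 1, k + 1))
    hess[:k, :k] = -(p ** 2) * (A.T * (w * e)) @ A
    hab = -p * (w * (de - e * s)) @ A
    hess[:k, k] = hess[k, :k] = hab
    hess[k, k] = float(np.sum(w * (d * s - e * s * (s + 1))))
    return ll, grad, hess


def fit_weibull_aft(data: pd.DataFrame, robust: bool | None = None,
                    design: list[str] | None = None) -> AftFit:
    """Weighted Weibull AFT maximum likelihood with right-censored rows.

    ``design`` names the covariate columns (default ``["x", "z"]``); an
    intercept is always included first.  Variance is the inverse observed
    information, replaced by a clustered sandwich under the same
    auto-robust rule as :func:`fit_cox`.
    """
    cols = design if design is not None else ["x", "z"]
    time = data["time"].to_numpy(float)
    event = data["event"].to_numpy(int)
    weight = data["weight"].to_numpy(float)
    keep = weight > 0
    time, event, weight = time[keep], event[keep], weight[keep]
    A = np.column_stack([np.ones(keep.sum())] + [data.loc[keep, c].to_numpy(float) for c in cols])
    ids = data.loc[keep, "id"].to_numpy()
    if (weight * event).sum() <= 0:
        raise ValueError("no events: the Weibull AFT likelihood is unbounded")
    if robust is None:
        robust = bool(np.any(~np.isin(weight, (0.0, 1.0)))
                      or pd.Series(ids).duplicated().any())

    logt = np.log(time)
    # init: weighted LS of log t on events; shape from Gumbel residual variance
    ev = event == 1
    Ae, we, ye = A[ev], weight[ev], logt[ev]
    try:
        a0 = np.linalg.lstsq(Ae * np.sqrt(we)[:, None], ye * np.sqrt(we), rcond=None)[0]
    except np.linalg.LinAlgError:
        a0 = np.zeros(A.shape[1])
    res = ye - Ae @ a0
    sd = math.sqrt(max(np.average(res ** 2, weights=we), 1e-8))
    p0 = min(max(math.pi / (sd * math.sqrt(6.0)), 1e-2), 100.0)
    theta = np.concatenate([a0, [math.log(p0)]])

    ll, grad, hess = _aft_ll_grad_hess(logt, event, weight, A, theta)
    for _ in range(200):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular AFT information: {exc}") from exc
        if grad @ step <= 0:
            # Hessian indefinite far from the optimum: fall back to a
            # normalized steepest-ascent step (halving handles the scale)
            step = grad / (1.0 + np.linalg.norm(grad))
        new = theta + step
        ll_new, g_new, h_new = _aft_ll_grad_hess(logt, event, weight, A, new)
        halv = 0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-12) and halv < 40:
            step /= 2.0
            new = theta + step
            ll_new, g_new, h_new = _aft_ll_grad_hess(logt, event, weight, A, new)
            halv += 1
        theta, ll, grad, hess = new, ll_new, g_new, h_new
        if np.max(np.abs(grad)) < 1e-8 or np.max(np.abs(step)) < 1e-13:
            break
    else:
        raise ConvergenceError("Weibull AFT iterations did not converge")

    info = -hess
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"degenerate AFT fit: {exc}") from exc
    if robust:
        k = A.shape[1]
        alpha, logp = theta[:k], theta[k]
        p = math.exp(logp)
        s = p * (logt - A @ alpha)
        e = np.exp(np.clip(s, -700, 700))
        sc = np.empty((len(logt), k + 1))
        sc[:, :k] = -p * ((weight * (event - e))[:, None] * A)
        sc[:, k] = weight * (event * (1 + s) - e * s)
        cl = pd.factorize(ids)[0]
        gsum = np.zeros((cl.max() + 1, k + 1))
        np.add.at(gsum, cl, sc)
        vcov = vcov @ (gsum.T @ gsum) @ vcov
    return AftFit(alpha=theta[:-1], shape_p=math.exp(theta[-1]), vcov=vcov,
                  loglik=ll, n_effective=float(weight.sum()),
                  names=tuple(["intercept"] + cols))


def aft_to_cox(alpha1: float, shape_p: float) -> float:
    """Cox log-hazard ratio implied by a Weibull AFT coefficient:
    beta1 = -alpha1 * p."""
    if not shape_p > 0:
        raise ValueError("shape_p must be > 0")
    return -alpha1 * shape_p


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class MiResult:
    """Rubin's-rules pooled estimate over B imputations."""

    estimate: float
    within: float             # mean model-based variance W-bar
    between: float            # sample variance of the B estimates
    total_variance: float     # W-bar + (1 + 1/B) * between
    df: float
    B: int

    @property
    def se(self) -> float:
        return math.sqrt(self.total_variance)


def rubin_pool(estimates, variances=None) -> MiResult:
    """Pool B point estimates (and optionally their model variances).

    When ``variances`` is None — e.g. KM medians, which carry no
    closed-form variance — the within component is zero and the interval
    rests on the between-imputation spread alone.
    """
    est = np.asarray(estimates, dtype=float)
    B = len(est)
    if B < 2:
        raise ValueError("Rubin's rules need at least 2 imputations")
    if variances is None:
        var = np.zeros(B)
    else:
        var = np.asarray(variances, dtype=float)
        if len(var) != B:
            raise ValueError("estimates and variances must have equal length")
    ok = np.isfinite(est)
    est, var = est[ok], var[ok]
    b_used = len(est)
    if b_used < 2:
        return MiResult(float(est[0]) if b_used else float("nan"),
                        float("nan"), float("nan"), float("nan"),
                        float("nan"), B)
    wbar = float(np.mean(var))
    bvar = float(np.var(est, ddof=1))
    total = wbar + (1.0 + 1.0 / b_used) * bvar
    if bvar > 0:
        df = (b_used - 1) * (1.0 + wbar / ((1.0 + 1.0 / b_used) * bvar)) ** 2
    else:
        df = float("inf")
    return MiResult(estimate=float(np.mean(est)), within=wbar, between=bvar,
                    total_variance=total, df=df, B=B)
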