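"""Synthetic linked-cohort generator.

Emulates the study design of a historic census cohort linked to death
records: lifetimes follow a Weibull accelerated failure-time model in a
binary exposure ``x`` and covariate ``z``; every subject is observed once
at the census (age ``w``, drawn uniformly over their lifetime) and the
analysis happens a fixed ``c`` years later (age ``v = w + c``).  Deaths
before ``v`` may or may not be linked to a death record: the match
indicator is Bernoulli with probability given by a link function of
``(x, z)``, survivors are never matched, and each match carries a
Beta-distributed probabilistic score ``p_match``.  Scores below the
unequivocal threshold get a noisy matched event age, with noise standard
deviation ``error_base**(1/p_match)`` — the weaker the match, the larger
the error.

Five preset scenario files (``setting1`` … ``setting5``) encode the
benchmark simulation grid: two lifetime models, MCAR/MAR missingness
patterns, and a score law that may depend on ``z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort import LinkedCohort

__all__ = [
    "ScenarioSpec",
    "load_setting",
    "load_scenario",
    "draw_cohort",
    "weibull_median",
    "apply_match_error",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative parameters for one simulation setting.

    Parameters
    ----------
    alpha : tuple of float
        AFT linear coefficients (a0, a1, a2): log lifetime scale is
        ``a0 + a1*x + a2*z``.
    shape_p : float
        Weibull shape p (> 0); survival S(t) = exp(-gamma t**p) with
        ``gamma = exp(-(a0 + a1 x + a2 z))**p``.
    delta : tuple of float
        Missingness linear coefficients (d0, d1, d2) on the link scale.
    missing_link : str
        'logit' (default) or 'exp'; maps d0 + d1 x + d2 z to P(matched).
        'exp' is range-checked and errors if it exceeds 1.
    followup_c : float
        Years between census and analysis date; v = w + c.
    score_beta : tuple of float
        Beta(a, b) law of the match score p_match.
    score_depends_on_z : bool
        If True the score law is Beta(a - z, b + z).
    unequivocal_threshold : float
        Scores >= threshold are unequivocal: the matched age equals the
        true event age; below it, measurement error is added.
    error_base : float
        Base of the measurement-error SD, error_base**(1/p_match).
    floor_at_census : bool
        Floor noisy matched ages at w + 0.01 years (an event before the
        census observation is logically impossible); set False to keep
        raw draws.
    n : int
        Cohort size.
    seed : int
        RNG seed; same seed reproduces the cohort bitwise.
    """

    alpha: tuple[float, float, float] = (4.4, -0.2, 0.0)
    shape_p: float = 6.0
    delta: tuple[float, float, float] = (-1.0, 0.0, 2.0)
    missing_link: str = "logit"
    followup_c: float = 50.0
    score_beta: tuple[float, float] = (8.0, 2.0)
    score_depends_on_z: bool = False
    unequivocal_threshold: float = 0.8
    error_base: float = 1.8
    floor_at_census: bool = True
    n: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not self.shape_p > 0:
            raise ValueError("shape_p must be > 0")
        if not all(b > 0 for b in self.score_beta):
            raise ValueError("Beta parameters must be > 0")
        if not 0 <= self.unequivocal_threshold <= 1:
            raise ValueError("unequivocal_threshold must be in [0,1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.missing_link not in ("logit", "exp", "zero"):
            raise ValueError(f"unknown missing_link {self.missing_link!r}")

    def with_(self, **kw) -> "ScenarioSpec":
        """Copy with fields replaced (e.g. ``spec.with_(seed=7)``)."""
        return replace(self, **kw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["alpha"] = list(d["alpha"])
        d["delta"] = list(d["delta"])
        d["score_beta"] = list(d["score_beta"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_scenario(path) -> ScenarioSpec:
    """Load a :class:`ScenarioSpec` from a YAML/JSON mapping file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("alpha", "delta", "score_beta"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ScenarioSpec(**raw)


def load_setting(number: int, **overrides) -> ScenarioSpec:
    """Load preset scenario ``setting1`` … ``setting5``."""
    if number not in (1, 2, 3, 4, 5):
        raise ValueError("setting number must be 1..5")
    ref = resources.files("linksurv.settings") / f"setting{number}.yaml"
    with resources.as_file(ref) as path:
        spec = load_scenario(path)
    return spec.with_(**overrides) if overrides else spec


def weibull_median(alpha_lin: float, shape_p: float) -> float:
    """Median lifetime exp(alpha_lin) * ln(2)**(1/p) of the Weibull AFT
    model at linear predictor ``alpha_lin`` — the t solving S(t) = 1/2."""
    if not shape_p > 0:
        raise ValueError("shape_p must be > 0")
    return float(np.exp(alpha_lin) * math.log(2.0) ** (1.0 / shape_p))


def apply_match_error(t_true, p_match, threshold, error_base, rng,
                      floor_at=None):
    """Matched event age with score-dependent measurement error.

    Unequivocal scores (p_match >= threshold) return the true age exactly;
    otherwise Normal noise with SD ``error_base**(1/p_match)`` is added.
    ``floor_at`` (array-like or None) optionally floors the result, since
    a noisy draw can land before the census age or below zero.
    """
    t_true = np.asarray(t_true, dtype=float)
    p = np.asarray(p_match, dtype=float)
    if np.any(p <= 0):
        raise ValueError("p_match must be positive for matched records")
    sd = np.where(p < threshold, error_base ** (1.0 / p), 0.0)
    t_star = t_true + np.where(sd > 0, rng.normal(0.0, 1.0, size=t_true.shape) * sd, 0.0)
    if floor_at is not None:
        t_star = np.maximum(t_star, np.asarray(floor_at, dtype=float))
    return t_star


def _match_probability(spec: ScenarioSpec, x, z):
    lin = spec.delta[0] + spec.delta[1] * x + spec.delta[2] * z
    if not np.all(np.isfinite(lin)):
        raise ValueError("non-finite missingness linear predictor")
    if spec.missing_link == "logit":
        return expit(lin)
    if spec.missing_link == "zero":
        return np.zeros_like(lin, dtype=float)
    pr = np.exp(lin)
    if np.any(pr > 1):
        raise ValueError(
            "link 'exp' produced a match probability above 1; "
            "use missing_link='logit'"
        )
    return pr


def draw_cohort(spec: ScenarioSpec) -> LinkedCohort:
    """Draw one synthetic linked cohort under ``spec``.

    Generation order: covariates X, Z ~ Bernoulli(1/2); lifetime T from
    the Weibull AFT model; census age W ~ Uniform(0, T) and analysis age
    V = W + c; match indicator Bernoulli(link(delta'x)) then forced to 0
    for survivors (T >= V); match score from the Beta law; matched event
    age via :func:`apply_match_error`.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    x = rng.integers(0, 2, n)
    z = rng.integers(0, 2, n)
    mu = spec.alpha[0] + spec.alpha[1] * x + spec.alpha[2] * z
    # log T = mu + eps/p with standard Gumbel-min eps  <=>  T = e^mu * E^(1/p), E ~ Exp(1)
    t_true = np.exp(mu) * rng.exponential(size=n) ** (1.0 / spec.shape_p)
    w = rng.uniform(0.0, t_true)
    v = w + spec.followup_c
    delta_true = (t_true < v).astype(int)

    pr = _match_probability(spec, x, z)
    r = (rng.uniform(size=n) < pr).astype(int)
    r[t_true >= v] = 0  # no one alive at the analysis date is matched

    p_match = np.zeros(n)
    t_star = np.full(n, np.nan)
    m = r == 1
    if m.any():
        a = spec.score_beta[0] - (z[m] if spec.score_depends_on_z else 0.0)
        b = spec.score_beta[1] + (z[m] if spec.score_depends_on_z else 0.0)
        p_match[m] = rng.beta(a, b, size=int(m.sum()))
        floor = w[m] + 0.01 if spec.floor_at_census else None
        t_star[m] = apply_match_error(
            t_true[m], p_match[m], spec.unequivocal_threshold,
            spec.error_base, rng, floor_at=floor,
        )

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "x": x,
            "z": z,
            "w": w,
            "v": v,
            "r": r,
            "p_match": p_match,
            "t_star": t_star,
            "t_true": t_true,
            "delta_true": delta_true,
        }
    )
    return LinkedCohort(df)
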