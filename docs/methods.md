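# Methods

## Setting and assumptions

One row per census record: binary exposure `x`, binary covariate `z`,
age at census `w > 0`, age at the analysis date `v = w + c` (the
calendar gap `c` is constant, so `v` varies by birth year), match
indicator `r`, match score `p_match` and, when `r = 1`, the matched
death age `t_star`. The timescale is years since birth throughout; ages
are continuous floats and never rounded.

Assumptions inherited from the study design:

* nobody alive at the analysis date is matched (`r = 1 ⇒ T < v`);
* at most one match per record (the best-scoring candidate);
* match errors are random: `p_match` is the probability the linked
  record is truly the person's, independent of the linkage variables,
  so equivocal matches affect variance and measurement error but the
  missingness process itself is MCAR or MAR given `(x, z)`.

`r = 1` always means "matched / death age observed". Scores at or above
the unequivocal threshold `P` (default 0.8) are treated as exact
everywhere — in the generator (no measurement error), in complete-case
filtering, and in the imputation engines. Using one convention on both
sides keeps generator and analysis consistent; with a continuous Beta
score the boundary itself has probability zero.

## Estimation layer

* **Weighted Kaplan–Meier.** Product-limit with weight sums in the event
  and at-risk counts; invariant to rescaling all weights. The median is
  `min t : S(t) ≤ 0.5` (the curve value *at or below* one half), and a
  curve that never reaches 0.5 yields NaN — undefined medians propagate
  as missing, never extrapolated. Exposure-group medians `M_x` pool over
  `z`; cell medians `M_xz` condition on both.
* **Weighted Cox PH** on `(x, z)`: Newton–Raphson on the partial
  likelihood with Efron tie handling. Pseudo-rows of the same record
  with identical (time, event, covariates) are merged by summing weights
  before fitting, which keeps tie counts meaningful and makes the fit
  invariant to splitting one observation into fractional-weight copies.
* **Weighted Weibull AFT** by full maximum likelihood with right
  censoring, parameterized as `(α, log p)`; Newton with step-halving and
  a steepest-ascent fallback where the Hessian is indefinite. Initial
  values come from least squares on the uncensored log-times.
* **Variance.** Inverse observed information by default; when any weight
  is fractional or a record contributes several rows, a sandwich
  clustered on record id replaces it (equivocal matches contribute two
  correlated pseudo-rows). Both solvers reproduce lifelines point
  estimates to ~1e-5 and robust SEs to ~2% in the test suite; they are
  implemented in numpy because the Monte Carlo study refits both models
  tens of thousands of times and general-purpose fitters dominate the
  runtime at that scale.
* **Rubin's rules.** Pooled mean; total variance `W̄ + (1 + 1/B)·B_var`;
  Barnard–Rubin-free classical df `(B−1)(1 + W̄/((1+1/B)B_var))²`.
  Medians have no closed-form within-imputation variance, so they are
  pooled with the between-imputation component only (an optional
  bootstrap within-variance was considered and dropped as out of
  proportion to its use; the study summarizes median *bias*, not median
  CIs).

## Missing-data methods

Weights per record (threshold `P`, propensity `P̂ = P̂(r=1|x,z)` from a
maximum-likelihood logistic fit with both covariates, whatever the
generative link):

| | unequivocal | equivocal | nonmatch |
|---|---|---|---|
| CC   | 1 | – | – |
| IPW  | 1/P̂ | p/P̂ | – |
| CENS | 1 | p (at `t_star`) | 1 (censored at `w`) |
| MI   | 1 | p (at `t_star`) + (1−p) (at `T_imp`) | 1 (at `T_imp`) |

CENS carries no complementary censored row for equivocal matches — only
the down-weighted matched age — matching the weighting table as printed.
No weight truncation is applied by default (an optional cap exists for
pathological propensities).

**MICS.** Working Weibull AFT fitted to unequivocal matches only, all
treated as events. Imputation inverts the conditional CDF given survival
to `w`, so `T_imp ≥ w` by construction; `T_imp > v` is stored censored
at `v`, mimicking the gold-standard analysis. Proper MI (parameter
redraw from the asymptotic normal of `(α̂, log p̂)` per imputation) is the
default so Rubin variance is valid; an improper mode exists for
ablation. The observed `t_star` of an equivocal match does not inform
its imputation draw — the imputed row is the complement of the match,
conditioned only on `(w, x, z)`.

**MIRM.** Least squares for `log(min(t_star, τ))` on the imputation
design over unequivocal matches. Per imputation, coefficients are drawn
from their normal sampling distribution and log-times from the residual
normal; results are exponentiated, capped at `τ`, then censored at `v`
when beyond it. The cap is applied on the time scale after
exponentiation; like MICS, imputed times beyond `v` are censored there
— both choices are configurable since the restricted-mean literature
admits either reading. Default `τ = 120` with `τ = 80` as the standard
alternative (near the upper bound and the median of the simulated
lifetime distributions, respectively); `B = 10` imputations by default —
bias summaries were insensitive to `B` in exploratory runs, as expected
for point-estimate pooling.

**Imputation formulas.** Default design `x + z`, matching the analysis
model. `x` (covariate omitted) and `x*z` (interaction added) are
selectable to study imputation-model misspecification while the analysis
model stays `x + z`.

## Synthetic cohorts

`draw_cohort` generates, in order: `x, z ~ Bernoulli(1/2)`; `T` from the
Weibull AFT model (`T = exp(α'x)·E^{1/p}`, `E ~ Exp(1)`); `w ~ U(0, T)`
(everyone is alive at their census age by construction); `v = w + c`
with `c = 50`; match indicator Bernoulli(link(δ₀ + δ₁x + δ₂z)) then
forced to 0 for survivors; Beta match scores; matched ages with
score-dependent Normal error of SD `1.8^(1/p_match)` below the
threshold.

Numerical choices:

* **Missingness link.** The default is the inverse logit. A raw
  exponential link is available but range-checked and refused when the
  linear predictor implies a "probability" above one — which it does for
  every preset δ, so the logit is the only internally consistent choice
  across the benchmark grid; the suppression of survivor matches is
  applied after the Bernoulli draw.
* **Noise floor.** Score-dependent noise can push a matched age below
  the census age or below zero; the default floors it at `w + 0.01`
  years (an event before the census observation is logically impossible
  here), configurable to keep raw draws. The reader still accepts
  externally supplied files with `t_star < w` and logs them.
* **Seeding.** One `numpy` generator per cohort; replicate `k` of a
  study uses `base_seed + k`, so method arms share cohorts and bias
  contrasts against the gold standard are paired. Identical seeds
  reproduce cohorts bitwise.

The five presets encode the benchmark grid: lifetimes
`α = (4.4, −0.2, 0)` (settings 1–2) or `(4.5, −0.2, −0.2)` (3–5);
missingness `δ = (−1, 0, 2)`, `(−1, 2, 0)`, `(−1, 0, 2)`, `(−1, 1, 1)`,
`(−1, 1, 1)`; setting 5 degrades score quality when `z = 1`
(Beta(8−z, 2+z)).

What the generator does *not* emulate: multiple candidate matches,
linkage variables themselves, calendar-period mortality trends,
competing risks, or missingness depending on unobserved quantities
(MNAR). Passing tests therefore speak to the methods' behaviour under
MCAR/MAR with random match error, not to linkage pipelines where match
failure is driven by the death age itself.

## Monte Carlo study

`run_study` draws K replicate cohorts, applies the gold standard
(deaths before `v` observed at the true age, survivors censored at `v`)
plus each requested method to the same cohort, and summarizes
per-replicate-paired mean bias, empirical SE and mean model SE for
`β₁`, `α₁`, the six medians and `M₁ − M₀`. Method failures in a
replicate are logged and excluded, with a hard error above a 20%
failure rate; results are reduction-order independent and fully
deterministic given `(spec, K, base_seed, config)`.

Default problem sizes: the headline gold-standard median summaries use
K = 500 replicates of n = 1000; the method-comparison checks in the
test suite use K = 100, which is sufficient to resolve every bias
contrast that is an order of magnitude above its Monte Carlo error.

## Known limitations

* When missingness is independent of the exposure (presets 1 and 3),
  censoring-at-census is nearly unbiased for `α₁`: `W ~ U(0, T)` scales
  with `T`, so the dependent-censoring bias is common to both exposure
  groups and cancels in the log event-time *ratio* (it does not cancel
  in the intercept or the medians). Bias orderings between CENS and the
  MI engines in those presets are therefore a matter of small
  finite-sample effects, not of method quality.
* The propensity model is deliberately logistic regardless of the
  generative link (the analyst never knows the truth), so fitted
  coefficients need not converge to the generative δ; only the fitted
  probabilities matter for IPW.
* Real applications (occupational cohorts linked through genealogy
  services and death indices) involve covariate sets, time-varying
  linkage quality and score distributions this package does not model;
  `analyze_cohort` accepts any cohort CSV with the canonical schema,
  but its validity there rests on the MAR-given-covariates assumption.
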