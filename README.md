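# linksurv

Survival analysis when event times come from **imperfect record linkage**
of a census cohort to death records.

Historical census cohorts are observed exactly once — at the census, age
`w` — and their death ages are recovered by probabilistically linking
census rows to vital records decades later. The linkage fails for many
records, and an unmatched record is ambiguous: the person may still have
been alive at the analysis date (age `v = w + c`), or dead with no
retrievable record. Matched records carry a score `p_match ∈ (0, 1]`
giving the probability the linked death record is truly theirs; weak
(*equivocal*) matches may also carry a mismeasured death age. Naive
handling of either problem distorts hazard ratios and median survival.

`linksurv` implements and evaluates five strategies for this setting:

| method | idea |
|---|---|
| `cc`   | complete case: unequivocal matches only |
| `ipw`  | all matches, weighted by `p_match / P̂(matched │ x, z)` from a logistic propensity model |
| `cens` | keep everyone; right-censor unmatched records at the census age `w`; weight equivocal matched ages by `p_match` |
| `mirm` | multiple imputation from a linear model for `log(min(T, τ))` (restricted-mean structure) |
| `mics` | multiple imputation by inverting the Weibull conditional survival distribution given survival to `w` |

## Model

Lifetimes follow a Weibull accelerated failure-time (AFT) model,

    log T = α₀ + α₁x + α₂z + ε/p,      S(t|x,z) = exp(−γ tᵖ),
    γ = exp(−(α₀ + α₁x + α₂z))ᵖ,

with binary exposure `x` and covariate `z`; `α₁` is the log event-time
ratio. Under the Weibull the Cox proportional-hazards log-HR is
`β₁ = −α₁·p`. Estimands are `β₁`, `α₁`, and the Kaplan–Meier medians
`M₀, M₁` (per exposure group) and `M₀₀ … M₁₁` (per exposure × covariate
cell), using the rule `min t : S(t) ≤ 0.5`.

MICS imputes a missing death age for a record observed alive at age `w`
by drawing `q ~ U(0,1)` and inverting the conditional CDF:

    T_imp = [wᵖ − log(1 − q)/γ̂]^(1/p)  ≥  w,

with `(α̂, p̂)` from a Weibull fit to the unequivocal matches (redrawn
from their asymptotic normal per imputation — proper MI). Equivocal
matches appear twice per completed dataset: the matched age with weight
`p_match` and the imputed age with weight `1 − p_match`. Estimates are
pooled across the `B` completed datasets by Rubin's rules.

A scenario generator (`draw_cohort` with presets `setting1 … setting5`)
reproduces the benchmark simulation grid — Weibull shape `p = 6`,
`W ~ U(0, T)`, `V = W + 50`, Beta(8,2) match scores (Beta(8−z, 2+z) in
setting 5), and measurement error with SD `1.8^(1/p_match)` on equivocal
matched ages — and carries the latent truth so every method can be
scored against a fully-observed gold standard.

## Worked example

```python
import linksurv as ls

cohort = ls.draw_cohort(ls.load_setting(4, seed=7))
for method in ("gold", "cc", "ipw", "cens", "mirm", "mics"):
    est = ls.analyze_cohort(cohort, method, B=10, rng=1)
    print(method, round(est["beta1"], 3), round(est["m1"], 1))
```

prints (see `examples/compare_methods.py` for the full table):

```
method     beta1   alpha1     M1     M0
gold       1.290   -0.218   61.6   78.7
cc         1.221   -0.224   57.6   70.4
ipw        1.293   -0.230   58.4   76.0
cens       1.555   -0.251   60.3   81.8
mirm       1.234   -0.231   58.0   74.1
mics       1.398   -0.232   60.1   78.5
```

The generative values are `β₁ = 1.2`, `M₁ ≈ 63`, `M₀ ≈ 78`. In this
setting matching depends on the exposure, so censoring at the census age
(`cens`) overstates the hazard ratio (1.56), the complete case loses the
unexposed median (70.4 vs 78.7), and the conditional-survival imputation
(`mics`) stays closest to the gold standard overall.

`examples/monte_carlo_study.py` runs the paired Monte Carlo comparison
(`run_study`), and `examples/conditional_survival_imputation.py` walks
through the MICS machinery. A thin CLI mirrors the library:

```sh
linksurv simulate --setting 1 --seed 3 -o cohort.csv
linksurv analyze  --cohort cohort.csv --method mics --B 10 -o results.csv
linksurv study    --setting 2 --K 100 --methods cc,cens,mics --seed 1 -o study.csv
```

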