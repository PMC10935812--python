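"""Inside the conditional-survival imputation engine (MICS).

A Weibull AFT working model fitted to the unequivocal matches gives each
record a conditional distribution of its death age given survival to the
census age w; inverting that CDF at uniform draws yields imputed ages
that are always >= w.  Equivocal matches keep their matched age with
weight p_match and add the imputed age with weight 1 - p_match.
"""

import numpy as np

import linksurv as ls

cohort = ls.draw_cohort(ls.load_setting(2, seed=3))

fit = ls.fit_complete_case_aft(cohort, threshold=0.8)
print(f"working model: alpha = {np.round(fit.alpha, 3)}, p = {fit.shape_p:.2f}")

# invert the conditional CDF at a few percentiles for one 60-year-old
for q in (0.0, 0.25, 0.5, 0.9):
    t = ls.mics_invert(q, w=60.0, x=1, z=0, fit=fit)
    print(f"  q = {q:4.2f} -> imputed death age {t:6.2f}")

imp = ls.mics_impute(cohort, threshold=0.8, B=10, rng=11, proper=True)
print(f"records imputed per dataset : {len(imp.imputed_ids)}")

# pool the Cox log-HR across the 10 completed datasets with Rubin's rules
fits = [ls.fit_cox(d) for d in imp.datasets]
pooled = ls.rubin_pool([f.beta1 for f in fits], [f.se[0] ** 2 for f in fits])
print(f"pooled beta1 = {pooled.estimate:.3f} (se {pooled.se:.3f}, "
      f"between-imputation var {pooled.between:.4f})")
# the pooled se exceeds any single completed-data se: Rubin's total
# variance adds the between-imputation spread to the average model variance
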