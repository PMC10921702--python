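"""Prognostic evaluation of marker positivity in a simulated IHC cohort.

Dichotomises patients at the upper tertile of stain positivity, compares
progression-free interval and overall survival by log-rank test, and fits
univariable and multivariable (extent of resection + radiotherapy) Cox
models. The cohort has a planted hazard ratio of 5 for the upper tertile.
"""

from organsurf import SimConfig, simulate
from organsurf.prognosis import evaluate_cohort, site_compare, tertile_split

cfg = SimConfig(n_patients=300, true_hr=5.0, censor_rate=0.3, seed=1)
cohort, _ = simulate.generate_survival_cohort(cfg)

group = tertile_split(cohort["stain_pct"])
print(f"cohort: {len(cohort)} patients, "
      f"{(group == 'upper').sum()} in the upper stain tertile, "
      f"{1 - cohort['pfi_event'].mean():.0%} censored (PFI)")

results = evaluate_cohort(cohort)
for endpoint in ("pfi", "os"):
    r = results[endpoint]
    uni, multi = r["univariable"], r["multivariable"]
    print(f"{endpoint.upper()}: log-rank p = {r['logrank_p']:.2e}")
    print(f"  univariable   HR = {uni['hr']:.2f} "
          f"(95% CI {uni['ci'][0]:.2f}-{uni['ci'][1]:.2f}, p = {uni['p']:.2e})")
    print(f"  multivariable HR = {multi['hr']:.2f} "
          f"(95% CI {multi['ci'][0]:.2f}-{multi['ci'][1]:.2f}, p = {multi['p']:.2e})")

u, p = site_compare(cohort["stain_pct"], cohort["site"])
print(f"stain positivity, skull base vs spine: Wilcoxon rank-sum p = {p:.2f}")
# the fitted HRs should bracket the planted value of 5; positivity is
# independent of site, so the rank-sum p is uniform over repeated cohorts
# (an occasional small value is a chance finding)
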