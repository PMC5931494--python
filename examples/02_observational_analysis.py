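"""Observational association of measured 25(OH)D with incident diabetes.

Fits the adjusted continuous model (per 25 nmol/l), the tertile analysis
with floating absolute risks, and the forward-stepwise adjustment path on
a cohort with an injected 9% protective effect per 25 nmol/l.
"""

import numpy as np

import vitdmr as v
from vitdmr import presets

cfg = presets.ckb_biochemistry_config(causal_logor_per_nmol=np.log(0.91) / 25.0)
cfg.n_individuals = 13_565
cfg.baseline_outcome_logodds = v.calibrate_intercept(cfg, (496 + 979) / 13_565)
cohort = v.simulate_cohort(cfg, seed=11)

est = v.fit_continuous(cohort)  # prevalent cases excluded by default
print(f"continuous ({est.n} individuals, {est.n_cases} incident cases):")
print(" ", est.describe())
print("  injected OR was 0.91; one replicate differs by sampling noise\n")

print("tertiles with floated 95% CIs (reference carries its own CI):")
for t in v.tertile_analysis(cohort):
    print(
        f"  tertile {t.category + 1}: OR {t.or_floated:.2f} "
        f"({t.ci_low:.2f}-{t.ci_high:.2f}), {t.n_events} events"
    )

print("\nforward-stepwise adjustment (entry p <= 0.05):")
for covs, e in v.stepwise_adjust(cohort, ["body_fat", "SBP", "age", "BMI"]):
    label = "+".join(covs) if covs else "crude"
    print(f"  {label:24s} OR {e.odds_ratio:.3f} per 25 nmol/l")
# Adjusting for the confounder (body fat) moves the estimate toward the
# injected causal value; pure noise covariates rarely enter.
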