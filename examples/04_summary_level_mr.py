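"""Summary-level Mendelian randomisation on a harmonized instrument set.

Builds four instruments consistent with a 14% lower diabetes risk per
25 nmol/l, then runs the Wald/IVW primary analysis and the MR-Egger and
weighted-median sensitivity analyses.
"""

import numpy as np

import vitdmr as v

theta = np.log(0.86) / 25.0  # injected: 14% lower risk per 25 nmol/l
rng = np.random.default_rng(3)
instruments = [
    v.HarmonizedInstrument(
        snp_id=snp,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=float(rng.normal(theta * bx, 0.012)),
        se_outcome=0.012,
    )
    for snp, bx, sx in [
        ("rs12785878", 2.84, 0.41),
        ("rs10741657", 0.95, 0.42),
        ("rs2282679", 3.59, 0.44),
        ("rs6013897", 0.51, 0.56),
    ]
]

print("per-SNP Wald ratios (per 25 nmol/l):")
wald = []
for h in instruments:
    res = v.wald_ratio(h)
    wald.append(res.estimate)
    print(f"  {h.snp_id}: {res.estimate.describe()}")

pooled = v.ivw([(e.beta, e.se) for e in wald])
print(f"\nIVW: {pooled.estimate.describe()}  (Q = {pooled.heterogeneity_q:.2f})")

slope, intercept = v.egger(instruments)
print(f"Egger slope:     {slope.estimate.describe()}")
print(f"Egger intercept: beta {intercept.estimate.beta:+.4f}, "
      f"p = {intercept.estimate.p:.2f}  (directional-pleiotropy test)")

median = v.weighted_median(instruments, n_boot=2000, seed=4)
print(f"Weighted median: {median.estimate.describe()}")
# With valid instruments all three estimators agree around the injected
# OR of 0.86 and the Egger intercept is compatible with zero.
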