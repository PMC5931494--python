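"""Cross-study meta-analysis with latitude subgroups and a forest table.

Simulates the 10-study summary panel (58,312 cases in total) around a 14%
lower risk per 25 nmol/l, pools the 2-synthesis-SNP estimates by
fixed-effect inverse variance, and prints the forest table.
"""

import numpy as np

import vitdmr as v
from vitdmr import presets
from vitdmr.meta import combine_studies, forest_table, studies_to_estimates

theta = np.log(0.86) / 25.0
studies = v.simulate_study_summaries(presets.default_meta_config(theta), seed=5)
weights = {s.snp_id: s.beta_exposure for s in presets.CKB_SNPS}

per_study = studies_to_estimates(studies, presets.SYNTHESIS_SNPS, weights)
res = combine_studies(per_study, score_set="2snp_synthesis")

print(forest_table(res).round(3).to_string(index=False))
print(f"\npooled: {res.pooled.describe()}")
for name, est in sorted(res.subgroups.items()):
    print(f"  {name}: OR {est.odds_ratio:.3f} ({est.ci_low:.3f}-{est.ci_high:.3f})")
print(f"heterogeneity: Q = {res.q:.1f}, I2 = {res.i2:.0f}%")
# Fixed-effect algebra guarantees the IVW of the two subgroup estimates
# equals the overall pooled estimate; weights sum to 100%.
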