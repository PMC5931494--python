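"""Simulate a biobank-style cohort and inspect its structure.

Generates 10,000 individuals with four 25(OH)D SNPs, a latitude/season
exposure gradient and a logistic diabetes outcome, then prints the summary
statistics the generator is calibrated to reproduce.
"""

import numpy as np

import vitdmr as v
from vitdmr import presets

cfg = presets.ckb_genetic_config(causal_logor_per_nmol=np.log(0.86) / 25.0, seed=0)
cfg.n_individuals = 10_000
cfg.measured_subset_fraction = 0.5
cohort = v.simulate_cohort(cfg, seed=1)

x = cohort["exposure_true"]
print(f"n = {len(cohort)}")
print(f"25(OH)D mean (SD): {x.mean():.1f} ({x.std():.1f}) nmol/l")
by_season = cohort.groupby("season")["exposure_true"].mean()
print(f"winter vs summer:  {by_season['winter']:.1f} vs {by_season['summer']:.1f} nmol/l")
by_lat = cohort.groupby("latitude")["exposure_true"].mean()
print(f"south (20N) vs north (46N): {by_lat[20.0]:.0f} vs {by_lat[46.0]:.0f} nmol/l")
for snp in ("rs12785878", "rs10741657", "rs2282679", "rs6013897"):
    print(f"{snp}: effect-allele frequency {cohort[snp].mean() / 2:.3f}")
print(f"diabetes cases: {(cohort['diabetes_status'] != 'none').mean():.1%}")
# The exposure carries area, season, genetic and confounder structure;
# the case fraction follows the configured logistic outcome model.
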