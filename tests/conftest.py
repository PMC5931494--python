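import numpy as np
import pytest

import vitdmr as v
from vitdmr import presets


@pytest.fixture(scope="session")
def biochem_cohort():
    """Small biochemistry-style cohort with an injected protective effect."""
    cfg = presets.ckb_biochemistry_config(
        causal_logor_per_nmol=np.log(0.80) / 25.0, seed=0
    )
    cfg.n_individuals = 4000
    cfg.baseline_outcome_logodds = v.calibrate_intercept(cfg, 0.11)
    return v.simulate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def genetic_cohort():
    """Mid-sized genetic cohort (all 4 SNPs, measured subset, causal effect)."""
    cfg = presets.ckb_genetic_config(
        causal_logor_per_nmol=np.log(0.86) / 25.0, seed=0
    )
    cfg.n_individuals = 16_000
    cfg.measured_subset_fraction = 0.25
    cfg.baseline_outcome_logodds = v.calibrate_intercept(cfg, 0.067)
    return v.simulate_cohort(cfg, seed=202)


@pytest.fixture(scope="session")
def harmonized_set():
    """Four summary-level instruments consistent with a common causal slope."""
    theta = np.log(0.86) / 25.0
    rng = np.random.default_rng(7)
    out = []
    for snp, bx, sx in [
        ("rs12785878", 2.84, 0.41),
        ("rs10741657", 0.95, 0.42),
        ("rs2282679", 3.59, 0.44),
        ("rs6013897", 0.51, 0.56),
    ]:
        se_y = 0.015
        out.append(
            v.HarmonizedInstrument(
                snp_id=snp,
                beta_exposure=bx,
                se_exposure=sx,
                beta_outcome=float(rng.normal(theta * bx, se_y)),
                se_outcome=se_y,
            )
        )
    return out
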