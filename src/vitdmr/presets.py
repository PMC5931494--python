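"""Ready-made configurations mirroring the China Kadoorie Biobank substudy.

The four SNPs, their 25(OH)D-raising allele frequencies (0.46, 0.36, 0.84,
0.70) and per-allele effects on 25(OH)D (2.84, 0.95, 0.51, 3.59 nmol/l) are
the published CKB values; the 10-area latitude gradient spans 20°N (mean
~90 nmol/l) to 46°N (~49 nmol/l) with overall mean/SD 62.1/20.2 nmol/l and a
winter/summer contrast of 57.4 vs 68.4 nmol/l.

The per-study case/control counts of the 10-study meta-analysis panel are
synthetic: only the totals (58,312 cases, 370,592 controls) and the CKB
counts are published, so the remaining studies carry invented but plausible
splits.
"""

from __future__ import annotations

from .config import (
    AreaSpec,
    ConfounderSpec,
    GeneratorConfig,
    MetaSimConfig,
    SnpSpec,
    StudySpec,
)

# The two synthesis SNPs are the primary instruments; GC/DBP (transport) and
# CYP24A1 (catabolism) carry known pleiotropy concerns.
SYNTHESIS_SNPS = ("rs12785878", "rs10741657")
ALL_SNPS = ("rs12785878", "rs10741657", "rs2282679", "rs6013897")

CKB_SNPS = (
    SnpSpec("rs12785878", "DHCR7", "T", "G", 0.46, 2.84),
    SnpSpec("rs10741657", "CYP2R1", "A", "G", 0.36, 0.95),
    SnpSpec("rs2282679", "GC/DBP", "T", "G", 0.70, 3.59),
    SnpSpec("rs6013897", "CYP24A1", "A", "T", 0.84, 0.51),
)

# 10 recruitment areas from the far south (Haikou-like, 20°N) to the far
# north (Harbin-like, 46°N).  Baselines are area-mean 25(OH)D levels chosen
# to reproduce both the printed endpoints (90 and 49 nmol/l) and the overall
# mean of 62.1 nmol/l under equal area sizes.
CKB_AREAS = (
    AreaSpec("area_01", 20.0, 90.0),
    AreaSpec("area_02", 23.0, 71.0),
    AreaSpec("area_03", 26.0, 66.0),
    AreaSpec("area_04", 29.0, 63.0),
    AreaSpec("area_05", 31.0, 61.0),
    AreaSpec("area_06", 33.0, 58.0),
    AreaSpec("area_07", 36.0, 57.0),
    AreaSpec("area_08", 39.0, 55.0),
    AreaSpec("area_09", 43.0, 51.0),
    AreaSpec("area_10", 46.0, 49.0),
)

# Baseline covariate distributions follow the published cohort characteristics
# (age 51.4 (10.6) y truncated to the 30-79 recruitment window, 60.5% women,
# BMI 23.7 (3.4), SBP 131.2 (21.3), DBP 77.8 (11.2), glucose 6.1 (2.4)).
# A mild body-fat confounding path (into both exposure and outcome) is on by
# default so that crude and adjusted observational estimates differ.
CKB_CONFOUNDERS = (
    ConfounderSpec("age", ("truncnormal", 51.4, 10.6, 30.0, 79.0),
                   beta_outcome=0.045),
    ConfounderSpec("sex", ("bernoulli", 0.605), beta_outcome=-0.10),
    ConfounderSpec("SBP", ("normal", 131.2, 21.3), beta_outcome=0.012),
    ConfounderSpec("DBP", ("normal", 77.8, 11.2)),
    ConfounderSpec("BMI", ("normal", 23.7, 3.4)),
    ConfounderSpec("WHR", ("normal", 0.88, 0.07)),
    ConfounderSpec("body_fat", ("normal", 26.0, 7.0),
                   beta_exposure=-0.15, beta_outcome=0.045),
    ConfounderSpec("physical_activity", ("truncnormal", 20.0, 10.0, 0.0, 60.0),
                   beta_outcome=-0.01),
    ConfounderSpec("random_glucose", ("truncnormal", 6.1, 2.4, 2.0, 30.0)),
)


def ckb_genetic_config(
    causal_logor_per_nmol: float = 0.0,
    seed: int = 0,
    baseline_outcome_logodds: float = -2.72,
) -> GeneratorConfig:
    """Configuration for the CKB-scale genetic cohort.

    n = 82,464 genotyped individuals, of whom a ~3.7% subset (matching the
    3,014 with both genotypes and assays) carries a measured 25(OH)D value;
    diabetes prevalence ~6.7% (5,566 cases) including prevalent cases.
    """
    return GeneratorConfig(
        n_individuals=82_464,
        snp_specs=CKB_SNPS,
        areas=CKB_AREAS,
        season_effect=11.0,
        exposure_residual_sd=16.0,
        causal_logor_per_nmol=causal_logor_per_nmol,
        confounder_specs=CKB_CONFOUNDERS,
        baseline_outcome_logodds=baseline_outcome_logodds,
        measured_subset_fraction=3_014 / 82_464,
        seed=seed,
    )


def ckb_biochemistry_config(
    causal_logor_per_nmol: float = 0.0,
    seed: int = 0,
    baseline_outcome_logodds: float = -2.20,
) -> GeneratorConfig:
    """Configuration for the measured-25(OH)D cohort used observationally.

    n = 13,565 with assays; ~10.9% are diabetes cases of which roughly a
    third are prevalent at baseline, leaving ~979 incident cases among
    ~13,069 after the prevalent exclusion.
    """
    return GeneratorConfig(
        n_individuals=13_565,
        snp_specs=CKB_SNPS,
        areas=CKB_AREAS,
        season_effect=11.0,
        exposure_residual_sd=16.0,
        causal_logor_per_nmol=causal_logor_per_nmol,
        confounder_specs=CKB_CONFOUNDERS,
        baseline_outcome_logodds=baseline_outcome_logodds,
        measured_subset_fraction=1.0,
        seed=seed,
    )


# Synthetic 10-study meta-analysis panel.  Totals match the published primary
# analysis (58,312 cases, 370,592 controls) and the CKB row is exact; the
# other splits are invented.  Three studies lack the catabolism SNP, leaving
# 7 studies for the 4-SNP analysis.
DEFAULT_STUDIES = (
    StudySpec("CKB", 33.0, 5_566, 76_898, ALL_SNPS),
    StudySpec("UK Biobank", 54.0, 18_607, 154_332, ALL_SNPS),
    StudySpec("DIAGRAM", 45.0, 12_171, 56_862,
              ("rs12785878", "rs10741657", "rs2282679")),
    StudySpec("T2D Exome", 42.0, 8_500, 30_000, ALL_SNPS),
    StudySpec("EPIC-InterAct-gwas", 48.0, 5_000, 9_000, ALL_SNPS),
    StudySpec("EPIC-InterAct-metabochip", 48.0, 3_500, 8_000, ALL_SNPS),
    StudySpec("Copenhagen", 56.0, 2_447, 25_000, ALL_SNPS),
    StudySpec("Norfolk Diabetes", 52.6, 1_500, 8_000, ALL_SNPS),
    StudySpec("CCCS", 52.2, 500, 1_000,
              ("rs12785878", "rs10741657", "rs2282679")),
    StudySpec("ADDITION-Ely", 52.4, 521, 1_500,
              ("rs12785878", "rs10741657", "rs2282679")),
)


def default_meta_config(
    causal_logor_per_nmol: float = 0.0, seed: int = 0
) -> MetaSimConfig:
    """Ten-study summary-statistics simulation at published total case counts."""
    return MetaSimConfig(
        studies=DEFAULT_STUDIES,
        snp_specs=CKB_SNPS,
        causal_logor_per_nmol=causal_logor_per_nmol,
        seed=seed,
    )
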