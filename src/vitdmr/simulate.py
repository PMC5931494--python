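"""Synthetic individual-level cohorts and study-level summary statistics.

The generator emulates a large population-based biobank: independent
bi-allelic SNPs in Hardy–Weinberg equilibrium, a plasma 25(OH)D exposure with
area (latitude), season, genetic and confounder structure, and a binary
diabetes outcome driven by a logistic model in which the causal effect of
25(OH)D and per-SNP direct (pleiotropic) effects are injected explicitly.
Every public function is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import GeneratorConfig, InvalidConfigError, MetaSimConfig

SEASONS = ("winter", "spring", "summer", "autumn")
# Season effects as a fraction of the winter->summer contrast; the two
# shoulder seasons sit halfway.
_SEASON_LEVEL = {"winter": 0.0, "spring": 0.5, "summer": 1.0, "autumn": 0.5}

__all__ = [
    "simulate_genotypes",
    "draw_covariates",
    "simulate_exposure",
    "simulate_outcome",
    "simulate_cohort",
    "calibrate_intercept",
    "simulate_study_summaries",
    "write_cohort",
    "read_cohort",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genotypes(freqs, n: int, seed, snp_ids=None) -> pd.DataFrame:
    """Draw Hardy–Weinberg genotype dosages, iid Binomial(2, p) per SNP.

    Parameters
    ----------
    freqs : sequence of float
        Effect-allele frequencies, each in the open interval (0, 1).
    n : int
        Number of individuals (rows).
    seed : int or numpy Generator
    snp_ids : optional sequence of column names (defaults to ``snp_1`` ...).
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    freqs = list(freqs)
    for p in freqs:
        if not 0.0 < p < 1.0:
            raise InvalidConfigError(f"allele frequency {p} outside (0,1)")
    rng = _rng(seed)
    if snp_ids is None:
        snp_ids = [f"snp_{j + 1}" for j in range(len(freqs))]
    data = {
        sid: rng.binomial(2, p, size=n).astype(np.int8)
        for sid, p in zip(snp_ids, freqs)
    }
    return pd.DataFrame(data)


def _draw_confounder(spec, n, rng):
    kind = spec.dist[0]
    if kind == "normal":
        _, mu, sd = spec.dist
        return rng.normal(mu, sd, size=n)
    if kind == "truncnormal":
        _, mu, sd, lo, hi = spec.dist
        x = rng.normal(mu, sd, size=n)
        # redraw out-of-range values; the windows used here keep this cheap
        bad = (x < lo) | (x > hi)
        while bad.any():
            x[bad] = rng.normal(mu, sd, size=int(bad.sum()))
            bad = (x < lo) | (x > hi)
        return x
    if kind == "bernoulli":
        _, p = spec.dist
        return rng.binomial(1, p, size=n).astype(float)
    raise InvalidConfigError(f"unknown confounder distribution {kind!r}")


def draw_covariates(config: GeneratorConfig, n: int, seed) -> pd.DataFrame:
    """Assign areas (with latitude), seasons and confounder covariates."""
    rng = _rng(seed)
    areas = list(config.areas)
    idx = rng.integers(0, len(areas), size=n)
    cov = pd.DataFrame(
        {
            "area_id": [areas[i].area_id for i in idx],
            "latitude": np.array([areas[i].latitude for i in idx]),
            "season": rng.choice(SEASONS, size=n),
        }
    )
    cov["_area_baseline"] = np.array([areas[i].baseline_exposure for i in idx])
    for spec in config.confounder_specs:
        cov[spec.name] = _draw_confounder(spec, n, rng)
    return cov


def _genetic_term(genotypes: pd.DataFrame, config: GeneratorConfig):
    """Centred genetic contribution sum_j beta_Xj (g_j - 2 p_j)."""
    term = np.zeros(len(genotypes))
    for s in config.snp_specs:
        if s.snp_id in genotypes.columns:
            term += s.beta_exposure * (
                genotypes[s.snp_id].to_numpy(dtype=float)
                - 2.0 * s.effect_allele_freq
            )
    return term


def _confounder_exposure_term(covariates, config):
    term = np.zeros(len(covariates))
    for spec in config.confounder_specs:
        if spec.beta_exposure != 0.0:
            x = covariates[spec.name].to_numpy(dtype=float)
            term += spec.beta_exposure * (x - x.mean())
    return term


def simulate_exposure(
    genotypes: pd.DataFrame,
    config: GeneratorConfig,
    seed,
    covariates: pd.DataFrame | None = None,
) -> np.ndarray:
    """Plasma 25(OH)D per individual (nmol/l).

    exposure = area baseline + centred season term + centred genetic term
    + centred confounder terms + Normal(0, residual_sd).  Centring makes the
    configured area baselines the area means, so a single-area configuration
    with baseline 62.1 yields a cohort mean of 62.1 nmol/l regardless of the
    genetic betas.
    """
    if config.exposure_residual_sd < 0:
        raise InvalidConfigError("exposure_residual_sd must be >= 0")
    rng = _rng(seed)
    n = len(genotypes)
    if covariates is None:
        covariates = draw_covariates(config, n, rng)
    if len(covariates) != n:
        raise InvalidConfigError("genotype and covariate tables disagree on n")
    season_level = covariates["season"].map(_SEASON_LEVEL).to_numpy(dtype=float)
    season_term = config.season_effect * (season_level - 0.5)
    exposure = (
        covariates["_area_baseline"].to_numpy(dtype=float)
        + season_term
        + _genetic_term(genotypes, config)
        + _confounder_exposure_term(covariates, config)
    )
    if config.exposure_residual_sd > 0:
        exposure = exposure + rng.normal(0.0, config.exposure_residual_sd, size=n)
    return exposure


def _outcome_linear_predictor(exposure, genotypes, covariates, config):
    """Everything in the outcome logit except the intercept."""
    lp = config.causal_logor_per_nmol * (
        np.asarray(exposure, dtype=float) - config.exposure_reference
    )
    for s in config.snp_specs:
        if s.direct_outcome_logor != 0.0 and s.snp_id in genotypes.columns:
            lp += s.direct_outcome_logor * (
                genotypes[s.snp_id].to_numpy(dtype=float)
                - 2.0 * s.effect_allele_freq
            )
    for spec in config.confounder_specs:
        if spec.beta_outcome != 0.0:
            x = covariates[spec.name].to_numpy(dtype=float)
            lp += spec.beta_outcome * (x - x.mean())
    return lp


def simulate_outcome(
    exposure,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    config: GeneratorConfig,
    seed,
) -> np.ndarray:
    """Diabetes status per individual: ``none``, ``prevalent`` or ``incident``.

    P(case) = logistic(intercept + causal term + direct SNP terms +
    confounder terms); a configured fraction of cases is labelled prevalent
    (diagnosed before baseline), the remainder incident.
    """
    if not np.isfinite(config.causal_logor_per_nmol):
        raise InvalidConfigError("causal_logor_per_nmol must be finite")
    if not np.isfinite(config.baseline_outcome_logodds):
        raise InvalidConfigError("baseline_outcome_logodds must be finite")
    rng = _rng(seed)
    lp = config.baseline_outcome_logodds + _outcome_linear_predictor(
        exposure, genotypes, covariates, config
    )
    case = rng.random(len(lp)) < expit(lp)
    status = np.full(len(lp), "none", dtype=object)
    prevalent = case & (rng.random(len(lp)) < config.prevalent_fraction)
    status[case] = "incident"
    status[prevalent] = "prevalent"
    return status


def simulate_cohort(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Generate a full cohort table.

    Columns: one dosage column per SNP, ``exposure_true``,
    ``exposure_measured`` (NaN outside the measured subset), ``area_id``,
    ``latitude``, ``season``, the configured covariates, and
    ``diabetes_status``.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_individuals
    genotypes = simulate_genotypes(
        [s.effect_allele_freq for s in config.snp_specs],
        n,
        rng,
        snp_ids=[s.snp_id for s in config.snp_specs],
    )
    if config.freq_latitude_slope != 0.0:
        # optional allele-frequency gradient with latitude, redrawn per area
        lat_mean = float(np.mean([a.latitude for a in config.areas]))
        cov = draw_covariates(config, n, rng)
        lat = cov["latitude"].to_numpy()
        for s in config.snp_specs:
            p_i = np.clip(
                s.effect_allele_freq
                + config.freq_latitude_slope * (lat - lat_mean),
                0.01,
                0.99,
            )
            genotypes[s.snp_id] = rng.binomial(2, p_i).astype(np.int8)
    else:
        cov = draw_covariates(config, n, rng)
    exposure_true = simulate_exposure(genotypes, config, rng, covariates=cov)
    status = simulate_outcome(exposure_true, genotypes, cov, config, rng)

    n_measured = int(round(config.measured_subset_fraction * n))
    measured_idx = rng.choice(n, size=n_measured, replace=False)
    measured = np.zeros(n, dtype=bool)
    measured[measured_idx] = True
    exposure_measured = np.full(n, np.nan)
    exposure_measured[measured] = (
        config.assay_bias_factor * exposure_true[measured]
    )
    if config.assay_sd > 0:
        exposure_measured[measured] += rng.normal(
            0.0, config.assay_sd, size=n_measured
        )

    table = cov.drop(columns=["_area_baseline"]).copy()
    for s in config.snp_specs:
        table[s.snp_id] = genotypes[s.snp_id].to_numpy()
    table["exposure_true"] = exposure_true
    table["exposure_measured"] = exposure_measured
    table["diabetes_status"] = status
    return table


def calibrate_intercept(
    config: GeneratorConfig,
    target_case_fraction: float,
    calibration_seed: int = 987_654,
) -> float:
    """Intercept such that the expected case fraction matches the target.

    Draws one calibration cohort's non-intercept linear predictor (with its
    own fixed seed, independent of analysis seeds) and solves
    mean(logistic(b0 + lp)) = target by bisection.  Deterministic.
    """
    if not 0.0 < target_case_fraction < 1.0:
        raise InvalidConfigError("target_case_fraction must be in (0,1)")
    rng = np.random.default_rng(calibration_seed)
    n = config.n_individuals
    genotypes = simulate_genotypes(
        [s.effect_allele_freq for s in config.snp_specs],
        n,
        rng,
        snp_ids=[s.snp_id for s in config.snp_specs],
    )
    cov = draw_covariates(config, n, rng)
    exposure = simulate_exposure(genotypes, config, rng, covariates=cov)
    lp = _outcome_linear_predictor(exposure, genotypes, cov, config)

    def gap(b0):
        return float(np.mean(expit(b0 + lp))) - target_case_fraction

    lo, hi = logit(target_case_fraction) - 10.0, logit(target_case_fraction) + 10.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate_study_summaries(meta_config: MetaSimConfig, seed=None) -> pd.DataFrame:
    """Per-study per-SNP outcome summary statistics for K studies.

    Each study's per-allele log OR for an available SNP is drawn about
    causal_logor_per_nmol * beta_Xj + direct_j with the standard
    case–control standard error sqrt((1/cases + 1/controls) / (2 p (1-p))),
    which shrinks as the counts grow.
    """
    meta_config.validate()
    if seed is None:
        seed = meta_config.seed
    rng = np.random.default_rng(seed)
    specs = {s.snp_id: s for s in meta_config.snp_specs}
    rows = []
    for st in meta_config.studies:
        for snp_id in st.available_snps:
            s = specs[snp_id]
            true_logor = (
                meta_config.causal_logor_per_nmol * s.beta_exposure
                + s.direct_outcome_logor
            )
            p = s.effect_allele_freq
            se = np.sqrt(
                (1.0 / st.n_cases + 1.0 / st.n_controls) / (2.0 * p * (1.0 - p))
            )
            rows.append(
                {
                    "study_id": st.study_id,
                    "latitude_deg": st.latitude,
                    "latitude_class": "northern" if st.latitude > 50 else "southern",
                    "n_cases": st.n_cases,
                    "n_controls": st.n_controls,
                    "snp_id": snp_id,
                    "gene": s.gene,
                    "effect_allele": s.effect_allele,
                    "other_allele": s.other_allele,
                    "effect_allele_freq": p,
                    "beta_outcome": rng.normal(true_logor, se),
                    "se_outcome": se,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV I/O (tab-separated, UTF-8, "." decimal, "NA" missing — used everywhere)

def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
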