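"""Configuration objects for the synthetic cohort and study-summary generators.

Everything the generator does is driven by a :class:`GeneratorConfig`; the
defaults (see :mod:`vitdmr.presets`) reproduce the structure of the China
Kadoorie Biobank genetic substudy: four independent 25(OH)D SNPs, a 10-area
latitude gradient, a winter/summer season contrast and a measured-exposure
subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class SnpSpec:
    """One SNP instrument: identity, frequency and its effect pathways.

    Parameters
    ----------
    snp_id : str
        Column name used for the dosage in cohort tables (e.g. ``rs12785878``).
    gene : str
        Gene label (``DHCR7``, ``CYP2R1``, ``GC/DBP``, ``CYP24A1``).
    effect_allele, other_allele : str
        The effect allele is the 25(OH)D-raising allele.
    effect_allele_freq : float
        Population frequency of the effect allele, in (0, 1).
    beta_exposure : float
        Per-allele effect on plasma 25(OH)D, nmol/l.
    direct_outcome_logor : float
        Per-allele direct (pleiotropic) effect on diabetes log-odds, i.e. a
        pathway bypassing 25(OH)D. Zero for a valid instrument.
    """

    snp_id: str
    gene: str
    effect_allele: str
    other_allele: str
    effect_allele_freq: float
    beta_exposure: float
    direct_outcome_logor: float = 0.0

    def validate(self) -> None:
        if not 0.0 < self.effect_allele_freq < 1.0:
            raise InvalidConfigError(
                f"{self.snp_id}: effect_allele_freq must lie in (0,1), "
                f"got {self.effect_allele_freq}"
            )


@dataclass(frozen=True)
class AreaSpec:
    """A recruitment area: identifier, latitude (degrees N) and the mean
    25(OH)D level (nmol/l) of its residents."""

    area_id: str
    latitude: float
    baseline_exposure: float


@dataclass(frozen=True)
class ConfounderSpec:
    """A covariate with optional arrows into exposure and outcome.

    ``dist`` is ``("normal", mean, sd)``, ``("truncnormal", mean, sd, lo, hi)``
    or ``("bernoulli", p)``.  ``beta_exposure`` is nmol/l per unit,
    ``beta_outcome`` log-odds per unit; non-zero values in both make the
    covariate a genuine confounder.
    """

    name: str
    dist: tuple
    beta_exposure: float = 0.0
    beta_outcome: float = 0.0


@dataclass
class GeneratorConfig:
    """Full description of one synthetic cohort.

    The exposure model is

        25(OH)D = area baseline + season term + sum_j beta_Xj (g_j - 2 p_j)
                  + confounder terms (centred) + N(0, exposure_residual_sd),

    so configured area baselines are the area means.  The outcome model is

        logit P(case) = baseline_outcome_logodds
                        + causal_logor_per_nmol * (25(OH)D - 62.1)
                        + sum_j direct_j g_j + confounder terms (centred).

    Centring keeps ``baseline_outcome_logodds`` interpretable as the
    logit of the overall case fraction at average covariate values.
    """

    n_individuals: int
    snp_specs: Sequence[SnpSpec]
    areas: Sequence[AreaSpec]
    season_effect: float = 11.0  # winter -> summer contrast, nmol/l
    exposure_residual_sd: float = 15.9
    causal_logor_per_nmol: float = 0.0
    confounder_specs: Sequence[ConfounderSpec] = field(default_factory=tuple)
    baseline_outcome_logodds: float = -2.63
    measured_subset_fraction: float = 1.0
    prevalent_fraction: float = 496.0 / (496.0 + 979.0)
    exposure_reference: float = 62.1  # centring point for the causal term
    assay_sd: float = 0.0  # additive measurement error on measured 25(OH)D
    assay_bias_factor: float = 1.0  # optional multiplicative assay bias
    freq_latitude_slope: float = 0.0  # optional allele-freq gradient per degree
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise InvalidConfigError("n_individuals must be >= 1")
        if not self.snp_specs:
            raise InvalidConfigError("at least one SNP spec is required")
        for s in self.snp_specs:
            s.validate()
        if not self.areas:
            raise InvalidConfigError("at least one area is required")
        if self.exposure_residual_sd < 0:
            raise InvalidConfigError("exposure_residual_sd must be >= 0")
        if not 0.0 < self.measured_subset_fraction <= 1.0:
            raise InvalidConfigError("measured_subset_fraction must be in (0,1]")
        if not 0.0 <= self.prevalent_fraction <= 1.0:
            raise InvalidConfigError("prevalent_fraction must be in [0,1]")


@dataclass(frozen=True)
class StudySpec:
    """One study contributing outcome-side summary statistics."""

    study_id: str
    latitude: float
    n_cases: int
    n_controls: int
    available_snps: tuple  # snp_ids carried by the study


@dataclass
class MetaSimConfig:
    """Configuration for simulating per-study per-SNP summary statistics."""

    studies: Sequence[StudySpec]
    snp_specs: Sequence[SnpSpec]
    causal_logor_per_nmol: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.studies) < 1:
            raise InvalidConfigError("at least one study is required")
        for st in self.studies:
            if st.n_cases < 1 or st.n_controls < 1:
                raise InvalidConfigError(
                    f"{st.study_id}: case/control counts must be >= 1"
                )
        for s in self.snp_specs:
            s.validate()


# ---------------------------------------------------------------------------
# YAML round-trip

def _to_plain(obj):
    import numpy as np

    if isinstance(obj, (SnpSpec, AreaSpec, ConfounderSpec, StudySpec)):
        d = asdict(obj)
        return {k: _to_plain(v) for k, v in d.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def save_config(config: GeneratorConfig, path) -> None:
    """Write a GeneratorConfig as a YAML document."""
    doc = {k: _to_plain(v) for k, v in asdict(config).items()}
    doc["snp_specs"] = [_to_plain(s) for s in config.snp_specs]
    doc["areas"] = [_to_plain(a) for a in config.areas]
    doc["confounder_specs"] = [_to_plain(c) for c in config.confounder_specs]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> GeneratorConfig:
    """Read a GeneratorConfig from YAML and validate it."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    cfg = GeneratorConfig(
        n_individuals=int(doc["n_individuals"]),
        snp_specs=tuple(SnpSpec(**s) for s in doc["snp_specs"]),
        areas=tuple(AreaSpec(**a) for a in doc["areas"]),
        season_effect=float(doc.get("season_effect", 11.0)),
        exposure_residual_sd=float(doc.get("exposure_residual_sd", 15.9)),
        causal_logor_per_nmol=float(doc.get("causal_logor_per_nmol", 0.0)),
        confounder_specs=tuple(
            ConfounderSpec(
                name=c["name"],
                dist=tuple(c["dist"]),
                beta_exposure=float(c.get("beta_exposure", 0.0)),
                beta_outcome=float(c.get("beta_outcome", 0.0)),
            )
            for c in doc.get("confounder_specs", [])
        ),
        baseline_outcome_logodds=float(doc.get("baseline_outcome_logodds", -2.63)),
        measured_subset_fraction=float(doc.get("measured_subset_fraction", 1.0)),
        prevalent_fraction=float(doc.get("prevalent_fraction", 496.0 / 1475.0)),
        exposure_reference=float(doc.get("exposure_reference", 62.1)),
        assay_sd=float(doc.get("assay_sd", 0.0)),
        assay_bias_factor=float(doc.get("assay_bias_factor", 1.0)),
        freq_latitude_slope=float(doc.get("freq_latitude_slope", 0.0)),
        seed=int(doc.get("seed", 0)),
    )
    cfg.validate()
    return cfg
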