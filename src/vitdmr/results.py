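"""Result containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._fits import Z975


@dataclass(frozen=True)
class Estimate:
    """An effect on the log odds-ratio scale with its Wald inference.

    ``unit`` records the scale the effect is expressed on (``per-allele``,
    ``per-25-nmol/l``, ``per-tertile`` ...); ``method`` labels the procedure
    that produced it.
    """

    beta: float
    se: float
    unit: str
    method: str
    n: int | None = None
    n_cases: int | None = None

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"standard error must be positive, got {self.se}")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z975 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z975 * self.se))

    @property
    def p(self) -> float:
        return float(2.0 * norm.sf(abs(self.beta) / self.se))

    @property
    def percent_lower_risk(self) -> float:
        """100 * (1 - OR): the '14% lower risk' reading of an odds ratio."""
        return 100.0 * (1.0 - self.odds_ratio)

    def describe(self) -> str:
        return (
            f"{self.method}: OR {self.odds_ratio:.3f} "
            f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}) {self.unit}, "
            f"p={self.p:.3g}"
        )


@dataclass(frozen=True)
class FloatedRisk:
    """One exposure category under the floated-absolute-risk presentation.

    Every category — including the reference, whose odds ratio is 1 by
    convention — carries its own floated standard error, so each category
    can be plotted with its own confidence interval.
    """

    category: int
    n_events: int
    or_floated: float
    se_floated: float

    def __post_init__(self):
        if not self.se_floated > 0:
            raise ValueError("floated standard error must be positive")

    @property
    def ci_low(self) -> float:
        return float(self.or_floated * np.exp(-Z975 * self.se_floated))

    @property
    def ci_high(self) -> float:
        return float(self.or_floated * np.exp(Z975 * self.se_floated))


@dataclass(frozen=True)
class SnpInstrument:
    """Exposure-side summary for one SNP, oriented so the effect allele
    raises 25(OH)D (beta_exposure > 0 after orientation)."""

    snp_id: str
    gene: str
    effect_allele: str
    other_allele: str
    effect_allele_freq: float
    beta_exposure: float
    se_exposure: float

    def __post_init__(self):
        if not self.se_exposure > 0:
            raise ValueError("se_exposure must be positive")

    @property
    def oriented(self) -> bool:
        return self.beta_exposure > 0


def orient(instr: SnpInstrument) -> SnpInstrument:
    """Flip alleles so the effect allele raises the exposure. Idempotent."""
    if instr.beta_exposure >= 0:
        return instr
    return SnpInstrument(
        snp_id=instr.snp_id,
        gene=instr.gene,
        effect_allele=instr.other_allele,
        other_allele=instr.effect_allele,
        effect_allele_freq=1.0 - instr.effect_allele_freq,
        beta_exposure=-instr.beta_exposure,
        se_exposure=instr.se_exposure,
    )


@dataclass(frozen=True)
class ScoreModel:
    """A weighted allele score and its first-stage strength.

    The score is S = sum_j w_j g_j / mean(w), which puts S back on an
    "allele count" scale so that ``per_allele_effect`` (the slope of
    25(OH)D on S, nmol/l) is comparable to single-SNP per-allele effects.
    """

    snp_ids: tuple
    weights: dict  # snp_id -> nmol/l per allele
    per_allele_effect: float
    se_per_allele_effect: float
    f_statistic: float

    @property
    def strong(self) -> bool:
        """Conventional weak-instrument screen: F > 10."""
        return self.f_statistic > 10.0


@dataclass(frozen=True)
class MrResult:
    """One Mendelian-randomisation estimate plus method bookkeeping."""

    method: str  # wald | ivw | egger_slope | egger_intercept | weighted_median | score_iv
    estimate: Estimate
    n_snps: int
    heterogeneity_q: float | None = None
    bootstrap_reps: int | None = None


@dataclass(frozen=True)
class MetaResult:
    """Pooled cross-study result with latitude subgroups."""

    score_set: str
    pooled: Estimate
    per_study: object  # DataFrame: study_id, latitude_class, beta, se
    subgroups: dict = field(default_factory=dict)  # class -> Estimate
    q: float = 0.0
    i2: float = 0.0
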