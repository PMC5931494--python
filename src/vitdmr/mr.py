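"""Summary-level and score-based Mendelian-randomisation estimators.

All causal estimates are expressed per 25-nmol/l higher 25(OH)D, the scale
the field reports vitamin D effects on.  Inputs must already be oriented to
the exposure-raising allele (beta_exposure > 0); this module refuses
unoriented instruments rather than silently flipping them.

Estimators
----------
- ``wald_ratio``:    single-SNP ratio estimate (delta-method SE).
- ``ivw``:           fixed-effect inverse-variance-weighted combination.
- ``egger``:         weighted regression with a free intercept; the
                     intercept p-value tests directional pleiotropy.
- ``weighted_median``: consistent when instruments carrying < 50% of the
                     weight are invalid; bootstrap SE.
- ``score_iv``:      individual-level weighted-allele-score instrumental
                     variable estimate (area-stratified logistic fits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._fits import Z975, design_matrix, fit_logit, ivw_combine, stratified_coefficient
from .results import Estimate, MrResult, ScoreModel

PER_UNIT = 25.0  # nmol/l reporting unit for causal effects


class OrientationError(ValueError):
    """An instrument's exposure effect is not positive (not oriented)."""


class WeakInstrumentError(ValueError):
    """The exposure effect is too small for a stable ratio estimate."""


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Per-SNP exposure and outcome effects on the same effect allele."""

    snp_id: str
    beta_exposure: float  # nmol/l per allele, > 0 after orientation
    se_exposure: float
    beta_outcome: float  # log OR per allele, exposure-raising allele
    se_outcome: float

    def __post_init__(self):
        if self.beta_exposure <= 0:
            raise OrientationError(
                f"{self.snp_id}: beta_exposure must be > 0 (orient first)"
            )
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


def ci_to_se(or_point: float, ci_low: float, ci_high: float) -> float:
    """Recover the SE of a log odds ratio from its printed 95% CI."""
    if not (ci_low > 0 and or_point > 0 and ci_high > 0):
        raise ValueError("odds ratio and CI bounds must be positive")
    if not ci_low <= or_point <= ci_high:
        raise ValueError("CI bounds must bracket the point estimate")
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * Z975)
    if se == 0.0:
        warnings.warn("degenerate CI (zero width): se = 0")
    return float(se)


def scale_per_25(
    beta_per_allele: float,
    se: float,
    beta_exposure_per_allele: float,
    method: str = "scaled",
) -> Estimate:
    """Rescale a per-allele log OR to a per-25-nmol/l log OR.

    First-order scaling: both the effect and its SE are multiplied by
    25 / beta_exposure; the exposure-side sampling uncertainty is ignored
    (appropriate when the first stage is strong, F >> 10).
    """
    if beta_exposure_per_allele <= 0:
        raise OrientationError("beta_exposure must be > 0 (orient first)")
    factor = PER_UNIT / beta_exposure_per_allele
    return Estimate(
        beta=beta_per_allele * factor,
        se=se * factor,
        unit="per-25-nmol/l",
        method=method,
    )


def wald_ratio(
    instr: HarmonizedInstrument,
    min_beta_exposure: float = 0.1,
    second_order: bool = False,
) -> MrResult:
    """Single-instrument ratio estimate, per 25 nmol/l.

    beta = 25 * beta_outcome / beta_exposure.  The default SE is the
    first-order delta method 25 * se_outcome / beta_exposure; with
    ``second_order`` the exposure-side variance term
    beta_outcome^2 se_exposure^2 / beta_exposure^4 is added.
    """
    if instr.beta_exposure < min_beta_exposure:
        raise WeakInstrumentError(
            f"{instr.snp_id}: beta_exposure {instr.beta_exposure} below "
            f"minimum {min_beta_exposure} nmol/l"
        )
    beta = PER_UNIT * instr.beta_outcome / instr.beta_exposure
    var = instr.se_outcome**2 / instr.beta_exposure**2
    if second_order:
        var += (
            instr.beta_outcome**2
            * instr.se_exposure**2
            / instr.beta_exposure**4
        )
    se = PER_UNIT * float(np.sqrt(var))
    return MrResult(
        method="wald",
        estimate=Estimate(beta=beta, se=se, unit="per-25-nmol/l", method="wald"),
        n_snps=1,
    )


def ivw(estimates, unit: str = "per-25-nmol/l") -> MrResult:
    """Fixed-effect inverse-variance-weighted pooling of (beta, se) pairs."""
    pairs = [(float(b), float(s)) for b, s in estimates]
    if len(pairs) < 2:
        raise ValueError("ivw requires at least 2 estimates")
    betas = [b for b, _ in pairs]
    ses = [s for _, s in pairs]
    if any(s <= 0 for s in ses):
        raise ValueError("all standard errors must be positive")
    beta, se, q = ivw_combine(betas, ses)
    return MrResult(
        method="ivw",
        estimate=Estimate(beta=beta, se=se, unit=unit, method="ivw"),
        n_snps=len(pairs),
        heterogeneity_q=q,
    )


def egger(instruments) -> tuple[MrResult, MrResult]:
    """MR-Egger regression: slope (causal effect) and intercept (pleiotropy).

    Weighted regression of beta_outcome on beta_exposure with a free
    intercept and weights 1/se_outcome^2.  SEs carry the multiplicative
    random-effects inflation max(1, sqrt(RSS_w / (J - 2))).  The slope is
    reported per 25 nmol/l; the intercept stays per-allele and its p-value
    is the directional-pleiotropy test.
    """
    instruments = list(instruments)
    j = len(instruments)
    if j < 3:
        raise ValueError(
            "MR-Egger needs >= 3 instruments (a 2-point weighted fit is exact)"
        )
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    w = 1.0 / np.array([i.se_outcome for i in instruments]) ** 2
    X = sm.add_constant(bx)
    res = sm.WLS(by, X, weights=w).fit()
    intercept, slope = res.params
    # multiplicative overdispersion, never deflating below the FE model
    rss = float(np.sum(w * res.resid**2))
    phi = max(1.0, np.sqrt(rss / (j - 2)))
    base_cov = np.asarray(res.cov_params()) / res.scale  # unit-scale covariance
    se_intercept, se_slope = phi * np.sqrt(np.diag(base_cov))
    slope_res = MrResult(
        method="egger_slope",
        estimate=Estimate(
            beta=PER_UNIT * slope,
            se=PER_UNIT * float(se_slope),
            unit="per-25-nmol/l",
            method="egger_slope",
        ),
        n_snps=j,
    )
    intercept_res = MrResult(
        method="egger_intercept",
        estimate=Estimate(
            beta=float(intercept),
            se=float(se_intercept),
            unit="per-allele",
            method="egger_intercept",
        ),
        n_snps=j,
    )
    return slope_res, intercept_res


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative weights placed at
    p_i = (cumsum(w) - w_i/2) / sum(w), linear interpolation to 0.5."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= p[0]:
        return float(v[0])
    if 0.5 >= p[-1]:
        return float(v[-1])
    return float(np.interp(0.5, p, v))


def weighted_median(instruments, n_boot: int = 2000, seed: int = 0) -> MrResult:
    """Weighted-median MR estimate with a parametric-bootstrap SE.

    Per-SNP Wald ratios are ordered and weighted by their inverse
    variances; the estimate interpolates the weighted CDF at 0.5.  The SE
    comes from resampling (beta_outcome, beta_exposure) from their normal
    sampling distributions ``n_boot`` times (seeded).
    """
    instruments = list(instruments)
    if len(instruments) < 2:
        raise ValueError("weighted median requires >= 2 instruments")
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sx = np.array([i.se_exposure for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])

    def estimate(bx_, by_):
        ratios = PER_UNIT * by_ / bx_
        var = PER_UNIT**2 * (sy**2 / bx_**2 + by_**2 * sx**2 / bx_**4)
        w = 1.0 / var
        if np.sum(w) <= 0:
            raise ValueError("zero total weight")
        return _weighted_median(ratios, w)

    point = estimate(bx, by)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        boots[b] = estimate(np.where(bx_b > 0, bx_b, bx), by_b)
    se = float(np.std(boots, ddof=1))
    return MrResult(
        method="weighted_median",
        estimate=Estimate(
            beta=point, se=se, unit="per-25-nmol/l", method="weighted_median"
        ),
        n_snps=len(instruments),
        bootstrap_reps=n_boot,
    )


def allele_score(genotypes: pd.DataFrame, weights: dict) -> np.ndarray:
    """Weighted allele score S = sum_j w_j g_j / mean(w) (allele-count scale)."""
    snp_ids = list(weights)
    missing = [s for s in snp_ids if s not in genotypes.columns]
    if missing:
        raise KeyError(f"missing SNP columns: {missing}")
    w = np.array([weights[s] for s in snp_ids], dtype=float)
    G = genotypes[snp_ids].to_numpy(dtype=float)
    return G @ w / w.mean()


def score_iv(
    cohort: pd.DataFrame,
    score_model: ScoreModel,
    adjust=("age", "sex"),
    stratify_by: str | None = "area_id",
) -> MrResult:
    """Individual-level allele-score instrumental-variable estimate.

    The per-allele score log OR for diabetes comes from area-stratified
    logistic fits (cases = prevalent + incident) pooled by inverse
    variance, then is rescaled to per 25 nmol/l using the score's
    cross-validated per-allele effect on 25(OH)D.
    """
    df = cohort.copy()
    df["_score"] = allele_score(df, score_model.weights)
    y_all = (df["diabetes_status"] != "none").astype(float)

    def fit_one(sub):
        X = pd.concat(
            [sub[["_score"]], design_matrix(sub, adjust)], axis=1
        )
        return fit_logit(y_all.loc[sub.index], X, label="score_iv")

    beta, se, _ = stratified_coefficient(
        df, fit_one, "_score", stratify_by, drop_failures=True
    )
    est = scale_per_25(beta, se, score_model.per_allele_effect, method="score_iv")
    return MrResult(method="score_iv", estimate=est, n_snps=len(score_model.snp_ids))
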