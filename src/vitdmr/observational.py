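"""Observational association of measured 25(OH)D with incident diabetes.

Implements the classical epidemiological toolkit used alongside the genetic
analyses: a continuous per-25-nmol/l logistic estimate with covariate
adjustment, a tertile analysis presented with floating absolute risks (every
category, including the reference, carries its own floated variance), and a
forward-stepwise covariate-adjustment sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._fits import FitFailureError, design_matrix, fit_logit
from .results import Estimate, FloatedRisk

EXPOSURE_COL = "exposure_measured"
DEFAULT_COVARIATES = ("age", "sex", "latitude", "SBP", "physical_activity", "body_fat")


class DegenerateCovarianceError(ValueError):
    """Floated variances came out negative (near-collinear categories)."""


def _analysis_frame(cohort: pd.DataFrame, exclude_prevalent: bool) -> pd.DataFrame:
    df = cohort[cohort[EXPOSURE_COL].notna()].copy()
    if exclude_prevalent:
        df = df[df["diabetes_status"] != "prevalent"]
    return df


def _case_vector(df: pd.DataFrame) -> np.ndarray:
    return (df["diabetes_status"] != "none").astype(float).to_numpy()


def fit_continuous(
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    exclude_prevalent: bool = True,
    per: float = 25.0,
) -> Estimate:
    """Adjusted logistic estimate per ``per`` nmol/l higher 25(OH)D.

    Restricted to the measured subset; with ``exclude_prevalent`` (the
    default, mirroring the incident analysis) baseline cases are dropped to
    avoid reverse causality.  The per-25 estimate is exactly the per-1
    estimate with beta and SE multiplied by 25.
    """
    df = _analysis_frame(cohort, exclude_prevalent)
    y = _case_vector(df)
    X = pd.concat(
        [
            (df[EXPOSURE_COL] / per).rename("exposure"),
            design_matrix(df, covariates),
        ],
        axis=1,
    )
    try:
        params, cov = fit_logit(y, X, label=f"covariates={list(covariates)}")
    except FitFailureError:
        raise
    return Estimate(
        beta=float(params["exposure"]),
        se=float(np.sqrt(cov.loc["exposure", "exposure"])),
        unit=f"per-{per:g}-nmol/l",
        method="observational_logistic",
        n=len(df),
        n_cases=int(y.sum()),
    )


def floated_variances(coef_cov: np.ndarray):
    """Floated variances (f0, f1, f2) for a 3-category exposure.

    Given the 2x2 covariance of the two non-reference log ORs (b1, b2):
    f0 = Cov(b1,b2), f1 = Var(b1) - f0, f2 = Var(b2) - f0.  These
    reconstruct every pairwise contrast variance exactly:
    f0 + f1 = Var(b1), f0 + f2 = Var(b2), f1 + f2 = Var(b1 - b2).
    """
    c = np.asarray(coef_cov, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("expected the 2x2 covariance of the non-reference log ORs")
    if not np.allclose(c, c.T):
        raise ValueError("covariance must be symmetric")
    f0 = float(c[0, 1])
    f1 = float(c[0, 0] - f0)
    f2 = float(c[1, 1] - f0)
    if f0 < 0 or f1 < 0 or f2 < 0:
        raise DegenerateCovarianceError(
            f"negative floated variance ({f0:.3g}, {f1:.3g}, {f2:.3g}): "
            "categories nearly collinear"
        )
    return f0, f1, f2


def assign_tertiles(x: np.ndarray):
    """Empirical-tertile labels 0/1/2; boundary values go to the lower tertile."""
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct exposure values for tertiles")
    q1, q2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    return np.where(x <= q1, 0, np.where(x <= q2, 1, 2))


def tertile_analysis(
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    exclude_prevalent: bool = True,
):
    """Tertile odds ratios with floating absolute risks.

    Fits a logistic model with indicators for tertiles 2 and 3 plus the
    covariates, then converts the coefficient covariance into floated
    variances so the reference tertile (OR = 1) also gets a CI.
    Returns a list of three :class:`FloatedRisk`.
    """
    df = _analysis_frame(cohort, exclude_prevalent)
    y = _case_vector(df)
    tert = assign_tertiles(df[EXPOSURE_COL].to_numpy())
    counts = np.bincount(tert, minlength=3)
    if np.any(counts == 0):
        raise ValueError("empty tertile")
    X = pd.concat(
        [
            pd.Series((tert == 1).astype(float), index=df.index, name="tertile_2"),
            pd.Series((tert == 2).astype(float), index=df.index, name="tertile_3"),
            design_matrix(df, covariates),
        ],
        axis=1,
    )
    params, cov = fit_logit(y, X, label="tertile model")
    b1, b2 = float(params["tertile_2"]), float(params["tertile_3"])
    c = cov.loc[["tertile_2", "tertile_3"], ["tertile_2", "tertile_3"]].to_numpy()
    f0, f1, f2 = floated_variances(c)
    events = [int(y[tert == k].sum()) for k in range(3)]
    return [
        FloatedRisk(0, events[0], 1.0, float(np.sqrt(f0))),
        FloatedRisk(1, events[1], float(np.exp(b1)), float(np.sqrt(f1))),
        FloatedRisk(2, events[2], float(np.exp(b2)), float(np.sqrt(f2))),
    ]


def nonlinearity_test(
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    exclude_prevalent: bool = True,
) -> float:
    """Wald p-value for a quadratic exposure term.

    An approximation to a formal departure-from-linearity test: the
    centred squared exposure is added to the continuous model and its
    coefficient tested against zero.
    """
    df = _analysis_frame(cohort, exclude_prevalent)
    y = _case_vector(df)
    x = df[EXPOSURE_COL] / 25.0
    xc = x - x.mean()
    X = pd.concat(
        [
            x.rename("exposure"),
            (xc**2).rename("exposure_sq"),
            design_matrix(df, covariates),
        ],
        axis=1,
    )
    params, cov = fit_logit(y, X, label="nonlinearity model")
    z = params["exposure_sq"] / np.sqrt(cov.loc["exposure_sq", "exposure_sq"])
    from scipy.stats import norm

    return float(2.0 * norm.sf(abs(z)))


def stepwise_adjust(
    cohort: pd.DataFrame,
    candidates,
    p_entry: float = 0.05,
    exclude_prevalent: bool = True,
):
    """Forward-stepwise covariate entry (entry criterion p <= p_entry).

    At each step the candidate with the smallest Wald p-value enters if it
    meets the criterion; the exposure estimate is recorded after every
    step.  Deterministic given the data (ties broken by candidate order).
    Returns a list of (covariate tuple, Estimate), starting with the
    unadjusted model.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    selected: list = []
    remaining = list(candidates)
    path = [(tuple(selected), fit_continuous(cohort, selected, exclude_prevalent))]
    df = _analysis_frame(cohort, exclude_prevalent)
    y = _case_vector(df)
    while remaining:
        best = None
        for cand in remaining:
            X = pd.concat(
                [
                    (df[EXPOSURE_COL] / 25.0).rename("exposure"),
                    design_matrix(df, selected + [cand]),
                ],
                axis=1,
            )
            try:
                params, cov = fit_logit(y, X, label=f"candidate {cand}")
            except FitFailureError:
                continue
            block = design_matrix(df, [cand]).columns
            # joint Wald test for multi-column (categorical) candidates
            b = params[list(block)].to_numpy()
            V = cov.loc[list(block), list(block)].to_numpy()
            from scipy.stats import chi2

            stat = float(b @ np.linalg.solve(V, b))
            pval = float(chi2.sf(stat, df=len(block)))
            if best is None or pval < best[1]:
                best = (cand, pval)
        if best is None or best[1] > p_entry:
            break
        selected.append(best[0])
        remaining.remove(best[0])
        path.append(
            (tuple(selected), fit_continuous(cohort, selected, exclude_prevalent))
        )
    return path
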