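"""Internal regression helpers shared by the analysis modules.

Thin wrappers around statsmodels OLS/Logit plus the fixed-effect
inverse-variance combiner and a deterministic design-matrix builder
(categorical covariates are dummy-coded with sorted levels, first level as
reference).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z975 = 1.959964  # two-sided 95% normal quantile, fixed by convention


class FitFailureError(RuntimeError):
    """A regression failed to converge or the design was degenerate."""


def design_matrix(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design block for the named covariates (no intercept).

    Object/categorical columns become 0/1 dummies with the first sorted
    level as reference, so the design is deterministic for a given table.
    """
    blocks = []
    for name in covariates:
        col = df[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                blocks.append(
                    pd.Series((col == lev).astype(float), name=f"{name}[{lev}]")
                )
        else:
            blocks.append(col.astype(float))
    if not blocks:
        return pd.DataFrame(index=df.index)
    return pd.concat(blocks, axis=1)


def fit_logit(y: np.ndarray, X: pd.DataFrame, label: str = "model"):
    """Logistic fit returning (params, cov).  Raises FitFailureError on
    separation or non-convergence."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(np.asarray(y, dtype=float), Xc).fit(
                disp=0, maxiter=100
            )
    except Exception as exc:  # PerfectSeparation, LinAlgError, ...
        raise FitFailureError(f"logistic fit failed for {label}: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise FitFailureError(f"logistic fit did not converge for {label}")
    cov = res.cov_params()
    if not np.all(np.isfinite(np.asarray(cov))):
        raise FitFailureError(f"degenerate covariance for {label}")
    return res.params, cov


def fit_ols(y: np.ndarray, X: pd.DataFrame, label: str = "model"):
    """OLS fit returning (params, cov)."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.OLS(np.asarray(y, dtype=float), Xc).fit()
    except Exception as exc:
        raise FitFailureError(f"linear fit failed for {label}: {exc}") from exc
    return res.params, res.cov_params()


def ivw_combine(betas, ses):
    """Fixed-effect inverse-variance pooling.

    Returns (pooled beta, pooled se, Q) with
    beta = sum(b_i/se_i^2)/sum(1/se_i^2), se = 1/sqrt(sum(1/se_i^2)),
    Q = sum(((b_i - beta)/se_i)^2).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("nothing to combine")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(((betas - beta) / ses) ** 2))
    return beta, se, q


def stratified_coefficient(
    df: pd.DataFrame,
    fit_one,
    term: str,
    stratify_by: str | None,
    min_per_stratum: int = 30,
    drop_failures: bool = False,
):
    """Fit per stratum, extract one coefficient, pool by inverse variance.

    ``fit_one(sub)`` must return (params, cov) indexed by term names.  Falls
    back to a single unstratified fit (with a warning) when fewer than two
    strata reach ``min_per_stratum`` rows.  With ``drop_failures`` a stratum
    whose fit fails (e.g. separation) is dropped with a warning instead of
    aborting.
    """
    if stratify_by is not None:
        groups = [
            (key, sub)
            for key, sub in df.groupby(stratify_by, sort=True)
            if len(sub) >= min_per_stratum
        ]
        if len(groups) < 2:
            warnings.warn(
                f"fewer than 2 strata with >= {min_per_stratum} rows; "
                "falling back to an unstratified fit"
            )
            groups = None
    else:
        groups = None

    if groups is None:
        params, cov = fit_one(df)
        return float(params[term]), float(np.sqrt(cov.loc[term, term])), 0.0

    betas, ses = [], []
    for key, sub in groups:
        try:
            params, cov = fit_one(sub)
        except FitFailureError as exc:
            if drop_failures:
                warnings.warn(f"stratum {key!r} dropped: {exc}")
                continue
            raise
        betas.append(float(params[term]))
        ses.append(float(np.sqrt(cov.loc[term, term])))
    if not betas:
        raise FitFailureError("every stratum failed to fit")
    return ivw_combine(betas, ses)
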