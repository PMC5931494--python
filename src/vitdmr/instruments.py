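"""Genetic instrument construction from individual-level data.

Covers Hardy–Weinberg checks by recruitment area, per-SNP effects on
25(OH)D and on diabetes (area-stratified fits pooled by inverse variance),
cross-validated internal weights for the allele score with its first-stage
F-statistic, and a pleiotropy scan of each SNP against cardiometabolic
traits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from ._fits import design_matrix, fit_logit, fit_ols, stratified_coefficient
from .mr import allele_score
from .results import ScoreModel, SnpInstrument, orient

EXPOSURE_COL = "exposure_measured"
DEFAULT_ADJUST = ("age", "sex", "season")
HWE_FLAG_P = 1e-3  # areas below this are flagged in the per-area report


def hwe_test(genotype_counts) -> tuple[float, float]:
    """1-df chi-square test of Hardy–Weinberg proportions.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa) ordered by copies of the
    effect allele (0, 1, 2).  Expected counts use the sample allele
    frequency.  A monomorphic SNP returns (0, 1) with a warning.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (n1 + 2 * n2) / (2.0 * n)
    if p == 0.0 or p == 1.0:
        warnings.warn("monomorphic SNP: HWE test undefined, returning (0, 1)")
        return 0.0, 1.0
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(chi2_dist.sf(chi2, df=1))


def hwe_by_area(cohort: pd.DataFrame, snp_ids, area_col: str = "area_id") -> pd.DataFrame:
    """HWE assessed separately per area, flagging p < 1e-3."""
    rows = []
    for snp in snp_ids:
        for area, sub in cohort.groupby(area_col, sort=True):
            counts = [int((sub[snp] == k).sum()) for k in (0, 1, 2)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chi2, p = hwe_test(counts)
            rows.append(
                {
                    "snp_id": snp,
                    "area_id": area,
                    "n": sum(counts),
                    "chi2": chi2,
                    "p": p,
                    "flagged": p < HWE_FLAG_P,
                }
            )
    return pd.DataFrame(rows)


def _measured(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort[cohort[EXPOSURE_COL].notna()]
    if df.empty:
        raise ValueError("no individuals with measured exposure")
    return df


def per_snp_exposure_effects(
    cohort: pd.DataFrame,
    snp_specs,
    adjust=DEFAULT_ADJUST,
    stratify_by: str | None = "area_id",
):
    """Per-allele effect of each SNP on 25(OH)D, oriented afterwards.

    Per-area linear fits (adjusted for the given covariates) combined by
    fixed-effect inverse variance; the instrument is then flipped, if
    needed, so its effect allele raises 25(OH)D.  Returns a list of
    :class:`SnpInstrument`.
    """
    df = _measured(cohort)
    out = []
    for spec in snp_specs:
        def fit_one(sub, snp=spec.snp_id):
            X = pd.concat(
                [sub[snp].astype(float), design_matrix(sub, adjust)], axis=1
            )
            return fit_ols(sub[EXPOSURE_COL].to_numpy(), X, label=snp)

        beta, se, _ = stratified_coefficient(df, fit_one, spec.snp_id, stratify_by)
        out.append(
            orient(
                SnpInstrument(
                    snp_id=spec.snp_id,
                    gene=spec.gene,
                    effect_allele=spec.effect_allele,
                    other_allele=spec.other_allele,
                    effect_allele_freq=spec.effect_allele_freq,
                    beta_exposure=beta,
                    se_exposure=se,
                )
            )
        )
    return out


def cv_weights(
    cohort: pd.DataFrame,
    snp_ids,
    k: int = 10,
    seed: int = 0,
    adjust=DEFAULT_ADJUST,
    stratify_by: str | None = "area_id",
) -> ScoreModel:
    """Internal allele-score weights by k-fold cross-validation.

    The measured subset is partitioned into k seeded folds.  For each fold
    the per-SNP weights come from a joint adjusted linear model fitted on
    the other k-1 folds, and the held-out rows receive a score built from
    those out-of-fold weights.  The final weights are the fold average;
    the score's per-allele effect on 25(OH)D (and the first-stage
    F-statistic, computed as (beta/se)^2 for the single score term) come
    from regressing exposure on the cross-validated score with the same
    adjustment, stratified by area.
    """
    snp_ids = list(snp_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    df = _measured(cohort).copy()
    n = len(df)
    if n < k:
        raise ValueError(f"measured subset ({n}) smaller than k ({k})")
    if n < 10 * k and k != n:  # k = n is deliberate leave-one-out
        warnings.warn(
            f"measured subset ({n}) below 10*k ({10 * k}); "
            "fold weight estimates will be noisy"
        )

    while True:
        rng = np.random.default_rng(seed)
        fold = rng.permutation(np.arange(n) % k)
        ok = all(
            all(df[s].to_numpy()[fold != f].std() > 0 for s in snp_ids)
            for f in range(k)
        )
        if ok:
            break
        k -= 1
        warnings.warn(f"zero-variance SNP in a training fold; reducing k to {k}")
        if k < 2:
            raise ValueError("cannot form >= 2 usable folds")

    fold_weights = np.empty((k, len(snp_ids)))
    cv_score = np.empty(n)
    y = df[EXPOSURE_COL].to_numpy()
    adj = design_matrix(df, adjust)
    G = df[snp_ids].astype(float)
    for f in range(k):
        train = fold != f
        X = pd.concat([G[train], adj[train]], axis=1)
        params, _ = fit_ols(y[train], X, label=f"fold {f}")
        w = params[snp_ids].to_numpy()
        fold_weights[f] = w
        held = ~train
        cv_score[held] = G[held].to_numpy() @ w / w.mean()

    weights = fold_weights.mean(axis=0)
    df["_cv_score"] = cv_score

    def fit_score(sub):
        X = pd.concat([sub[["_cv_score"]], design_matrix(sub, adjust)], axis=1)
        return fit_ols(sub[EXPOSURE_COL].to_numpy(), X, label="cv score")

    beta, se, _ = stratified_coefficient(df, fit_score, "_cv_score", stratify_by)
    return ScoreModel(
        snp_ids=tuple(snp_ids),
        weights={s: float(w) for s, w in zip(snp_ids, weights)},
        per_allele_effect=float(beta),
        se_per_allele_effect=float(se),
        f_statistic=float((beta / se) ** 2),
    )


def per_snp_outcome_effects(
    cohort: pd.DataFrame,
    snp_ids,
    adjust=("age", "sex"),
    stratify_by: str | None = "area_id",
) -> pd.DataFrame:
    """Per-allele log OR for diabetes for each SNP (prevalent + incident).

    Area-stratified logistic fits pooled by inverse variance; an area with
    separation is dropped with a warning.
    """
    y = (cohort["diabetes_status"] != "none").astype(float)
    n_cases = int(y.sum())
    if n_cases < 1 or n_cases == len(cohort):
        raise ValueError("need at least one case and one control")
    rows = []
    for snp in snp_ids:
        def fit_one(sub, snp=snp):
            X = pd.concat(
                [sub[snp].astype(float), design_matrix(sub, adjust)], axis=1
            )
            return fit_logit(y.loc[sub.index], X, label=snp)

        beta, se, _ = stratified_coefficient(
            cohort, fit_one, snp, stratify_by, drop_failures=True
        )
        rows.append(
            {
                "snp_id": snp,
                "beta_outcome": beta,
                "se_outcome": se,
                "or_per_allele": float(np.exp(beta)),
                "p": float(2.0 * norm.sf(abs(beta / se))),
            }
        )
    return pd.DataFrame(rows)


def score_outcome_effect(
    cohort: pd.DataFrame,
    score_model: ScoreModel,
    adjust=("age", "sex"),
    stratify_by: str | None = "area_id",
):
    """Per-allele log OR of the weighted allele score for diabetes."""
    df = cohort.copy()
    df["_score"] = allele_score(df, score_model.weights)
    y = (df["diabetes_status"] != "none").astype(float)

    def fit_one(sub):
        X = pd.concat([sub[["_score"]], design_matrix(sub, adjust)], axis=1)
        return fit_logit(y.loc[sub.index], X, label="score")

    beta, se, _ = stratified_coefficient(
        df, fit_one, "_score", stratify_by, drop_failures=True
    )
    return beta, se


DEFAULT_TRAITS = ("SBP", "DBP", "BMI", "WHR", "body_fat", "random_glucose")


def pleiotropy_trait_scan(
    cohort: pd.DataFrame,
    snp_ids,
    traits=DEFAULT_TRAITS,
    adjust=DEFAULT_ADJUST,
    stratify_by: str | None = "area_id",
) -> pd.DataFrame:
    """Per-allele effect of each SNP on each cardiometabolic trait.

    A non-null association here marks a pathway bypassing 25(OH)D, i.e.
    potential pleiotropy of the instrument.  Per-area adjusted linear fits
    pooled by inverse variance; a constant trait raises an error.
    """
    rows = []
    for trait in traits:
        if trait not in cohort.columns:
            raise KeyError(f"trait {trait!r} not in cohort")
        if cohort[trait].std() == 0:
            raise ValueError(f"trait {trait!r} is constant")
        for snp in snp_ids:
            def fit_one(sub, snp=snp, trait=trait):
                X = pd.concat(
                    [sub[snp].astype(float), design_matrix(sub, adjust)], axis=1
                )
                return fit_ols(sub[trait].to_numpy(), X, label=f"{snp}~{trait}")

            beta, se, _ = stratified_coefficient(
                cohort, fit_one, snp, stratify_by
            )
            rows.append(
                {
                    "snp_id": snp,
                    "trait": trait,
                    "effect": beta,
                    "se": se,
                    "p": float(2.0 * norm.sf(abs(beta / se))),
                }
            )
    return pd.DataFrame(rows)
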