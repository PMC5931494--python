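"""Cross-study meta-analysis of per-25-nmol/l causal estimates.

Each study contributes per-allele log ORs for the SNPs it carries; these
are converted to per-25-nmol/l Wald ratios (weighted by each SNP's effect
on 25(OH)D), pooled within study by fixed-effect inverse variance, and then
pooled across studies, overall and within latitude subgroups (northern
> 50°N vs southern <= 50°N).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._fits import ivw_combine
from .mr import HarmonizedInstrument, wald_ratio
from .results import Estimate, MetaResult

LATITUDE_SPLIT = 50.0  # degrees north; the forest plots' subgroup boundary

SCORE_SETS = {
    "2snp_synthesis": ("rs12785878", "rs10741657"),
    "3snp": ("rs12785878", "rs10741657", "rs2282679"),
    "4snp": ("rs12785878", "rs10741657", "rs2282679", "rs6013897"),
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_studies(
    rows: pd.DataFrame,
    reference_instruments,
    strict: bool = True,
):
    """Align study rows to the exposure-raising allele of each instrument.

    Rows whose alleles are swapped relative to the reference get their
    log OR sign-flipped and frequency complemented; rows on the opposite
    strand are aligned through base complements.  Strand-ambiguous (A/T,
    C/G) SNPs are flagged and, under ``strict``, excluded.  Returns
    (harmonized rows, rejected rows with a ``reason`` column).
    """
    ref = {r.snp_id: r for r in reference_instruments}
    kept, rejected = [], []
    for _, row in rows.iterrows():
        snp = row["snp_id"]
        if snp not in ref:
            rejected.append({**row, "reason": "no reference instrument"})
            continue
        r = ref[snp]
        ea, oa = str(row["effect_allele"]).upper(), str(row["other_allele"]).upper()
        if _is_palindromic(ea, oa):
            if strict:
                rejected.append({**row, "reason": "strand-ambiguous (palindromic)"})
                continue
            row = row.copy()
            row["ambiguous"] = True
        ref_ea, ref_oa = r.effect_allele.upper(), r.other_allele.upper()
        comp = (_COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?"))
        if (ea, oa) == (ref_ea, ref_oa) or comp == (ref_ea, ref_oa):
            kept.append(dict(row))
        elif (ea, oa) == (ref_oa, ref_ea) or comp == (ref_oa, ref_ea):
            flipped = dict(row)
            flipped["effect_allele"] = r.effect_allele
            flipped["other_allele"] = r.other_allele
            flipped["beta_outcome"] = -float(row["beta_outcome"])
            if "effect_allele_freq" in row and pd.notna(row["effect_allele_freq"]):
                flipped["effect_allele_freq"] = 1.0 - float(row["effect_allele_freq"])
            kept.append(flipped)
        else:
            rejected.append({**row, "reason": f"irreconcilable alleles {ea}/{oa}"})
    kept_df = pd.DataFrame(kept)
    rej_df = pd.DataFrame(rejected)
    return kept_df, rej_df


def study_estimate(
    study_rows: pd.DataFrame,
    score_set,
    exposure_weights: dict,
) -> Estimate:
    """One study's per-25-nmol/l estimate from its per-SNP log ORs.

    Each SNP's per-allele log OR is converted to a Wald ratio using the
    exposure-side weight beta_Xj (nmol/l per allele) and the ratios are
    pooled within the study by fixed-effect inverse variance.
    """
    snp_ids = list(score_set)
    have = set(study_rows["snp_id"])
    missing = [s for s in snp_ids if s not in have]
    if missing:
        raise KeyError(f"study lacks SNPs {missing}")
    betas, ses = [], []
    for snp in snp_ids:
        row = study_rows[study_rows["snp_id"] == snp].iloc[0]
        res = wald_ratio(
            HarmonizedInstrument(
                snp_id=snp,
                beta_exposure=float(exposure_weights[snp]),
                se_exposure=1e-6,  # external weights treated as fixed
                beta_outcome=float(row["beta_outcome"]),
                se_outcome=float(row["se_outcome"]),
            )
        )
        betas.append(res.estimate.beta)
        ses.append(res.estimate.se)
    if len(betas) == 1:
        beta, se = betas[0], ses[0]
    else:
        beta, se, _ = ivw_combine(betas, ses)
    return Estimate(
        beta=beta, se=se, unit="per-25-nmol/l", method="study_ivw"
    )


def studies_to_estimates(
    summaries: pd.DataFrame,
    score_set,
    exposure_weights: dict,
) -> pd.DataFrame:
    """Per-study estimates table for a score set; studies lacking a SNP in
    the set are excluded (with a log column noting why)."""
    rows = []
    for study_id, sub in summaries.groupby("study_id", sort=False):
        try:
            est = study_estimate(sub, score_set, exposure_weights)
        except KeyError:
            continue
        lat = float(sub["latitude_deg"].iloc[0])
        rows.append(
            {
                "study_id": study_id,
                "latitude_deg": lat,
                "latitude_class": "northern" if lat > LATITUDE_SPLIT else "southern",
                "n_cases": int(sub["n_cases"].iloc[0]),
                "n_controls": int(sub["n_controls"].iloc[0]),
                "beta": est.beta,
                "se": est.se,
            }
        )
    return pd.DataFrame(rows)


def combine_studies(
    per_study: pd.DataFrame,
    score_set: str = "",
    subgroup_by: str = "latitude_class",
) -> MetaResult:
    """Fixed-effect pooling across studies with latitude subgroups.

    Reports the pooled per-25-nmol/l estimate, per-subgroup estimates,
    Cochran's Q and I^2 = max(0, (Q - df)/Q) * 100.
    """
    if per_study.empty:
        raise ValueError("no study estimates to combine")
    beta, se, q = ivw_combine(per_study["beta"], per_study["se"])
    dfree = len(per_study) - 1
    i2 = 0.0 if dfree == 0 or q <= dfree else 100.0 * (q - dfree) / q
    pooled = Estimate(beta=beta, se=se, unit="per-25-nmol/l", method="meta_ivw")
    subgroups = {}
    if subgroup_by in per_study.columns:
        for key, sub in per_study.groupby(subgroup_by, sort=True):
            b, s, _ = ivw_combine(sub["beta"], sub["se"])
            subgroups[key] = Estimate(
                beta=b, se=s, unit="per-25-nmol/l", method=f"meta_ivw[{key}]"
            )
    return MetaResult(
        score_set=score_set,
        pooled=pooled,
        per_study=per_study.reset_index(drop=True),
        subgroups=subgroups,
        q=q,
        i2=i2,
    )


def forest_table(meta: MetaResult) -> pd.DataFrame:
    """Forest-plot table: rows ordered by subgroup then study, with OR,
    95% CI and percent inverse-variance weight (summing to 100)."""
    df = meta.per_study.copy()
    w = 1.0 / df["se"] ** 2
    df["weight_pct"] = 100.0 * w / w.sum()
    df["or"] = np.exp(df["beta"])
    df["ci_low"] = np.exp(df["beta"] - 1.959964 * df["se"])
    df["ci_high"] = np.exp(df["beta"] + 1.959964 * df["se"])
    sort_cols = [c for c in ("latitude_class", "study_id") if c in df.columns]
    df = df.sort_values(sort_cols).reset_index(drop=True)
    cols = sort_cols + ["or", "ci_low", "ci_high", "weight_pct"]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]
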