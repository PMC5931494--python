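"""End-to-end pipeline: simulate -> observational -> instruments -> MR -> meta.

The stage order mirrors the pre-specified analysis plan: observational
association first, then instrument construction and genetic analyses, then
the cross-study meta-analysis.  A run writes every stage's table plus a
manifest (inputs, seeds, row counts, SHA-256 checksums); re-running with an
identical config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GeneratorConfig, MetaSimConfig
from .instruments import (
    cv_weights,
    hwe_by_area,
    per_snp_exposure_effects,
    per_snp_outcome_effects,
)
from .io import write_table
from .meta import combine_studies, forest_table, harmonize_studies, studies_to_estimates
from .mr import HarmonizedInstrument, egger, ivw, score_iv, wald_ratio, weighted_median
from .observational import fit_continuous, tertile_analysis
from .presets import SYNTHESIS_SNPS, ckb_genetic_config, default_meta_config
from .simulate import read_cohort, simulate_cohort, simulate_study_summaries, write_cohort

log = logging.getLogger("vitdmr.pipeline")

ALL_STAGES = ("simulate", "observational", "instruments", "mr", "meta")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int
    out_dir: str
    stages: tuple = ALL_STAGES
    generator: GeneratorConfig | None = None  # default: CKB-scale preset
    meta_sim: MetaSimConfig | None = None
    score_snps: tuple = SYNTHESIS_SNPS
    cv_folds: int = 10
    methods: tuple = ("wald", "ivw", "egger", "median", "score")

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if self.generator is not None:
            self.generator.validate()


def demo_config(seed: int = 0, n: int = 8000) -> RunConfig:
    """A small configuration that exercises every stage in seconds."""
    gen = ckb_genetic_config(causal_logor_per_nmol=np.log(0.86) / 25.0, seed=seed)
    gen.n_individuals = n
    gen.measured_subset_fraction = 0.5
    gen.baseline_outcome_logodds = -2.45
    return RunConfig(
        seed=seed,
        out_dir="vitdmr_demo",
        generator=gen,
        meta_sim=default_meta_config(np.log(0.86) / 25.0, seed=seed),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _estimate_row(res) -> dict:
    e = res.estimate if hasattr(res, "estimate") else res
    return {
        "method": e.method,
        "unit": e.unit,
        "or": e.odds_ratio,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "beta": e.beta,
        "se": e.se,
        "p": e.p,
        "n": e.n if e.n is not None else "NA",
        "n_cases": e.n_cases if e.n_cases is not None else "NA",
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator or ckb_genetic_config(seed=config.seed)
    meta_cfg = config.meta_sim or default_meta_config(seed=config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "status": "ok",
    }
    outputs: dict[str, Path] = {}

    def record(stage: str, files: dict, rows: dict) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in files.values()},
            "rows": rows,
        }
        outputs.update(files)

    current = None
    try:
        if "simulate" in config.stages:
            current = "simulate"
            log.info("[simulate] generating cohort (n=%d)", gen.n_individuals)
            cohort = simulate_cohort(gen, seed=config.seed)
            cohort_path = out / "cohort.tsv"
            write_cohort(cohort, cohort_path)
            studies = simulate_study_summaries(meta_cfg, seed=config.seed + 1)
            studies_path = out / "studies.tsv"
            write_table(studies, studies_path)
            record(
                "simulate",
                {"cohort": cohort_path, "studies": studies_path},
                {"cohort": len(cohort), "studies": len(studies)},
            )
        else:
            cohort = None
            studies = None

        if "observational" in config.stages:
            current = "observational"
            if cohort is None:
                cohort = read_cohort(out / "cohort.tsv")
            log.info("[observational] continuous + tertile analysis")
            est = fit_continuous(cohort)
            tert = tertile_analysis(cohort)
            obs_path = out / "observational.tsv"
            write_table(pd.DataFrame([_estimate_row(est)]), obs_path)
            tert_path = out / "tertiles.tsv"
            write_table(
                pd.DataFrame(
                    [
                        {
                            "tertile": t.category + 1,
                            "n_events": t.n_events,
                            "or_floated": t.or_floated,
                            "se_floated": t.se_floated,
                            "ci_low": t.ci_low,
                            "ci_high": t.ci_high,
                        }
                        for t in tert
                    ]
                ),
                tert_path,
            )
            record(
                "observational",
                {"observational": obs_path, "tertiles": tert_path},
                {"estimates": 1, "tertiles": len(tert)},
            )

        if "instruments" in config.stages:
            current = "instruments"
            if cohort is None:
                cohort = read_cohort(out / "cohort.tsv")
            log.info("[instruments] HWE, per-SNP effects, CV score weights")
            snp_ids = [s.snp_id for s in gen.snp_specs]
            hwe = hwe_by_area(cohort, snp_ids)
            instrs = per_snp_exposure_effects(cohort, gen.snp_specs)
            score = cv_weights(
                cohort, config.score_snps, k=config.cv_folds, seed=config.seed + 2
            )
            instr_path = out / "instruments.tsv"
            write_table(
                pd.DataFrame(
                    [
                        {
                            "snp_id": i.snp_id,
                            "gene": i.gene,
                            "effect_allele": i.effect_allele,
                            "other_allele": i.other_allele,
                            "effect_allele_freq": i.effect_allele_freq,
                            "beta_exposure": i.beta_exposure,
                            "se_exposure": i.se_exposure,
                        }
                        for i in instrs
                    ]
                ),
                instr_path,
            )
            score_path = out / "score.tsv"
            write_table(
                pd.DataFrame(
                    [
                        {
                            "snp_id": s,
                            "weight": score.weights[s],
                            "per_allele_effect": score.per_allele_effect,
                            "se_per_allele_effect": score.se_per_allele_effect,
                            "f_statistic": score.f_statistic,
                            # score scale: S = sum w_j g_j / mean(w)
                            "normalisation": "allele-count (weights over mean weight)",
                        }
                        for s in score.snp_ids
                    ]
                ),
                score_path,
            )
            hwe_path = out / "hwe.tsv"
            write_table(hwe, hwe_path)
            record(
                "instruments",
                {"instruments": instr_path, "score": score_path, "hwe": hwe_path},
                {"instruments": len(instrs), "hwe": len(hwe)},
            )
        else:
            instrs = None
            score = None

        if "mr" in config.stages:
            current = "mr"
            if cohort is None:
                cohort = read_cohort(out / "cohort.tsv")
            if instrs is None or score is None:
                raise ValueError("mr stage requires the instruments stage")
            log.info("[mr] per-SNP and score instrumental-variable estimates")
            outcome = per_snp_outcome_effects(cohort, [i.snp_id for i in instrs])
            harm = [
                HarmonizedInstrument(
                    snp_id=i.snp_id,
                    beta_exposure=i.beta_exposure,
                    se_exposure=i.se_exposure,
                    beta_outcome=float(
                        outcome.loc[outcome["snp_id"] == i.snp_id, "beta_outcome"].iloc[0]
                    ),
                    se_outcome=float(
                        outcome.loc[outcome["snp_id"] == i.snp_id, "se_outcome"].iloc[0]
                    ),
                )
                for i in instrs
            ]
            results = []
            if "wald" in config.methods:
                results += [wald_ratio(h) for h in harm]
            if "ivw" in config.methods:
                wald_all = [wald_ratio(h).estimate for h in harm]
                results.append(ivw([(e.beta, e.se) for e in wald_all]))
            if "egger" in config.methods and len(harm) >= 3:
                slope, intercept = egger(harm)
                results += [slope, intercept]
            if "median" in config.methods:
                results.append(weighted_median(harm, seed=config.seed + 3))
            if "score" in config.methods:
                results.append(score_iv(cohort, score))
            mr_path = out / "mr.tsv"
            write_table(
                pd.DataFrame(
                    [{"n_snps": r.n_snps, **_estimate_row(r)} for r in results]
                ),
                mr_path,
            )
            record("mr", {"mr": mr_path}, {"results": len(results)})

        if "meta" in config.stages:
            current = "meta"
            if studies is None:
                studies = pd.read_csv(
                    out / "studies.tsv", sep="\t", na_values=["NA"],
                    keep_default_na=False,
                )
            log.info("[meta] cross-study fixed-effect meta-analysis")
            weights = {s.snp_id: s.beta_exposure for s in meta_cfg.snp_specs}
            per_study = studies_to_estimates(studies, config.score_snps, weights)
            meta_res = combine_studies(per_study, score_set="+".join(config.score_snps))
            forest = forest_table(meta_res)
            meta_path = out / "meta.tsv"
            rows = [{"group": "overall", **_estimate_row(meta_res.pooled),
                     "q": meta_res.q, "i2": meta_res.i2}]
            for key, est in meta_res.subgroups.items():
                rows.append({"group": key, **_estimate_row(est), "q": "NA", "i2": "NA"})
            write_table(pd.DataFrame(rows), meta_path)
            forest_path = out / "forest.tsv"
            write_table(forest, forest_path)
            record(
                "meta",
                {"meta": meta_path, "forest": forest_path},
                {"studies": len(per_study)},
            )
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(current or "?", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
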