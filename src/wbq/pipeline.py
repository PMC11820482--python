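"""End-to-end pipeline: simulate -> score -> analyze, with a run manifest.

Each stage consumes the previous stage's CSV, so any stage can also be run
standalone on externally supplied files.  Outputs are the study-shaped
tables: demographics, working environment, water intake/discharge (each
compared by gender), the univariate screen, and the three multivariable
models, plus a diagnostics JSON.  A JSON manifest records tool version,
config hashes, seeds, and the SHA-256 of every output file; identical
configuration and seed give byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    MODEL1_GROUPS,
    ModelSet,
    assess_mar,
    build_design,
    compare_by_gender,
    diagnostics,
    fit_models,
    impute_chained,
    univariate_screen,
)
from .codebook import default_codebook, exclusion_filter, validate_responses
from .config import ScoringConfig
from .scoring import score_table
from .simulate import CohortSpec, generate_cohort, inject_missingness

logger = logging.getLogger("wbq")

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "analyze_scored",
           "make_gender_table", "models_table"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hashes: dict[str, str] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages: dict[str, str] = field(default_factory=dict)   # stage -> status
    started: str = ""
    finished: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


# ---------------------------------------------------------------------------
# tables


#: Descriptive table layouts: (variable, forced kind) per study table.
TABLE1_VARS = [("residence", "categorical"), ("family_status", "categorical"),
               ("profession", "categorical"), ("bmi", "continuous"),
               ("bmi_category", "categorical")]
TABLE2_VARS = [("work_hours_week", "continuous"),
               ("labor_intensity", "categorical"),
               ("physical_strain", "categorical"),
               ("mental_strain", "categorical"), ("wc_access", "categorical"),
               ("weather_exposure", "categorical"),
               ("water_access", "categorical"),
               ("bottle_at_work", "categorical"),
               ("bottle_during_day", "categorical"),
               ("glass_during_day", "categorical")]
TABLE3_VARS = [("water_from_foods", "continuous"),
               ("water_from_beverages", "continuous"),
               ("beverage_variety_binary", "categorical"),
               ("water_from_water", "continuous"),
               ("intake_total", "continuous"), ("loss_total", "continuous"),
               ("balance", "continuous")]


def make_gender_table(scored: pd.DataFrame,
                      variables: list[tuple[str, str]]) -> pd.DataFrame:
    """Gender-comparison descriptive table (n (%), mean (SD) or median [IQR])."""
    rows = []
    for var, kind in variables:
        try:
            res = compare_by_gender(scored, var, kind=kind)
        except ValueError as exc:
            logger.info("descriptives: skipping %s (%s)", var, exc)
            continue
        row = {"variable": var, "test": res.test,
               "statistic": round(res.statistic, 4),
               "p_value": round(res.pvalue, 4)}
        row.update({f"summary_{g}": s for g, s in res.summaries.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def univariate_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        for i, term in enumerate(r.fit.terms):
            if term == "const":
                continue
            rows.append({"predictor": r.predictor, "term": term,
                         "coef": r.fit.beta[i], "se": r.fit.se[i],
                         "p_value": r.fit.pvalues[i],
                         "adj_r2": r.fit.adj_r2})
    return pd.DataFrame(rows).round(4)


def models_table(models: ModelSet) -> pd.DataFrame:
    rows = []
    for name, fit in (("model1", models.model1), ("model2", models.model2),
                      ("model3", models.model3)):
        for i, term in enumerate(fit.terms):
            rows.append({"model": name, "term": term, "coef": fit.beta[i],
                         "se": fit.se[i], "p_value": fit.pvalues[i],
                         "adj_r2": fit.adj_r2, "rmse": fit.rmse, "n": fit.n,
                         "m": fit.m})
    return pd.DataFrame(rows).round(4)


# ---------------------------------------------------------------------------
# stages


def analyze_scored(scored: pd.DataFrame, seed: int = 20220512, m: int = 20,
                   n_iter: int = 10) -> dict:
    """Run the full statistical stage on a scored table.

    Returns a dict with the descriptive tables, the univariate screen, the
    MAR report, the imputation set and the fitted three-model cascade.
    """
    design = build_design(scored)
    log: list[str] = []
    uni = univariate_screen(design, log=log)
    mar = assess_mar(design[[c for g in MODEL1_GROUPS.values() for c in g]
                            + ["balance"]])
    model_cols = [c for g in MODEL1_GROUPS.values() for c in g] + ["balance"]
    imps = impute_chained(design[model_cols], m=m, seed=seed, n_iter=n_iter)
    models = fit_models(imps)
    diag = diagnostics(imps.completions[0], model_cols[:-1])
    return {"design": design, "univariate": uni, "mar": mar,
            "imputations": imps, "models": models, "diagnostics": diag,
            "log": log}


def run_pipeline(out_dir: str | Path, seed: int = 20220512,
                 cohort_spec: CohortSpec | None = None,
                 scoring_config: ScoringConfig | None = None,
                 m: int = 20, n_iter: int = 10,
                 with_missingness: bool = True) -> RunManifest:
    """Simulate, score and analyze in order, writing all study tables.

    Stage failure halts the run with the failing stage named; outputs from
    completed stages are retained and listed in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_spec = cohort_spec or CohortSpec(seed=seed)
    scoring_config = scoring_config or ScoringConfig()
    manifest = RunManifest(
        version=__version__, seed=seed,
        config_hashes={
            "cohort_spec": _hash_obj({
                "n": cohort_spec.n, "seed": cohort_spec.seed,
                "intercept": cohort_spec.intercept,
                "noise_sd": cohort_spec.noise_sd,
                "true_coefficients": cohort_spec.true_coefficients,
                "marginals": cohort_spec.marginals,
            }),
            "scoring_config": _hash_obj(scoring_config.to_dict()),
        },
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def record(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out))] = _sha256(path)

    stage = "simulate"
    try:
        cohort = generate_cohort(cohort_spec, scoring_config)
        responses = cohort.responses
        if with_missingness and cohort_spec.missingness.rate > 0:
            miss = inject_missingness(responses, cohort_spec.missingness,
                                      seed=seed)
            responses = miss.data
        logger.info("simulate: n=%d resampled=%d augmented=%d",
                    len(responses), cohort.resampled, cohort.augmented)
        cohort_path = out / "cohort.csv"
        responses.to_csv(cohort_path, index=False)
        record(cohort_path)
        manifest.stages[stage] = "ok"

        stage = "score"
        validated = validate_responses(responses, default_codebook())
        retained, exclusions, warns = exclusion_filter(validated.data)
        for w in warns:
            logger.info("score: %s", w)
        logger.info("score: %d retained, %d excluded", len(retained),
                    len(exclusions))
        scored = score_table(retained, scoring_config)
        scored_path = out / "scored.csv"
        scored.to_csv(scored_path, index=False)
        record(scored_path)
        manifest.stages[stage] = "ok"

        stage = "analyze"
        result = analyze_scored(scored, seed=seed, m=m, n_iter=n_iter)
        for name, vars_ in (("table1", TABLE1_VARS), ("table2", TABLE2_VARS),
                            ("table3", TABLE3_VARS)):
            tab = make_gender_table(scored, vars_)
            path = out / f"{name}.csv"
            tab.to_csv(path, index=False)
            record(path)
        path = out / "table4.csv"
        univariate_table(result["univariate"]).to_csv(path, index=False)
        record(path)
        path = out / "table5.csv"
        models_table(result["models"]).to_csv(path, index=False)
        record(path)
        diag = result["diagnostics"]
        diag_payload = {
            "vif": {k: (None if not np.isfinite(v) else round(v, 4))
                    for k, v in diag.vif.items()},
            "vif_flags": diag.vif_flags,
            "residual_normality": dataclasses.asdict(diag.residual_normality)
            if diag.residual_normality else None,
            "heteroscedasticity": diag.heteroscedasticity,
            "residual_vs_fitted": diag.residual_vs_fitted,
            "mar_systematic": result["mar"].systematic,
            "imputation": {"m": result["imputations"].m,
                           "n_iter": result["imputations"].n_iter,
                           "methods": result["imputations"].methods,
                           "seed": result["imputations"].seed},
            "selection_log": result["models"].selection_log,
            "exclusions": [[str(e.id), e.reason] for e in exclusions],
        }
        path = out / "diagnostics.json"
        path.write_text(json.dumps(diag_payload, indent=2, sort_keys=True))
        record(path)
        manifest.stages[stage] = "ok"
    except Exception as exc:
        manifest.stages[stage] = f"failed: {exc}"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.to_json(out / "manifest.json")
        raise PipelineError(stage, exc) from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    return manifest
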