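"""End-to-end orchestration: score -> features -> fit -> interpret -> write.

A run is configured by a single YAML document (strict schema; unknown keys
are errors) and is a pure function of (inputs, config, seed): re-running
with the same config produces byte-identical outputs regardless of the
worker count. Each configured predictor set ("census", "all", "random")
gets its own family of pathway models; when both census and all are fitted,
a Spearman comparison of their R2_pred rankings is emitted as a
cancer-specificity diagnostic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .errors import ValidationError
from .features import (
    AlterationMatrix,
    build_feature_matrix,
    randomize_alterations,
    restrict_to_census,
)
from .interpret import (
    compare_rankings,
    driver_enrichment,
    flag_novel_candidates,
    predictor_weights,
    rank_pathways,
)
from .io import ExpressionMatrix, read_gene_list, read_gmt, read_matrix, write_table
from .regression import RegressionConfig, fit_all_pathways, save_models
from .scoring import ScoringConfig, score_collection

logger = logging.getLogger(__name__)

PredictorSet = Literal["census", "all", "random"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputPaths(_Strict):
    expression: str
    gene_sets: str
    mutations: str
    cnv: str
    census: Optional[str] = None
    drivers: Optional[str] = None


class ScoringSection(_Strict):
    backend: Literal["gsva", "ssgsea"] = "gsva"
    es_mode: Literal["diff", "max"] = "diff"
    tau: float = 1.0
    ssgsea_alpha: float = 0.25
    min_set_size: int = 5
    max_set_size: int = 500


class RegressionSection(_Strict):
    n_folds: int = 10
    lambda_rule: Literal["min", "one_se"] = "min"
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    standardize: bool = True
    pooled_r2: bool = False
    alpha_level: float = 0.05
    n_jobs: int = 1


class FeaturesSection(_Strict):
    min_mutated: int = 3
    randomize_mode: Literal["columns", "rows"] = "columns"


class InterpretationSection(_Strict):
    log_base: float = 10.0
    top_k: int = 10


class RunConfig(_Strict):
    """Versioned run configuration (YAML)."""

    schema_version: int = 1
    inputs: InputPaths
    out_dir: str
    seed: int = 0
    predictor_sets: list[PredictorSet] = ["census", "all"]
    scoring: ScoringSection = ScoringSection()
    features: FeaturesSection = FeaturesSection()
    regression: RegressionSection = RegressionSection()
    interpretation: InterpretationSection = InterpretationSection()

    @field_validator("predictor_sets")
    @classmethod
    def _nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("predictor_sets must not be empty")
        if len(set(v)) != len(v):
            raise ValueError("predictor_sets contains duplicates")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} is not a YAML mapping")
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expr = ExpressionMatrix.from_tsv(config.inputs.expression)
    collection = read_gmt(config.inputs.gene_sets)
    mut = read_matrix(config.inputs.mutations, orientation="samples", kind="mutation")
    cnv = read_matrix(config.inputs.cnv, orientation="samples", kind="cnv")
    census = (
        read_gene_list(config.inputs.census, label="census")
        if config.inputs.census
        else None
    )
    drivers = (
        read_gene_list(config.inputs.drivers, label="drivers")
        if config.inputs.drivers
        else None
    )

    scoring_cfg = ScoringConfig(
        tau=config.scoring.tau,
        es_mode=config.scoring.es_mode,
        backend=config.scoring.backend,
        ssgsea_alpha=config.scoring.ssgsea_alpha,
        min_set_size=config.scoring.min_set_size,
        max_set_size=config.scoring.max_set_size,
    )
    scores = score_collection(expr, collection, scoring_cfg)
    scores.to_tsv(out / "pathway_scores.tsv")

    full = build_feature_matrix(mut, cnv, min_mutated=config.features.min_mutated)
    matrices: dict[str, AlterationMatrix] = {}
    for label in config.predictor_sets:
        if label == "census":
            if census is None:
                raise ValidationError("predictor set 'census' requires inputs.census")
            matrices[label] = restrict_to_census(full, census)
        elif label == "all":
            matrices[label] = full
        elif label == "random":
            base = restrict_to_census(full, census) if census is not None else full
            matrices[label] = randomize_alterations(
                base, seed=config.seed + 1, mode=config.features.randomize_mode
            )

    reg_cfg = RegressionConfig(
        n_folds=config.regression.n_folds,
        lambda_rule=config.regression.lambda_rule,
        n_lambda=config.regression.n_lambda,
        lambda_min_ratio=config.regression.lambda_min_ratio,
        standardize=config.regression.standardize,
        seed=config.seed,
        alpha_level=config.regression.alpha_level,
        pooled_r2=config.regression.pooled_r2,
        n_jobs=config.regression.n_jobs,
    )

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_samples": len(expr.sample_ids),
        "n_pathways_scored": len(scores.pathway_ids),
        "predictor_sets": {},
        "outputs": {"pathway_scores": str(out / "pathway_scores.tsv")},
    }

    rankings: dict[str, pd.DataFrame] = {}
    weight_tables: dict[str, pd.DataFrame] = {}
    for label, X in matrices.items():
        models = fit_all_pathways(scores, X, reg_cfg, predictor_set_label=label)
        save_models(models, out / f"models_{label}.jsonl")
        ranking = rank_pathways(models)
        write_table(ranking, out / f"pathway_ranking_{label}.tsv", index=False)
        weights = predictor_weights(
            models, feature_names=X.feature_names,
            log_base=config.interpretation.log_base,
        )
        write_table(weights, out / f"predictor_weights_{label}.tsv", index=False)
        rankings[label] = ranking
        weight_tables[label] = weights
        set_info = {
            "n_features": len(X.feature_names),
            "n_models": len(models),
            "mean_r2_pred": float(ranking["r2_pred"].mean()),
        }
        if drivers is not None:
            enr = driver_enrichment(weights, drivers)
            set_info["driver_enrichment"] = {
                "u_statistic": enr.u_statistic,
                "p_value": enr.p_value,
                "n_drivers": enr.n_drivers,
                "n_features": enr.n_features,
            }
        manifest["predictor_sets"][label] = set_info
        manifest["outputs"][f"models_{label}"] = str(out / f"models_{label}.jsonl")
        manifest["outputs"][f"pathway_ranking_{label}"] = str(
            out / f"pathway_ranking_{label}.tsv"
        )
        manifest["outputs"][f"predictor_weights_{label}"] = str(
            out / f"predictor_weights_{label}.tsv"
        )

    if "census" in rankings and "all" in rankings:
        a = rankings["census"].set_index("pathway")["r2_pred"]
        b = rankings["all"].set_index("pathway")["r2_pred"]
        rho = compare_rankings(a, b)
        comp = pd.DataFrame(
            [{"comparison": "r2_pred census vs all", "spearman_rho": rho,
              "n_shared": len(a.index.intersection(b.index))}]
        )
        write_table(comp, out / "predictor_set_comparison.tsv", index=False)
        manifest["outputs"]["predictor_set_comparison"] = str(
            out / "predictor_set_comparison.tsv"
        )
        manifest["spearman_r2_census_vs_all"] = rho

    if census is not None and len(weight_tables) >= 2:
        novel = flag_novel_candidates(
            weight_tables, census, top_k=config.interpretation.top_k
        )
        if len(novel):
            write_table(novel, out / "novel_candidates.tsv", index=False)
            manifest["outputs"]["novel_candidates"] = str(out / "novel_candidates.tsv")
        manifest["n_novel_candidates"] = int(len(novel))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
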