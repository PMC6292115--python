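"""Synthetic multi-omics fixtures with planted driver -> pathway effects.

The generator emulates the statistical structure the regression stage
assumes: each pathway has a latent per-sample activity that is linear in a
small set of driver alteration features plus Gaussian noise, and the
expression of the pathway's member genes tracks that activity. Mutation
indicators are sparse Bernoulli draws; CNV values are continuous (or
discrete dosage levels). The fraction ``signal_fraction`` of each pathway's
activity variance attributable to its drivers is the planted ground truth
that downstream R2_pred should recover.

Everything is deterministic for a fixed seed, including the emitted files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import CNV, MUT, feature_name
from .io import ExpressionMatrix, GeneList, GeneSet, GeneSetCollection


@dataclass
class SimulationDesign:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized tumor cohort: 300 samples, 8000 measured
    genes, 20 pathways of 60-100 genes each, 100 mutation-profiled and 100
    CNV-profiled genes (200 alteration features), 10 of which are drivers.
    Sets of tens of genes embedded in a transcriptome-scale background —
    where pathway members are a small minority of ranked genes, as in real
    expression data — are the conditions under which the rank-based
    activity score is a stable readout of the latent pathway state.
    Driver mutation frequency 0.15 is typical of recurrently mutated cancer
    genes; continuous CNV values are standard-normal dosage scores. Half of
    each pathway's activity variance comes from its drivers by default.
    """

    n_samples: int = 300
    n_genes: int = 8000
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (60, 100)
    n_mut_genes: int = 100
    n_cnv_genes: int = 100
    n_driver_features: int = 10
    drivers_per_pathway: int = 2
    mutation_frequency: float = 0.15
    cnv_distribution: Literal["normal", "discrete"] = "normal"
    effect_size: float = 1.0
    signal_fraction: float = 0.5
    expression_loading: float = 1.0
    gene_noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    mixed_sign_loading: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mutation_frequency < 1):
            raise ValidationError("mutation_frequency must be in (0, 1)")
        if not (0 <= self.signal_fraction < 1):
            raise ValidationError("signal_fraction must be in [0, 1)")
        lo, hi = self.pathway_size_range
        if lo < 1 or lo > hi:
            raise ValidationError("invalid pathway_size_range")
        if self.n_pathways * hi > self.n_genes:
            raise ValidationError(
                "n_genes too small for n_pathways disjoint pathways of the "
                "requested size"
            )
        if self.n_driver_features > self.n_mut_genes + self.n_cnv_genes:
            raise ValidationError("more driver features than alteration features")
        if self.drivers_per_pathway > self.n_driver_features:
            raise ValidationError("drivers_per_pathway exceeds n_driver_features")


@dataclass
class GroundTruth:
    """What was planted, for validating recovery downstream."""

    driver_features: list[str]
    memberships: dict[str, list[str]]
    effects: dict[str, dict[str, float]]  # pathway -> feature -> beta
    realized_signal_fraction: dict[str, float]
    activity: pd.DataFrame = field(repr=False)  # pathways x samples

    def to_json(self, path: str | Path) -> None:
        payload = {
            "driver_features": self.driver_features,
            "memberships": self.memberships,
            "effects": self.effects,
            "realized_signal_fraction": self.realized_signal_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GeneSetCollection, GroundTruth]:
    """Draw one cohort: (expression, mutations, cnv, gene sets, ground truth).

    Mutation and CNV frames are samples x genes. Pathway memberships are
    disjoint; genes not in any pathway are pure noise genes that stress the
    scoring and selection stages. Drivers are assigned to pathways
    round-robin (then random extras) so every driver influences at least
    one pathway.
    """
    d = design
    rng = np.random.default_rng(d.seed)
    samples = [f"S{j:04d}" for j in range(d.n_samples)]
    genes = [f"G{i:05d}" for i in range(d.n_genes)]
    mut_genes = [f"MG{i:04d}" for i in range(d.n_mut_genes)]
    cnv_genes = [f"CG{i:04d}" for i in range(d.n_cnv_genes)]

    # --- alterations -------------------------------------------------------
    mut = rng.binomial(1, d.mutation_frequency, size=(d.n_samples, d.n_mut_genes))
    if d.cnv_distribution == "normal":
        cnv = rng.standard_normal((d.n_samples, d.n_cnv_genes))
    else:
        cnv = rng.integers(-2, 3, size=(d.n_samples, d.n_cnv_genes)).astype(float)
    mut_df = pd.DataFrame(mut, index=samples, columns=mut_genes, dtype=float)
    cnv_df = pd.DataFrame(cnv, index=samples, columns=cnv_genes)

    all_features = [feature_name(g, MUT) for g in mut_genes] + [
        feature_name(g, CNV) for g in cnv_genes
    ]
    feature_values = {
        feature_name(g, MUT): mut_df[g].to_numpy() for g in mut_genes
    }
    feature_values.update(
        {feature_name(g, CNV): cnv_df[g].to_numpy() for g in cnv_genes}
    )
    driver_features = sorted(
        rng.choice(all_features, size=d.n_driver_features, replace=False).tolist()
    )

    # --- pathway memberships ----------------------------------------------
    lo, hi = d.pathway_size_range
    pathway_ids = [f"PW{m:03d}" for m in range(d.n_pathways)]
    memberships: dict[str, list[str]] = {}
    cursor = 0
    for pid in pathway_ids:
        size = int(rng.integers(lo, hi + 1))
        memberships[pid] = genes[cursor : cursor + size]
        cursor += size
    collection = GeneSetCollection(
        [
            GeneSet(pid, "synthetic pathway", frozenset(members))
            for pid, members in memberships.items()
        ],
        source_label="synthetic",
    )

    # --- planted effects ---------------------------------------------------
    effects: dict[str, dict[str, float]] = {}
    for m, pid in enumerate(pathway_ids):
        chosen = {
            driver_features[(m * d.drivers_per_pathway + r) % d.n_driver_features]
            for r in range(d.drivers_per_pathway)
        }
        while len(chosen) < d.drivers_per_pathway:  # duplicates from wrap-around
            chosen.add(driver_features[int(rng.integers(d.n_driver_features))])
        effects[pid] = {feat: d.effect_size for feat in sorted(chosen)}

    # --- latent activity and expression ------------------------------------
    activity = np.zeros((d.n_pathways, d.n_samples))
    realized: dict[str, float] = {}
    expr = np.empty((d.n_genes, d.n_samples))
    baselines = rng.normal(d.baseline_mean, d.baseline_sd, size=d.n_genes)
    for m, pid in enumerate(pathway_ids):
        signal = np.zeros(d.n_samples)
        if d.signal_fraction > 0:
            for feat, beta in effects[pid].items():
                signal = signal + beta * feature_values[feat]
            signal = signal - signal.mean()
        var_sig = float(signal.var())
        if d.signal_fraction > 0 and var_sig > 0:
            eps_sd = float(np.sqrt(var_sig * (1 - d.signal_fraction) / d.signal_fraction))
        else:
            signal = np.zeros(d.n_samples)
            var_sig = 0.0
            eps_sd = 1.0
        eps = rng.normal(0.0, eps_sd, size=d.n_samples)
        a = signal + eps
        activity[m] = a
        realized[pid] = var_sig / float(a.var()) if a.var() > 0 else 0.0

    member_rows = np.zeros(d.n_genes, dtype=bool)
    for m, pid in enumerate(pathway_ids):
        for g in memberships[pid]:
            i = int(g[1:])
            member_rows[i] = True
            sign = 1.0
            if d.mixed_sign_loading and rng.random() < 0.5:
                sign = -1.0
            expr[i] = (
                baselines[i]
                + sign * d.expression_loading * activity[m]
                + rng.normal(0.0, d.gene_noise_sd, size=d.n_samples)
            )
    noise_rows = ~member_rows
    expr[noise_rows] = baselines[noise_rows, None] + rng.standard_normal(
        (int(noise_rows.sum()), d.n_samples)
    )

    expr_matrix = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    truth = GroundTruth(
        driver_features=driver_features,
        memberships=memberships,
        effects=effects,
        realized_signal_fraction=realized,
        activity=pd.DataFrame(activity, index=pathway_ids, columns=samples),
    )
    return expr_matrix, mut_df, cnv_df, collection, truth


def write_dataset(design: SimulationDesign, out_dir: str | Path) -> dict[str, str]:
    """Simulate and write all fixture files; returns the path manifest."""
    from .io import write_gmt, write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, mut, cnv, collection, truth = simulate_dataset(design)
    paths = {
        "expression": str(out / "expression.tsv"),
        "mutations": str(out / "mutations.tsv"),
        "cnv": str(out / "cnv.tsv"),
        "gene_sets": str(out / "pathways.gmt"),
        "ground_truth": str(out / "ground_truth.json"),
        "design": str(out / "design.json"),
    }
    expr.to_tsv(paths["expression"])
    write_table(mut, paths["mutations"], index_label="sample")
    write_table(cnv, paths["cnv"], index_label="sample")
    write_gmt(collection, paths["gene_sets"])
    truth.to_json(paths["ground_truth"])
    with open(paths["design"], "w") as fh:
        json.dump(dataclasses.asdict(design), fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Tiny worked examples used across docs and tests
# ---------------------------------------------------------------------------


@dataclass
class WorkedExample:
    """Hand-checkable fixtures: a 3-gene/2-sample scoring instance whose
    enrichment scores are exactly +1 and -1 in the first sample, and a
    4-point regression whose least-squares line is y = 0.9 x."""

    expression: ExpressionMatrix
    collection: GeneSetCollection
    expected_scores: pd.DataFrame  # pathways x samples
    regression_x: np.ndarray
    regression_y: np.ndarray
    expected_slope: float
    expected_intercept: float
    expected_halfwidth: float  # prediction interval at x0=2.5, alpha=0.05
    prediction_x0: float


def make_worked_example() -> WorkedExample:
    # Genes A and B fall from sample s1 to s2, C rises: in s1 the
    # decreasing-kcdf order is (A, B, C) with position weights
    # (0.5, 0.5, 1.5), so the set {A} walks straight up (ES = +1) and
    # {C} straight down (ES = -1).
    expr = ExpressionMatrix(
        pd.DataFrame(
            {"s1": [2.0, 1.0, 0.0], "s2": [0.0, -1.0, 2.0]},
            index=["A", "B", "C"],
        )
    )
    collection = GeneSetCollection(
        [
            GeneSet("SET_UP", "top-ranked singleton", frozenset({"A"})),
            GeneSet("SET_DOWN", "bottom-ranked singleton", frozenset({"C"})),
        ],
        source_label="worked-example",
    )
    expected_scores = pd.DataFrame(
        {"s1": [1.0, -1.0], "s2": [0.0, 1.0]}, index=["SET_UP", "SET_DOWN"]
    )
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 2.0, 2.0, 4.0])
    # Sxy = 4.5, Sxx = 5 -> slope 0.9, intercept 0; sigma2 = 0.35, dof = 2,
    # at x0 = 2.5 the 95% interval half-width is t_{.975,2}*sqrt(.35*1.25).
    return WorkedExample(
        expression=expr,
        collection=collection,
        expected_scores=expected_scores,
        regression_x=x,
        regression_y=y,
        expected_slope=0.9,
        expected_intercept=0.0,
        expected_halfwidth=2.8460,
        prediction_x0=2.5,
    )
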