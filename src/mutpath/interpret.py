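"""Ranking pathways and inferring driver genes from fitted models.

Pathways are ranked by cross-validated predictive performance (R2_pred):
pathways whose expression-level activity is well predicted from somatic
alterations in cancer-associated genes are candidates for biological
importance. Gene-level alteration features are ranked by a weight

    W_g = (1/M) * sum_m  s_gm * max(0, R2_pred,m) ,

the average over all M pathway models of the product of predictor
significance s_gm = -log(p-value) of the feature in model m's unpenalised
refit (0 when the feature was not selected) and the model's clamped
R2_pred. High-W features concentrate significant effects in predictive
models and are treated as candidate drivers. Enrichment of known drivers
among the W ranking is tested with a one-sided Wilcoxon rank-sum test;
families of p-values are converted to q-values by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .features import parse_feature_name
from .io import GeneList
from .regression import PathwayModel

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    label: str
    u_statistic: float
    p_value: float
    q_value: float
    n_drivers: int
    n_features: int


def rank_pathways(models: Sequence[PathwayModel]) -> pd.DataFrame:
    """Rank pathway models by descending R2_pred (ties: lexicographic id)."""
    if not models:
        raise ValidationError("no pathway models to rank")
    rows = [
        {
            "pathway": m.pathway_id,
            "r2_pred": m.r2_pred,
            "n_selected": len(m.selected),
            "predictor_set": m.predictor_set_label,
        }
        for m in models
    ]
    df = pd.DataFrame(rows).sort_values(
        ["r2_pred", "pathway"], ascending=[False, True], kind="stable"
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def predictor_weights(
    models: Sequence[PathwayModel],
    feature_names: Sequence[str] | None = None,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Per-feature driver weight W averaged over all models in a collection.

    ``feature_names`` fixes the feature universe so never-selected features
    appear with W = 0; by default the universe is the union of selected
    features across models. Negative R2_pred is clamped to 0 inside W only
    (a model with no predictive power contributes no evidence either way).
    Ranking is invariant to the log base.
    """
    if not models:
        raise ValidationError("no pathway models supplied")
    if log_base <= 1:
        raise ValidationError("log_base must be > 1")
    M = len(models)
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    if feature_names is not None:
        for nm in feature_names:
            totals[nm] = 0.0
            counts[nm] = 0
    log_scale = math.log(log_base)
    for m in models:
        r2 = max(0.0, m.r2_pred)
        for nm, p in m.refit_pvalues.items():
            if p <= 0:
                p = np.finfo(float).tiny
                logger.warning("p-value of 0 for %s in %s replaced by tiny", nm, m.pathway_id)
            totals[nm] = totals.get(nm, 0.0) + (-math.log(p) / log_scale) * r2
            counts[nm] = counts.get(nm, 0) + 1
    rows = []
    for nm in totals:
        gene, ftype = parse_feature_name(nm)
        rows.append(
            {
                "feature": nm,
                "gene": gene,
                "type": ftype,
                "weight": totals[nm] / M,
                "n_models_selected": counts[nm],
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["weight", "feature"], ascending=[False, True], kind="stable"
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def driver_enrichment(
    weights: pd.DataFrame,
    known_drivers: GeneList,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Wilcoxon rank-sum test of whether known drivers have larger W.

    A feature counts as a driver if its gene is in ``known_drivers`` (both
    the MUT and CNV features of a driver gene count). Exact enumeration is
    used when both groups have <= 10 members and the weights are tie-free;
    otherwise the normal approximation with tie correction.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unsupported alternative {alternative!r}")
    is_driver = weights["gene"].isin(known_drivers.genes).to_numpy()
    w = weights["weight"].to_numpy(dtype=float)
    wd, wn = w[is_driver], w[~is_driver]
    if len(wd) == 0 or len(wn) == 0:
        raise ValidationError(
            "enrichment needs at least one driver and one non-driver feature"
        )
    ties = len(np.unique(w)) < len(w)
    method = "exact" if (len(wd) <= 10 and len(wn) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(wd, wn, alternative=alternative, method=method)
    return EnrichmentResult(
        label=known_drivers.label,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        q_value=float(res.pvalue),  # single test; BH over a family is the caller's job
        n_drivers=int(len(wd)),
        n_features=int(len(w)),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compare_rankings(
    a: Mapping[str, float] | pd.Series,
    b: Mapping[str, float] | pd.Series,
) -> float:
    """Tie-corrected Spearman rank correlation over shared identifiers."""
    sa, sb = pd.Series(dict(a)), pd.Series(dict(b))
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared ids, got {len(shared)}")
    rho = stats.spearmanr(sa.loc[shared], sb.loc[shared]).statistic
    return float(rho)


def flag_novel_candidates(
    weight_tables: Mapping[str, pd.DataFrame],
    census: GeneList,
    top_k: int = 10,
) -> pd.DataFrame:
    """Non-census features ranking in the top_k of every weight table.

    Replication of a high rank across independently scored pathway
    collections is the evidence that a gene without an established cancer
    association may be a novel driver.
    """
    if len(weight_tables) < 2:
        raise ValidationError("need at least two weight tables for replication")
    per_table: dict[str, dict[str, int]] = {}
    for label, table in weight_tables.items():
        top = table[table["rank"] <= top_k]
        novel = top[~top["gene"].isin(census.genes)]
        per_table[label] = dict(zip(novel["feature"], novel["rank"]))
    labels = list(per_table)
    common = set(per_table[labels[0]])
    for label in labels[1:]:
        common &= set(per_table[label])
    rows = []
    for feat in sorted(common):
        gene, ftype = parse_feature_name(feat)
        row = {"feature": feat, "gene": gene, "type": ftype}
        for label in labels:
            row[f"rank_{label}"] = per_table[label][feat]
        rows.append(row)
    return pd.DataFrame(rows)
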