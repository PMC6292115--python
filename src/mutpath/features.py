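"""Sample-by-feature somatic alteration predictors.

A feature is a (gene, type) pair: MUT columns are 0/1 indicators of a
non-silent somatic mutation in the gene; CNV columns carry gene-level copy
number values as provided (continuous or thresholded — no re-encoding
happens here; standardisation is a regression concern). Features can be
restricted to a cancer-gene census, and a column-randomised null matrix can
be generated for calibration runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneList, _check_unique

logger = logging.getLogger(__name__)

MUT = "MUT"
CNV = "CNV"


def feature_name(gene: str, ftype: str) -> str:
    """Display name: mutation features are the bare gene, CNV features are
    suffixed, e.g. ``TP53`` vs ``MET (CNV)``."""
    return gene if ftype == MUT else f"{gene} ({ftype})"


def parse_feature_name(name: str) -> tuple[str, str]:
    if name.endswith(f" ({CNV})"):
        return name[: -len(f" ({CNV})")], CNV
    return name, MUT


@dataclass
class AlterationMatrix:
    """Samples in rows; columns are a MultiIndex of (gene, type)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValidationError("AlterationMatrix columns must be (gene, type) pairs")
        _check_unique(self.data.index, "sample")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate (gene, type) feature columns")
        arr = self.data.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("alteration matrix contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[tuple[str, str]]:
        return list(self.data.columns)

    @property
    def feature_names(self) -> list[str]:
        return [feature_name(g, t) for g, t in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def genes(self) -> set[str]:
        return {g for g, _ in self.data.columns}

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["gene", "type"])
        out.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "AlterationMatrix":
        df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
        df.index = df.index.astype(str)
        df.columns = pd.MultiIndex.from_tuples(
            [(str(g), str(t)) for g, t in df.columns]
        )
        return cls(df.astype(float))


def build_feature_matrix(
    mutations: pd.DataFrame,
    cnv: pd.DataFrame,
    min_mutated: int = 3,
) -> AlterationMatrix:
    """Assemble MUT and CNV feature columns on a shared sample axis.

    ``mutations`` and ``cnv`` are sample-by-gene frames over the same sample
    set (order may differ). Mutation genes carried by fewer than
    ``min_mutated`` samples — or by every sample — are dropped, as are
    zero-variance CNV genes; counts are logged. A single-carrier indicator
    is useless in cross-validation, hence the default ``min_mutated=3``.
    """
    mut_samples, cnv_samples = set(mutations.index), set(cnv.index)
    if mut_samples != cnv_samples:
        missing = sorted((mut_samples ^ cnv_samples))[:10]
        raise ValidationError(f"mutation/CNV sample sets differ, e.g. {missing}")
    samples = list(mutations.index)
    cnv = cnv.loc[samples]

    mvals = mutations.to_numpy(dtype=float)
    if not np.isin(mvals, (0.0, 1.0)).all():
        raise ValidationError("mutation matrix must contain only 0/1 values")
    counts = mvals.sum(axis=0)
    keep_mut = (counts >= max(min_mutated, 1)) & (counts < len(samples))
    n_drop = int((~keep_mut).sum())
    if n_drop:
        logger.info("dropping %d mutation columns (carriers < %d or constant)",
                    n_drop, min_mutated)

    cvar = cnv.to_numpy(dtype=float).var(axis=0)
    keep_cnv = cvar > 0
    if int((~keep_cnv).sum()):
        logger.info("dropping %d zero-variance CNV columns", int((~keep_cnv).sum()))

    blocks = []
    if keep_mut.any():
        m = mutations.loc[:, keep_mut].astype(float)
        m.columns = pd.MultiIndex.from_tuples([(g, MUT) for g in m.columns])
        blocks.append(m)
    if keep_cnv.any():
        c = cnv.loc[:, keep_cnv].astype(float)
        c.columns = pd.MultiIndex.from_tuples([(g, CNV) for g in c.columns])
        blocks.append(c)
    if not blocks:
        raise ValidationError("no alteration features survive assembly filters")
    data = pd.concat(blocks, axis=1)
    data.index = [str(s) for s in samples]
    return AlterationMatrix(data)


def restrict_to_census(features: AlterationMatrix, census: GeneList) -> AlterationMatrix:
    """Keep only features whose gene is in the census; column order preserved."""
    keep = [(g, t) for g, t in features.features if g in census]
    if not keep:
        raise ValidationError(
            f"no alteration features remain after restricting to {census.label!r}"
        )
    return AlterationMatrix(features.data.loc[:, keep])


def randomize_alterations(
    features: AlterationMatrix,
    seed: int,
    mode: Literal["columns", "rows"] = "columns",
) -> AlterationMatrix:
    """Permute alteration values across samples to build a null matrix.

    ``columns`` (default) permutes each feature independently, destroying
    both feature–pathway and feature–feature association while preserving
    every column's marginal distribution — the stricter null. ``rows``
    permutes whole sample rows jointly, preserving co-occurrence structure.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    vals = features.values.copy()
    n = vals.shape[0]
    if mode == "columns":
        for j in range(vals.shape[1]):
            vals[:, j] = vals[rng.permutation(n), j]
    elif mode == "rows":
        vals = vals[rng.permutation(n), :]
    else:
        raise ValidationError(f"unknown randomization mode {mode!r}")
    return AlterationMatrix(
        pd.DataFrame(vals, index=features.data.index, columns=features.data.columns)
    )
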