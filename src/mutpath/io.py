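"""Readers and writers for the on-disk artifacts and the core matrix types.

Formats are deliberately plain: GMT for gene set collections (the MSigDB
distribution format), TSV with a header row and an identifier column for all
matrices, and one-symbol-per-line text files (``#`` comments allowed) for
gene lists. Gene identifiers are opaque, case-sensitive strings; no symbol
aliasing is attempted. Missing values are not permitted in any matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

Orientation = Literal["genes", "samples"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named group of genes assumed to share a biological function."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be nonempty")
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet]
    source_label: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass(frozen=True)
class GeneList:
    """A labelled set of gene identifiers (e.g. a cancer gene census)."""

    genes: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene list {self.label!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes in rows, samples in columns."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        if self.data.shape[1] < 2:
            raise ValidationError("expression matrix needs at least 2 samples")
        _check_finite(self.data, "expression")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path: str | Path, orientation: Orientation = "genes") -> "ExpressionMatrix":
        df = read_matrix(path, orientation=orientation)
        if orientation == "samples":
            df = df.T
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.data, path, index_label="gene")


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------


def _check_unique(index: Iterable, what: str) -> None:
    idx = pd.Index(index)
    if idx.has_duplicates:
        dupes = sorted(map(str, idx[idx.duplicated()].unique()))
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:10]}")


def _check_finite(df: pd.DataFrame, what: str) -> None:
    arr = df.to_numpy()
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"non-finite value in {what} matrix at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, source_label: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated; duplicate set names are an
    error. An empty file yields an empty collection with a logged warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, description=description, members=genes))
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, source_label=source_label or path.stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format with sorted members (stable round-trip)."""
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_gene_list(path: str | Path, label: str | None = None) -> GeneList:
    """Read a plain-text gene list, one symbol per line; ``#`` starts a comment."""
    path = Path(path)
    genes: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    if not genes:
        raise ValidationError(f"gene list file {path} contains no genes")
    return GeneList(frozenset(genes), label=label or path.stem)


def write_gene_list(gene_list: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene_list.genes):
            fh.write(g + "\n")


def read_matrix(
    path: str | Path,
    orientation: Orientation = "genes",
    kind: Literal["expression", "mutation", "cnv"] = "expression",
) -> pd.DataFrame:
    """Read a TSV matrix with a header row and first-column identifiers.

    The returned frame has rows as stored in the file; ``orientation`` names
    what those rows are and is recorded on ``df.index.name``. Mutation
    matrices are additionally validated to contain only 0/1 values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"could not read {path}: {exc}") from exc
    _check_unique(df.index, "row")
    _check_unique(df.columns, "column")
    # locate non-numeric cells precisely before failing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    df = numeric.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene" if orientation == "genes" else "sample"
    if kind == "mutation":
        vals = df.to_numpy()
        if not np.isin(vals, (0.0, 1.0)).all():
            i, j = np.argwhere(~np.isin(vals, (0.0, 1.0)))[0]
            raise ValidationError(
                f"{path}: mutation matrix must be 0/1, found {vals[i, j]} at "
                f"row {df.index[i]!r}, column {df.columns[j]!r}"
            )
    return df


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    index_label: str | None = None,
    index: bool = True,
) -> None:
    """Write a results table as TSV at full floating precision.

    Callers are responsible for the table's declared sort order; this writer
    preserves row order exactly.
    """
    if table.shape[0] == 0:
        raise ValidationError("refusing to write an empty table")
    table.to_csv(path, sep="\t", index=index, index_label=index_label,
                 float_format="%.17g")
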