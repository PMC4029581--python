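"""Gene-by-sample intensity matrices and their tab-separated I/O.

The central container is :class:`ExpressionMatrix`: a nonnegative
gene × sample table of bead-array fluorescence intensities together
with a sample → group map.  All downstream filters (cleaning,
fold-change cascades, gene-set interrogation) operate on this object.

On-disk format: a TSV whose first column holds gene symbols and whose
header row holds sample names; the group map is a separate two-column
TSV (sample, group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_group_map",
    "write_group_map",
]

CollapseRule = Literal["max", "mean", "first"]


class MatrixParseError(ValueError):
    """Raised when a matrix or group-map file violates the format contract."""


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive, whitespace-stripped gene-symbol normalization."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """A gene × sample intensity table with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene symbols, columns are unique
        sample names, entries are nonnegative intensities in arbitrary
        fluorescence units.
    groups
        Series mapping every sample name to its group label.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise MatrixParseError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise MatrixParseError(f"duplicate sample identifiers: {list(dups)}")
        vals = self.values.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise MatrixParseError("intensities must be finite and nonnegative")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise MatrixParseError(f"samples without a group label: {missing}")
        self.groups = self.groups.reindex(self.values.columns)

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        """Sample names belonging to *group*; error if the group is unknown."""
        hits = [s for s, g in self.groups.items() if g == group]
        if not hits:
            raise KeyError(f"unknown group: {group!r}")
        return hits

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.groups.copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.groups.copy())


def _collapse_duplicates(df: pd.DataFrame, rule: CollapseRule) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    if rule == "max":
        return df.groupby(level=0, sort=False).max()
    if rule == "mean":
        return df.groupby(level=0, sort=False).mean()
    if rule == "first":
        return df[~df.index.duplicated(keep="first")]
    raise ValueError(f"unknown collapse rule: {rule!r}")


def read_group_map(path: str | Path) -> pd.Series:
    """Read a two-column (sample, group) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise MatrixParseError(f"group map {path} must have exactly 2 columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if ser.index.has_duplicates:
        raise MatrixParseError(f"group map {path} repeats a sample id")
    return ser


def write_group_map(groups: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_matrix(
    path: str | Path,
    group_map_path: str | Path | None = None,
    *,
    groups: pd.Series | None = None,
    collapse: CollapseRule = "max",
) -> ExpressionMatrix:
    """Parse an intensity TSV plus group map into an :class:`ExpressionMatrix`.

    Multiple probes mapping to the same symbol are collapsed per sample
    using *collapse* (default: maximum).  Gene symbols are upper-cased
    and stripped of surrounding whitespace.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique()
        raise MatrixParseError(f"{path}: duplicate sample columns {list(dups)}")
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise MatrixParseError(f"{path}: non-numeric intensities in column(s) {bad}")
    df.index = [normalize_symbol(s) for s in df.index]
    df = _collapse_duplicates(df, collapse)
    if groups is None:
        if group_map_path is None:
            raise ValueError("either group_map_path or groups is required")
        groups = read_group_map(group_map_path)
    return ExpressionMatrix(df.astype(float), groups)


def write_matrix(m: ExpressionMatrix, path: str | Path, *, float_format: str = "%g") -> None:
    """Write the intensity table as TSV (gene symbols in the first column)."""
    out = m.values.copy()
    out.index.name = "SYMBOL"
    out.to_csv(path, sep="\t", float_format=float_format)
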