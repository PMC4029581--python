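"""Sample-level correlation and hierarchical clustering.

Pairwise Pearson correlation over genes (on log2 intensities by
default) summarizes how alike whole samples are; agglomerative
clustering on the distance 1 - r yields the familiar sample QC
dendrogram, serialized as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix

__all__ = ["CorrelationTable", "sample_correlation", "dendrogram"]

Linkage = Literal["average", "complete", "single"]


@dataclass
class CorrelationTable:
    """Symmetric Pearson r (and r squared) between all sample pairs.

    Undefined correlations (a zero-variance sample) are NaN, never 0.
    """

    r: pd.DataFrame

    @property
    def r2(self) -> pd.DataFrame:
        return self.r**2

    @property
    def sample_ids(self) -> list[str]:
        return list(self.r.columns)

    def has_missing(self) -> bool:
        return bool(self.r.isna().any().any())


def sample_correlation(m: ExpressionMatrix, log2_transform: bool = True) -> CorrelationTable:
    """Pearson correlation between samples, computed across genes.

    With *log2_transform* (default) intensities are log2-transformed
    first, which is the conventional scale for array similarity; the
    matrix should be cleaned so all values are >= 1.
    """
    if m.values.shape[0] < 2 or m.values.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    vals = m.values
    if log2_transform:
        if (vals.to_numpy() <= 0).any():
            raise ValueError("log2 transform requires strictly positive intensities")
        vals = np.log2(vals)
    sd = vals.std(axis=0)
    r = vals.corr(method="pearson")
    # pandas yields 1.0 on the diagonal even for constant columns; an
    # undefined correlation must stay undefined.
    for s in r.columns[sd == 0]:
        r.loc[s, :] = np.nan
        r.loc[:, s] = np.nan
    return CorrelationTable(r)


def _newick(node: hierarchy.ClusterNode, labels: list[str], parent_height: float) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{labels[node.id]}:{length:g}"
    left = _newick(node.get_left(), labels, node.dist)
    right = _newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{length:g}"


def dendrogram(corr: CorrelationTable, linkage: Linkage = "average") -> str:
    """Agglomerative sample tree on distance d = 1 - r, as Newick.

    Samples are ordered lexicographically before linkage so that
    tie-breaking between equal-distance merges is reproducible.
    """
    if corr.has_missing():
        raise ValueError("correlation table contains undefined entries")
    order = sorted(corr.sample_ids)
    r = corr.r.loc[order, order]
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    root = hierarchy.to_tree(z)
    return "(" + ",".join(
        _newick(child, order, root.dist) for child in (root.get_left(), root.get_right())
    ) + ");"
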