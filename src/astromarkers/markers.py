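"""Marker-gene discovery by all-pairs fold-change filtering.

The core inference of the pipeline.  A gene is a cell-type marker
candidate when its intensity ratio clears a fold threshold in *every*
cross-group sample pair — e.g. each of the two fetal-astrocyte samples
against each of the two neural-stem-cell (NSC) samples, four ratios in
all.  Candidates are then refined by a stringent cross-dataset
criterion: expressed in independent stem-cell-derived astrocyte lines
while absent from (or at low abundance in) independent NSC lines and
differentiated neurons.  The same machinery, at a 2-fold threshold,
drives gene-set (pathway / transcription-factor) interrogation.

Fold changes are ratios of cleaned linear intensities; the clip-to-1
cleaning rule guarantees every ratio is finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSet
from .matrix import ExpressionMatrix
from .preprocess import DETECTION_FLOOR, expressed_genes

__all__ = [
    "FoldChangeCriterion",
    "StringentPolicy",
    "MarkerResult",
    "PathwaySummary",
    "pairwise_fold_filter",
    "stringent_marker_filter",
    "interrogate_gene_set",
    "heatmap_matrix",
]

Direction = Literal["up", "down"]
Boundary = Literal["inclusive", "strict"]


@dataclass(frozen=True)
class FoldChangeCriterion:
    """All-pairs fold-change rule between two sample groups.

    direction="up" requires I[a]/I[b] to clear *fold_threshold* for
    every sample a in group_a and b in group_b; "down" uses I[b]/I[a].
    The boundary is inclusive (>=) by default; "strict" demands >.
    """

    group_a: str
    group_b: str
    fold_threshold: float = 5.0
    direction: Direction = "up"
    boundary: Boundary = "inclusive"

    def __post_init__(self) -> None:
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if self.group_a == self.group_b:
            raise ValueError("groups must differ")

    def passes(self, min_fold: float) -> bool:
        if self.boundary == "inclusive":
            return min_fold >= self.fold_threshold
        return min_fold > self.fold_threshold


@dataclass(frozen=True)
class StringentPolicy:
    """Cross-dataset refinement thresholds.

    expressed_floor       : minimum intensity in every sample of every
                            derived-astrocyte dataset.
    low_abundance_ceiling : intensity below which a gene counts as
                            absent/low in the other-NSC and neuron datasets.
    missing_policy        : how to treat a candidate absent from an
                            auxiliary dataset ("fail" the condition or
                            "ignore" that dataset).
    """

    expressed_floor: float = DETECTION_FLOOR
    low_abundance_ceiling: float = DETECTION_FLOOR
    missing_policy: Literal["fail", "ignore"] = "fail"

    def __post_init__(self) -> None:
        if self.expressed_floor <= 0 or self.low_abundance_ceiling <= 0:
            raise ValueError("floors must be positive")


@dataclass
class MarkerResult:
    """One candidate gene with its evidence trail."""

    gene: str
    min_pairwise_fold: float
    stage: Literal["pairwise_pass", "stringent_pass"] = "pairwise_pass"
    pair_folds: dict[tuple[str, str], float] = field(default_factory=dict)
    evidence: dict[str, bool] = field(default_factory=dict)


def _group_arrays(m: ExpressionMatrix, criterion: FoldChangeCriterion):
    a_cols = m.samples_in(criterion.group_a)
    b_cols = m.samples_in(criterion.group_b)
    if set(a_cols) & set(b_cols):
        raise ValueError("groups overlap")
    return a_cols, b_cols


def pairwise_fold_filter(
    m: ExpressionMatrix, criterion: FoldChangeCriterion
) -> list[MarkerResult]:
    """Genes whose fold change clears the threshold in every cross-group pair.

    Requires a cleaned matrix (all intensities >= 1).  Results are
    sorted by descending minimum pairwise fold, ties broken by symbol.
    """
    if (m.values.to_numpy() <= 0).any():
        raise ValueError("matrix must be cleaned (strictly positive intensities)")
    a_cols, b_cols = _group_arrays(m, criterion)
    A = m.values[a_cols].to_numpy()
    B = m.values[b_cols].to_numpy()
    # all-pairs minimum ratio: min(A)/max(B) for up, min(B)/max(A) for down
    if criterion.direction == "up":
        min_fold = A.min(axis=1) / B.max(axis=1)
    else:
        min_fold = B.min(axis=1) / A.max(axis=1)
    results = []
    for i, gene in enumerate(m.values.index):
        if not criterion.passes(min_fold[i]):
            continue
        if criterion.direction == "up":
            folds = {(a, b): m.values.at[gene, a] / m.values.at[gene, b]
                     for a in a_cols for b in b_cols}
        else:
            folds = {(b, a): m.values.at[gene, b] / m.values.at[gene, a]
                     for a in a_cols for b in b_cols}
        results.append(MarkerResult(gene, float(min_fold[i]), pair_folds=folds))
    results.sort(key=lambda r: (-r.min_pairwise_fold, r.gene))
    return results


def stringent_marker_filter(
    candidates: Sequence[MarkerResult],
    derived_astro: Sequence[ExpressionMatrix],
    other_nsc: Sequence[ExpressionMatrix],
    neurons: ExpressionMatrix | Sequence[ExpressionMatrix],
    policy: StringentPolicy | None = None,
) -> list[MarkerResult]:
    """Refine fold-filter candidates against independent datasets.

    A candidate survives iff it is expressed (>= expressed_floor) in
    every sample of every derived-astrocyte matrix AND below the
    low-abundance ceiling in every sample of every other-NSC and neuron
    matrix.  Candidate order is preserved.
    """
    policy = policy or StringentPolicy()
    if isinstance(neurons, ExpressionMatrix):
        neurons = [neurons]
    out = []
    for cand in candidates:
        evidence: dict[str, bool] = {}
        ok = True
        for kind, mats, cond in (
            ("derived_astro", derived_astro, lambda v: bool((v >= policy.expressed_floor).all())),
            ("other_nsc", other_nsc, lambda v: bool((v < policy.low_abundance_ceiling).all())),
            ("neurons", neurons, lambda v: bool((v < policy.low_abundance_ceiling).all())),
        ):
            for j, mat in enumerate(mats):
                key = f"{kind}[{j}]"
                if cand.gene not in mat.values.index:
                    evidence[key] = policy.missing_policy == "ignore"
                else:
                    evidence[key] = cond(mat.values.loc[cand.gene].to_numpy())
                ok = ok and evidence[key]
        if ok:
            out.append(
                MarkerResult(
                    cand.gene,
                    cand.min_pairwise_fold,
                    stage="stringent_pass",
                    pair_folds=dict(cand.pair_folds),
                    evidence=evidence,
                )
            )
    return out


@dataclass
class PathwaySummary:
    """Per-gene-set counts in the layout of a pathway summary table."""

    set_name: str
    n_genes: int
    n_in_matrix: int
    expressed_a: int
    expressed_b: int
    up_in_a: int
    down_in_a: int
    table: pd.DataFrame  # per-gene intensities + fold/flags, for heatmap export


def interrogate_gene_set(
    m: ExpressionMatrix,
    gene_set: GeneSet,
    group_a: str,
    group_b: str,
    fold: float = 2.0,
    expressed_threshold: float = DETECTION_FLOOR,
    boundary: Boundary = "inclusive",
) -> PathwaySummary:
    """Count expression and 2-fold differential calls for one gene set.

    "Expressed" means >= *expressed_threshold* in every sample of the
    group; up/down calls use the all-pairs fold filter restricted to
    the set.  Genes absent from the matrix count as not expressed and
    are reported in the per-gene table with NaN intensities.
    """
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    present = [g for g in gene_set.genes if g in m.values.index]
    sub = m.subset_genes(present)
    expr_a = expressed_genes(sub, group_a, expressed_threshold) if present else set()
    expr_b = expressed_genes(sub, group_b, expressed_threshold) if present else set()
    up = down = []
    if present:
        up = pairwise_fold_filter(
            sub, FoldChangeCriterion(group_a, group_b, fold, "up", boundary)
        )
        down = pairwise_fold_filter(
            sub, FoldChangeCriterion(group_a, group_b, fold, "down", boundary)
        )
    up_genes = {r.gene for r in up}
    down_genes = {r.gene for r in down}
    rows = []
    for g in gene_set.genes:
        row: dict[str, object] = {"gene": g, "in_matrix": g in m.values.index}
        for s in m.sample_ids:
            row[s] = m.values.at[g, s] if g in m.values.index else np.nan
        row["expressed_a"] = g in expr_a
        row["expressed_b"] = g in expr_b
        row["up_in_a"] = g in up_genes
        row["down_in_a"] = g in down_genes
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    return PathwaySummary(
        set_name=gene_set.name,
        n_genes=len(gene_set),
        n_in_matrix=len(present),
        expressed_a=len(expr_a),
        expressed_b=len(expr_b),
        up_in_a=len(up_genes),
        down_in_a=len(down_genes),
        table=table,
    )


def heatmap_matrix(
    table: pd.DataFrame,
    sample_ids: Sequence[str],
    transform: Literal["log2", "none"] = "log2",
    row_scale: Literal["none", "zscore"] = "none",
) -> pd.DataFrame:
    """Deterministic matrix of values ready for heatmap rendering.

    Rows are ordered by descending maximum absolute log2 fold between
    any two samples; genes missing from the matrix are dropped.  With
    row_scale="zscore" each row is centred and scaled to unit variance.
    """
    if table.empty:
        raise ValueError("per-gene table is empty")
    vals = table.loc[table["in_matrix"].astype(bool), list(sample_ids)].astype(float)
    vals = vals.clip(lower=1.0)
    logv = np.log2(vals)
    spread = logv.max(axis=1) - logv.min(axis=1)
    order = spread.sort_values(ascending=False, kind="stable")
    # stable sort + symbol tiebreak for reproducible output
    order = order.iloc[np.lexsort((order.index, -order.to_numpy()))]
    out = logv.loc[order.index] if transform == "log2" else vals.loc[order.index]
    if row_scale == "zscore":
        mu = out.mean(axis=1)
        sd = out.std(axis=1, ddof=0).replace(0.0, 1.0)
        out = out.sub(mu, axis=0).div(sd, axis=0)
    return out
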