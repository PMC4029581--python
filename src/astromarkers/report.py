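"""Pipeline orchestration: configured end-to-end runs and the fixture report.

``run_pipeline`` drives the expression side of the analysis from one
declarative config — clean, correlate, fold-filter, optional stringent
refinement and gene-set interrogation — writing every artifact plus a
manifest (config hash, seed, version) into an output directory.
Writes go through a temporary file and an atomic rename so a failed
run never leaves a corrupt artifact behind.

``reproduce_tables`` recomputes the headline counts from the bundled
intensity tables (24 stringent markers, 46 transcription factors up,
51 down) and reports pass/fail per check.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .datasets import load_fixture
from .genesets import GeneSet, read_gmt
from .markers import (
    FoldChangeCriterion,
    StringentPolicy,
    interrogate_gene_set,
    heatmap_matrix,
    pairwise_fold_filter,
    stringent_marker_filter,
)
from .matrix import ExpressionMatrix, read_matrix, write_matrix
from .preprocess import CleaningPolicy, clean_matrix
from .similarity import dendrogram, sample_correlation

__all__ = ["RunConfig", "run_pipeline", "reproduce_tables"]

log = logging.getLogger("astromarkers")


@dataclass
class RunConfig:
    """Declarative description of one expression-analysis run."""

    matrix_path: str
    group_map_path: str
    group_a: str
    group_b: str
    out_dir: str
    fold_threshold: float = 5.0
    boundary: str = "inclusive"
    cleaning: CleaningPolicy = field(default_factory=CleaningPolicy)
    stringent: StringentPolicy | None = None
    derived_astro_paths: tuple[tuple[str, str], ...] = ()  # (matrix, group map)
    other_nsc_paths: tuple[tuple[str, str], ...] = ()
    neuron_paths: tuple[tuple[str, str], ...] = ()
    gene_set_gmt: str | None = None
    pathway_fold: float = 2.0
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def _results_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"gene": r.gene, "min_pairwise_fold": r.min_pairwise_fold, "stage": r.stage}
        for (num, den), fold in r.pair_folds.items():
            row[f"fold[{num}/{den}]"] = fold
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis; returns the manifest dictionary."""
    for path in [config.matrix_path, config.group_map_path, config.gene_set_gmt] + [
        p for pair in (config.derived_astro_paths + config.other_nsc_paths
                       + config.neuron_paths) for p in pair
    ]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input does not exist: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    m = read_matrix(config.matrix_path, config.group_map_path)
    log.info("loaded matrix: %d genes x %d samples", *m.values.shape)
    cleaned = clean_matrix(m, config.cleaning)
    log.info(
        "cleaning (floor=%g, clip=%g): %d -> %d genes",
        config.cleaning.detection_floor, config.cleaning.clip_floor,
        m.values.shape[0], cleaned.values.shape[0],
    )
    _atomic_write(out / "cleaned_matrix.tsv", lambda p: write_matrix(cleaned, p))

    corr = sample_correlation(cleaned)
    _atomic_write(out / "sample_correlation.tsv",
                  lambda p: corr.r.to_csv(p, sep="\t", float_format="%.6f"))
    newick = dendrogram(corr)
    _atomic_write(out / "samples.nwk", lambda p: Path(p).write_text(newick + "\n"))

    criterion = FoldChangeCriterion(
        config.group_a, config.group_b, config.fold_threshold, "up", config.boundary
    )
    candidates = pairwise_fold_filter(cleaned, criterion)
    log.info("fold filter (>=%g, all pairs): %d genes pass",
             config.fold_threshold, len(candidates))
    results = candidates

    manifest: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_genes_input": int(m.values.shape[0]),
        "n_genes_cleaned": int(cleaned.values.shape[0]),
        "n_pairwise_pass": len(candidates),
    }

    if config.stringent is not None:
        aux = {
            kind: [read_matrix(mp, gp) for mp, gp in paths]
            for kind, paths in [
                ("derived_astro", config.derived_astro_paths),
                ("other_nsc", config.other_nsc_paths),
                ("neurons", config.neuron_paths),
            ]
        }
        results = stringent_marker_filter(
            candidates, aux["derived_astro"], aux["other_nsc"], aux["neurons"],
            config.stringent,
        )
        log.info("stringent filter: %d of %d candidates retained",
                 len(results), len(candidates))
        manifest["n_stringent_pass"] = len(results)

    frame = _results_frame(results)
    _atomic_write(out / "markers.tsv",
                  lambda p: frame.to_csv(p, sep="\t", index=False, float_format="%.6g"))

    if config.gene_set_gmt:
        summaries = []
        for gs in read_gmt(config.gene_set_gmt):
            summary = interrogate_gene_set(
                cleaned, gs, config.group_a, config.group_b, config.pathway_fold
            )
            summaries.append(
                {
                    "pathway": summary.set_name,
                    "n_genes": summary.n_genes,
                    "expressed_a": summary.expressed_a,
                    "expressed_b": summary.expressed_b,
                    "up_in_a": summary.up_in_a,
                    "down_in_a": summary.down_in_a,
                }
            )
            diff = summary.table[
                summary.table["up_in_a"].astype(bool) | summary.table["down_in_a"].astype(bool)
            ]
            if not diff.empty:
                hm = heatmap_matrix(diff, cleaned.sample_ids)
                _atomic_write(out / f"heatmap_{summary.set_name}.tsv",
                              lambda p, hm=hm: hm.to_csv(p, sep="\t", float_format="%.4f"))
        _atomic_write(out / "pathway_summary.tsv",
                      lambda p: pd.DataFrame(summaries).to_csv(p, sep="\t", index=False))
        manifest["pathways"] = {s["pathway"]: s["up_in_a"] for s in summaries}

    _atomic_write(out / "manifest.json",
                  lambda p: Path(p).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n"))
    return manifest


# (fixture_id, fold, direction, expected passing count)
_FIXTURE_CHECKS: tuple[tuple[str, float, str, int], ...] = (
    ("stringent_markers", 5.0, "up", 24),
    ("tf_up", 2.0, "up", 46),
    ("tf_down", 2.0, "down", 51),
)


def reproduce_tables(
    checks: Sequence[tuple[str, float, str, int]] = _FIXTURE_CHECKS,
    matrices: dict[str, ExpressionMatrix] | None = None,
) -> pd.DataFrame:
    """Recompute fold-filter counts on the bundled tables and compare.

    Returns a machine-readable frame with one row per check: fixture,
    threshold, direction, expected and recomputed counts, pass flag.
    """
    rows = []
    for table_id, fold, direction, expected in checks:
        m = (matrices or {}).get(table_id) or load_fixture(table_id)
        cleaned = clean_matrix(m)
        crit = FoldChangeCriterion("fetal_astrocyte", "nsc", fold, direction)  # type: ignore[arg-type]
        n = len(pairwise_fold_filter(cleaned, crit))
        rows.append(
            {
                "fixture": table_id,
                "fold_threshold": fold,
                "direction": direction,
                "expected": expected,
                "observed": n,
                "ok": n == expected,
            }
        )
    return pd.DataFrame(rows)
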