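"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the study design the pipeline targets: a small
two-group bead-array experiment (fetal astrocytes vs neural stem
cells) with a handful of genes planted at a known enrichment fold,
auxiliary datasets (stem-cell-derived astrocytes, extra NSC lines,
differentiated neurons) with planted presence/absence structure,
promoter sequences with planted motif occurrences, and qPCR Ct tables
encoding known true fold changes.  Everything is reproducible from a
single integer seed, and noiseless generation realizes the planted
structure exactly, so filters can be validated against truth by brute
force.

Intensities are lognormal: a log2-normal per-gene baseline times a
multiplicative noise factor with a chosen coefficient of variation,
matching the positive skew of bead-array fluorescence.  Sub-detection
probes are drawn uniformly in (0, 50) to exercise both cleaning rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .motifs import PWM, reverse_complement
from .preprocess import DETECTION_FLOOR
from .qpcr import CtTable

__all__ = [
    "StudyDesign",
    "generate_expression_study",
    "generate_aux_datasets",
    "MotifPlantSpec",
    "generate_promoters",
    "generate_ct_table",
    "write_truth_table",
]

ASTRO_GROUP = "fetal_astrocyte"
NSC_GROUP = "nsc"


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of a planted-marker two-group bead-array experiment.

    The first group is the enriched (astrocyte-like) group: planted
    marker genes carry *planted_fold* times the baseline intensity in
    every one of its samples.  ``noise_cv`` is the coefficient of
    variation of the multiplicative lognormal noise; 0 disables noise
    so planted folds are realized exactly.  ``frac_below_detection`` of
    the non-planted genes are sub-detection probes with all intensities
    uniform in (0, 50).
    """

    n_genes: int = 500
    groups: tuple[tuple[str, int], ...] = ((ASTRO_GROUP, 2), (NSC_GROUP, 2))
    n_planted_markers: int = 20
    planted_fold: float = 8.0
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_cv: float = 0.1
    frac_below_detection: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or any(n <= 0 for _, n in self.groups):
            raise ValueError("counts must be positive")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if self.n_planted_markers < 0 or self.n_planted_markers > self.n_genes:
            raise ValueError("n_planted_markers must lie in [0, n_genes]")
        if self.planted_fold < 1:
            raise ValueError("planted_fold must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if not 0 <= self.frac_below_detection <= 1:
            raise ValueError("frac_below_detection must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g, n in self.groups for i in range(n)]

    @property
    def group_map(self) -> pd.Series:
        return pd.Series(
            {f"{g}_{i + 1}": g for g, n in self.groups for i in range(n)}, name="group"
        )


def _noise_factor(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Lognormal factor with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), shape))


def generate_expression_study(design: StudyDesign) -> tuple[ExpressionMatrix, set[str]]:
    """Simulate the two-group intensity matrix; returns (matrix, planted genes).

    Planted genes have baseline intensity at or above the detection
    floor (so they survive cleaning) and exactly *planted_fold* times
    that baseline in every enriched-group sample before noise; with
    ``noise_cv = 0`` their minimum pairwise fold equals the planted
    fold exactly and no other gene exceeds fold 1.
    """
    rng = np.random.default_rng(design.seed)
    genes = design.gene_ids
    samples = design.sample_ids
    enriched = [s for s in samples if design.group_map[s] == design.groups[0][0]]

    baseline = 2.0 ** rng.normal(
        design.baseline_log2_mean, design.baseline_log2_sd, design.n_genes
    )
    planted_idx = np.sort(
        rng.choice(design.n_genes, size=design.n_planted_markers, replace=False)
    )
    planted = {genes[i] for i in planted_idx}
    # planted markers must be detectable in the comparator group too
    baseline[planted_idx] = np.maximum(baseline[planted_idx], DETECTION_FLOOR)

    vals = np.tile(baseline[:, None], (1, len(samples)))
    enr_cols = [samples.index(s) for s in enriched]
    vals[np.ix_(planted_idx, enr_cols)] *= design.planted_fold
    vals *= _noise_factor(rng, design.noise_cv, vals.shape)

    nonplanted_idx = np.setdiff1d(np.arange(design.n_genes), planted_idx)
    n_sub = int(round(design.frac_below_detection * nonplanted_idx.size))
    sub_idx = rng.choice(nonplanted_idx, size=n_sub, replace=False)
    vals[sub_idx] = rng.uniform(0.0, DETECTION_FLOOR, (n_sub, len(samples)))
    # keep everything strictly positive even at the sub-detection floor
    vals = np.maximum(vals, np.finfo(float).tiny)

    df = pd.DataFrame(vals, index=genes, columns=samples)
    return ExpressionMatrix(df, design.group_map), planted


def generate_aux_datasets(
    truth: Iterable[str],
    design: StudyDesign,
    stringent_true: Iterable[str] | int | None = None,
    n_derived_astro: int = 3,
    n_other_nsc: int = 2,
    n_neurons: int = 2,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, set[str]]:
    """Auxiliary datasets encoding the stringent marker criterion.

    Returns (derived_astrocytes, extra_NSCs, neurons, stringent_truth).
    The chosen stringent-true subset of *truth* is expressed (above the
    detection floor) in every derived-astrocyte sample and below the
    floor in every extra-NSC and neuron sample; every other planted
    gene deterministically violates exactly one of the three
    conditions, cycling through the failure modes.  All intensities
    are >= 1 so the matrices feed the filters directly.
    """
    rng = np.random.default_rng(design.seed + 1)
    truth = sorted(truth)
    if stringent_true is None:
        stringent_true = truth
    if isinstance(stringent_true, int):
        if stringent_true > len(truth):
            raise ValueError("stringent subset larger than the planted truth set")
        stringent_true = [truth[i] for i in np.sort(
            rng.choice(len(truth), size=stringent_true, replace=False))]
    else:
        stringent_true = sorted(stringent_true)
        if not set(stringent_true) <= set(truth):
            raise ValueError("stringent subset must be planted genes")

    genes = design.gene_ids
    floor = DETECTION_FLOOR

    def high(n):  # clearly expressed
        return rng.uniform(2 * floor, 40 * floor, n)

    def low(n):  # clearly below the detection floor, but >= 1
        return rng.uniform(1.0, floor, n)

    specs = [
        ("derived_astro", n_derived_astro),
        ("extra_nsc", n_other_nsc),
        ("neuron", n_neurons),
    ]
    mats = {}
    for kind, n_samp in specs:
        cols = [f"{kind}_{i + 1}" for i in range(n_samp)]
        vals = np.empty((len(genes), n_samp))
        for gi, g in enumerate(genes):
            if g in stringent_true:
                vals[gi] = high(n_samp) if kind == "derived_astro" else low(n_samp)
            elif g in truth:
                mode = truth.index(g) % 3
                if kind == "derived_astro":
                    vals[gi] = high(n_samp)
                    if mode == 0:  # fails the expression condition
                        vals[gi, 0] = low(1)[0]
                elif kind == "extra_nsc":
                    vals[gi] = low(n_samp)
                    if mode == 1:  # fails the absence condition here
                        vals[gi, 0] = high(1)[0]
                else:
                    vals[gi] = low(n_samp)
                    if mode == 2:  # fails the absence condition in neurons
                        vals[gi, 0] = high(1)[0]
            else:
                vals[gi] = rng.uniform(1.0, 4 * floor, n_samp)
        groups = pd.Series({c: kind for c in cols}, name="group")
        mats[kind] = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols), groups)
    return mats["derived_astro"], mats["extra_nsc"], mats["neuron"], set(stringent_true)


@dataclass(frozen=True)
class MotifPlantSpec:
    """How to plant motif occurrences into synthetic promoter sequences."""

    pwm_id: str
    sites_per_sequence: int = 1
    planted_positions: tuple[int, ...] | None = None
    strand_policy: str = "forward"  # forward | reverse | random
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sites_per_sequence < 0:
            raise ValueError("sites_per_sequence must be nonnegative")
        if self.strand_policy not in ("forward", "reverse", "random"):
            raise ValueError(f"unknown strand policy: {self.strand_policy!r}")
        comp = np.asarray(self.background_composition, float)
        if abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("background composition must be probabilities summing to 1")


def generate_promoters(
    n_sequences: int,
    length: int,
    spec: MotifPlantSpec,
    pwm: PWM,
) -> tuple[dict[str, str], list[tuple[str, int, int, str, str]]]:
    """Random-background promoters with the PWM consensus planted.

    Returns (sequences by id, truth sites) where each truth site is
    (seq_id, start, end, strand, pwm_id) with 0-based half-open
    coordinates.  Planted sites carry the PWM consensus (maximal
    log-odds score by construction); positions are either the explicit
    offsets of *spec* or drawn without overlap.
    """
    L = pwm.length
    if length < L:
        raise ValueError(f"sequence length {length} shorter than motif length {L}")
    if spec.planted_positions is not None:
        for pos in spec.planted_positions:
            if not 0 <= pos <= length - L:
                raise ValueError(f"planted position {pos} does not fit in length {length}")
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.background_composition, float)
    consensus = pwm.consensus
    seqs: dict[str, str] = {}
    truth: list[tuple[str, int, int, str, str]] = []
    for i in range(n_sequences):
        seq_id = f"promoter_{i + 1}"
        bases = rng.choice(list("ACGT"), size=length, p=comp)
        if spec.planted_positions is not None:
            positions = list(spec.planted_positions)
        else:
            positions = []
            # rejection-sample non-overlapping starts
            attempts = 0
            while len(positions) < spec.sites_per_sequence:
                cand = int(rng.integers(0, length - L + 1))
                if all(abs(cand - p) >= L for p in positions):
                    positions.append(cand)
                attempts += 1
                if attempts > 1000 * max(1, spec.sites_per_sequence):
                    raise ValueError("cannot place non-overlapping sites; sequence too short")
        for pos in positions:
            if spec.strand_policy == "random":
                strand = "+" if rng.integers(2) == 0 else "-"
            else:
                strand = "+" if spec.strand_policy == "forward" else "-"
            site = consensus if strand == "+" else reverse_complement(consensus)
            bases[pos : pos + L] = list(site)
            truth.append((seq_id, pos, pos + L, strand, spec.pwm_id))
        seqs[seq_id] = "".join(bases)
    return seqs, truth


def generate_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_folds: Mapping[str, Mapping[str, float]],
    reference_gene: str,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    control_condition: str | None = None,
) -> CtTable:
    """Simulate a qPCR Ct table realizing known true fold changes.

    ``true_folds[gene][condition]`` is the intended fold relative to
    the control condition (default: the first condition; its fold is 1
    by definition).  Per-condition loading offsets are applied to all
    genes and cancel in the comparative-CT normalization.  With
    ``ct_noise_sd = 0`` the downstream computation recovers the planted
    folds exactly.
    """
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} not among genes")
    control = control_condition or conditions[0]
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not among conditions")
    for g, per_cond in true_folds.items():
        for c, f in per_cond.items():
            if f <= 0:
                raise ValueError(f"true fold for {g!r}/{c!r} must be positive")
    rng = np.random.default_rng(seed)
    offsets = {c: float(rng.uniform(-1.0, 1.0)) for c in conditions}
    base_ct = {g: float(rng.uniform(22.0, 28.0)) for g in genes}
    base_ct[reference_gene] = 18.0
    rows = []
    for g in genes:
        for c in conditions:
            if g == reference_gene:
                ct0 = base_ct[g] + offsets[c]
            else:
                fold = true_folds.get(g, {}).get(c, 1.0) if c != control else 1.0
                ct0 = base_ct[g] + offsets[c] - np.log2(fold)
            for rep in range(1, n_replicates + 1):
                ct = ct0 + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                rows.append((g, c, rep, ct))
    return CtTable(pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"]))


def write_truth_table(truth: Iterable[str], path) -> None:
    """Sidecar TSV of planted gene ids (never embedded in the matrix)."""
    with open(path, "w") as fh:
        fh.write("gene\tplanted\n")
        for g in sorted(truth):
            fh.write(f"{g}\t1\n")
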