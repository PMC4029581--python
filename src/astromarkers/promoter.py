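"""TSS-anchored promoter windows, motif hits, and the shared-TF query.

Three windows around each gene's transcription start site (TSS) are
scanned by default: the proximal promoter (-500 to +100), the distal
promoter (-2000 to -500) and a wide regulatory region (-8000 to
+2000), with signed offsets in biological orientation — minus-strand
genes are reverse-complemented so "upstream" stays upstream.  Hits
from PWM scanning carry empirical p-values and an optional
conservation flag; the final query asks which transcription factors
have a significant site in *every* target gene's promoter while also
being expressed in the astrocyte samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, normalize_symbol
from .motifs import PWM, NullModel, empirical_pvalues, reverse_complement, scan
from .preprocess import DETECTION_FLOOR

__all__ = [
    "PromoterWindows",
    "TssAnnotation",
    "MotifHit",
    "read_tss_annotations",
    "extract_windows",
    "scan_windows",
    "read_conservation_track",
    "conservation_filter",
    "shared_binding_tfs",
    "write_hits",
    "DEFAULT_TARGET_GENES",
]

# structural genes used as the default promoter-scan target panel
DEFAULT_TARGET_GENES = ("GFAP", "CD44", "LGALS3", "DUSP23", "S100A6")


@dataclass(frozen=True)
class PromoterWindows:
    """Signed TSS-relative windows (bp); negative = upstream.

    Stored as (start, end) offsets, half-open after anchoring; the
    defaults are the proximal/distal/wide promoter regions.
    """

    windows: tuple[tuple[int, int], ...] = ((-500, 100), (-2000, -500), (-8000, 2000))
    names: tuple[str, ...] = ("proximal", "distal", "wide")

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.names):
            raise ValueError("one name per window required")
        for lo, hi in self.windows:
            if hi <= lo:
                raise ValueError(f"empty window ({lo}, {hi})")


@dataclass(frozen=True)
class TssAnnotation:
    contig: str
    position: int  # 0-based TSS coordinate on the contig
    strand: str  # '+' or '-'
    gene: str


@dataclass
class MotifHit:
    """A scored, strand-aware PWM occurrence inside one promoter window."""

    gene: str
    window_id: str
    offset: int  # 0-based within the (oriented) window
    strand: str  # '+' or '-' relative to the window sequence
    pwm_id: str
    score: float
    p_value: float = 1.0
    conserved: bool | None = None


def read_tss_annotations(path: str | Path) -> list[TssAnnotation]:
    """BED-like TSV: contig, TSS position (0-based), strand, gene symbol."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: need contig, position, strand, gene")
        contig, pos, strand, gene = parts[0], int(parts[1]), parts[2], parts[3]
        if strand not in "+-":
            raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
        out.append(TssAnnotation(contig, pos, strand, normalize_symbol(gene)))
    return out


def _get_contig(genome, contig: str) -> str:
    if isinstance(genome, Mapping):
        seq = genome[contig]
    else:  # pyfaidx.Fasta or similar
        seq = genome[contig][:].seq
    return str(seq).upper()


def extract_windows(
    genome,
    tss_annotations: Sequence[TssAnnotation],
    windows: PromoterWindows | None = None,
) -> dict[str, dict[str, str]]:
    """Per-gene, per-window promoter sequences anchored at the TSS.

    *genome* is either a mapping contig -> sequence or a pyfaidx.Fasta.
    For a plus-strand TSS at t, a window (lo, hi) covers contig
    [t+lo, t+hi); for a minus-strand gene it covers [t-hi, t-lo)
    reverse-complemented, so offset 0 of the returned sequence is the
    biological 5' end of the window in every case.  Windows running off
    a contig edge are truncated with a warning.
    """
    windows = windows or PromoterWindows()
    out: dict[str, dict[str, str]] = {}
    for ann in tss_annotations:
        contig = _get_contig(genome, ann.contig)
        if not 0 <= ann.position < len(contig):
            raise ValueError(
                f"TSS of {ann.gene} at {ann.position} outside contig "
                f"{ann.contig} (length {len(contig)})"
            )
        per_gene: dict[str, str] = {}
        for name, (lo, hi) in zip(windows.names, windows.windows):
            if ann.strand == "+":
                start, end = ann.position + lo, ann.position + hi
            else:
                start, end = ann.position - hi, ann.position - lo
            cstart, cend = max(0, start), min(len(contig), end)
            if (cstart, cend) != (start, end):
                warnings.warn(
                    f"window {name} of {ann.gene} truncated to contig bounds "
                    f"[{cstart}, {cend})",
                    stacklevel=2,
                )
            seq = contig[cstart:cend]
            per_gene[name] = seq if ann.strand == "+" else reverse_complement(seq)
        out[ann.gene] = per_gene
    return out


def scan_windows(
    sequences: Mapping[str, Mapping[str, str]],
    pwms: Sequence[PWM],
    null: NullModel = "shuffle_mono",
    n_permutations: int = 1000,
    seed: int | None = None,
    p_cutoff: float | None = None,
) -> list[MotifHit]:
    """Scan every gene's windows with every PWM, attaching empirical p-values.

    Returns all positions when *p_cutoff* is None, otherwise only hits
    with p < p_cutoff.  Randomness (for shuffle nulls) is seeded once
    and shared across scans, so results are reproducible end to end.
    """
    rng = np.random.default_rng(seed)
    hits: list[MotifHit] = []
    for gene in sequences:
        for window_id, seq in sequences[gene].items():
            for pwm in pwms:
                if len(seq) < pwm.length:
                    continue
                scores = scan(seq, pwm)
                pv = empirical_pvalues(
                    scores.ravel(), seq, pwm, null=null,
                    n_permutations=n_permutations, seed=rng,
                ).reshape(scores.shape)
                for s_idx, strand in enumerate("+-"):
                    for i in range(scores.shape[1]):
                        p = float(pv[s_idx, i])
                        if p_cutoff is not None and not p < p_cutoff:
                            continue
                        hits.append(
                            MotifHit(
                                gene=gene, window_id=window_id, offset=i,
                                strand=strand, pwm_id=pwm.id,
                                score=float(scores[s_idx, i]), p_value=p,
                            )
                        )
    return hits


def read_conservation_track(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """BED-like per-base conservation: seq_id, start, end, score."""
    track: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: need seq_id, start, end, score")
        try:
            start, end, score = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed record") from exc
        if end <= start:
            raise ValueError(f"{path}:{lineno}: empty interval")
        track.setdefault(parts[0], []).append((start, end, score))
    return track


def _mean_track_score(
    intervals: Iterable[tuple[int, int, float]], start: int, end: int
) -> float:
    per_base = np.zeros(end - start)
    for istart, iend, score in intervals:
        lo, hi = max(istart, start), min(iend, end)
        if hi > lo:
            per_base[lo - start : hi - start] = score  # later records override
    return float(per_base.mean())


def conservation_filter(
    hits: Sequence[MotifHit],
    track: Mapping[str, list[tuple[int, int, float]]],
    min_mean_score: float,
    motif_lengths: Mapping[str, int],
    *,
    key: str = "gene",
    strict: bool = False,
) -> list[MotifHit]:
    """Flag hits whose mean per-base conservation clears *min_mean_score*.

    Track records are keyed by gene (window-oriented coordinates);
    uncovered bases score 0.  By default hits are only flagged; with
    *strict* unconserved hits are dropped.
    """
    out = []
    for hit in hits:
        seq_id = getattr(hit, key)
        L = motif_lengths[hit.pwm_id]
        mean = _mean_track_score(track.get(seq_id, []), hit.offset, hit.offset + L)
        flagged = replace(hit, conserved=mean >= min_mean_score)
        if strict and not flagged.conserved:
            continue
        out.append(flagged)
    return out


def shared_binding_tfs(
    hits: Sequence[MotifHit],
    m: ExpressionMatrix,
    target_genes: Sequence[str] = DEFAULT_TARGET_GENES,
    p_cutoff: float = 0.01,
    expressed_floor: float = DETECTION_FLOOR,
    expression_group: str = "fetal_astrocyte",
    pwm_to_symbol: Mapping[str, str] | None = None,
) -> list[str]:
    """TFs with a significant site in *every* target promoter and astrocyte expression.

    A transcription factor qualifies iff (a) it has at least one hit
    with p < p_cutoff in each target gene's scanned windows, and (b)
    its own intensity is >= expressed_floor in every sample of
    *expression_group*.  PWM ids are mapped to gene symbols via
    *pwm_to_symbol* (identity after normalization by default).
    """
    targets = [normalize_symbol(g) for g in target_genes]
    scanned = {h.gene for h in hits}
    missing = [g for g in targets if g not in scanned]
    if missing:
        raise ValueError(f"target gene(s) without scanned windows: {missing}")
    sig: dict[str, set[str]] = {}
    for h in hits:
        if h.gene in targets and h.p_value < p_cutoff:
            sig.setdefault(h.pwm_id, set()).add(h.gene)
    astro_samples = m.samples_in(expression_group)
    out = []
    for pwm_id, genes_hit in sorted(sig.items()):
        if len(genes_hit) < len(targets):
            continue
        symbol = normalize_symbol((pwm_to_symbol or {}).get(pwm_id, pwm_id))
        if symbol not in m.values.index:
            continue
        if (m.values.loc[symbol, astro_samples] >= expressed_floor).all():
            out.append(symbol)
    return sorted(set(out))


def write_hits(hits: Sequence[MotifHit], path: str | Path) -> None:
    """Emit hits as a BED-like TSV (gene, window, offset, strand, pwm, score, p, conserved)."""
    df = pd.DataFrame(
        [
            (h.gene, h.window_id, h.offset, h.strand, h.pwm_id,
             round(h.score, 6), h.p_value, "" if h.conserved is None else int(h.conserved))
            for h in hits
        ],
        columns=["gene", "window", "offset", "strand", "pwm", "score", "p_value", "conserved"],
    )
    df.to_csv(path, sep="\t", index=False)
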