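"""Cleaning and detection rules for bead-array intensity matrices.

Two rules define "cleaning": probes whose intensity falls below the
detection floor (default 50) in *every* sample are dropped as
undetected, and any remaining intensity below the clip floor
(default 1) is raised to that floor so all downstream fold ratios are
finite.  The same detection floor also defines the "expressed" call
used when counting pathway genes per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["CleaningPolicy", "clean_matrix", "expressed_genes", "subtract_offset"]

DETECTION_FLOOR = 50.0
CLIP_FLOOR = 1.0


@dataclass(frozen=True)
class CleaningPolicy:
    """Thresholds for probe removal and intensity clipping.

    detection_floor : probes with all intensities strictly below this are removed.
    clip_floor      : surviving intensities strictly below this are set to it.
    """

    detection_floor: float = DETECTION_FLOOR
    clip_floor: float = CLIP_FLOOR

    def __post_init__(self) -> None:
        if self.clip_floor > self.detection_floor:
            raise ValueError("clip_floor must not exceed detection_floor")
        if self.clip_floor <= 0:
            raise ValueError("clip_floor must be positive")


def clean_matrix(m: ExpressionMatrix, policy: CleaningPolicy | None = None) -> ExpressionMatrix:
    """Drop all-below-floor probes, then clip tiny intensities up to the clip floor.

    Row order is preserved; values at or above the clip floor are untouched.
    Idempotent: cleaning a cleaned matrix is a no-op.
    """
    policy = policy or CleaningPolicy()
    detected = (m.values >= policy.detection_floor).any(axis=1)
    vals = m.values.loc[detected].clip(lower=policy.clip_floor)
    return ExpressionMatrix(vals, m.groups.copy())


def expressed_genes(
    m: ExpressionMatrix,
    group: str,
    threshold: float = DETECTION_FLOOR,
    mode: Literal["all_in_group", "any_sample"] = "all_in_group",
) -> set[str]:
    """Genes called expressed relative to *threshold*.

    ``all_in_group`` requires intensity >= threshold in every sample of
    *group* (the "expressed 2/2" convention for a two-sample group);
    ``any_sample`` requires it in at least one sample of the whole matrix.
    """
    if mode == "any_sample":
        mask = (m.values >= threshold).any(axis=1)
    elif mode == "all_in_group":
        cols = m.samples_in(group)
        mask = (m.values[cols] >= threshold).all(axis=1)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return set(m.values.index[mask])


def subtract_offset(m: ExpressionMatrix, offsets: dict[str, float]) -> ExpressionMatrix:
    """Subtract a per-sample constant background offset, clipping at 0.

    A deliberately simple stand-in for scanner-side background
    subtraction, intended for synthetic data; real exports are assumed
    to arrive already background-subtracted.
    """
    vals = m.values.copy()
    for sample, off in offsets.items():
        if sample not in vals.columns:
            raise KeyError(f"unknown sample: {sample!r}")
        vals[sample] = np.clip(vals[sample] - off, 0.0, None)
    return ExpressionMatrix(vals, m.groups.copy())
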