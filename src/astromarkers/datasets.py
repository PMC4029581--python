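"""Bundled four-sample intensity tables transcribed from the study's printed results.

Each table has the same four columns — two fetal-astrocyte samples
(Lonza and ScienCell) and two neural-stem-cell samples (NCRM-5 and H9)
— and is shipped verbatim as TSV package data, with no re-scaling:

``stringent_markers``
    The 24 genes that survived the full stringent marker cascade
    (>= 5-fold enriched in all four astrocyte/NSC pairs plus the
    cross-dataset presence/absence checks).
``tf_up``
    The 46 transcription factors up-regulated >= 2-fold in both
    astrocyte samples against both NSC samples.
``tf_down``
    The 51 transcription factors with the mirror-image down-regulation.
``tfbs_tf``
    The 23 astrocyte-expressed transcription factors reported to have
    binding sites in the promoters of the enriched structural genes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .matrix import ExpressionMatrix
from .simulate import ASTRO_GROUP, NSC_GROUP

__all__ = ["FIXTURE_IDS", "ASTRO_SAMPLES", "NSC_SAMPLES", "load_fixture"]

FIXTURE_IDS = ("stringent_markers", "tf_up", "tf_down", "tfbs_tf")

ASTRO_SAMPLES = ("LONZA_FET_AST", "SCIENCELL_FET_AST")
NSC_SAMPLES = ("NCRM5_NSC", "H9_NSC")


def load_fixture(table_id: str) -> ExpressionMatrix:
    """Load one bundled intensity table as an :class:`ExpressionMatrix`.

    The first two columns are labelled ``fetal_astrocyte`` and the last
    two ``nsc``.  Raises ``KeyError`` for an unknown id.
    """
    if table_id not in FIXTURE_IDS:
        raise KeyError(f"unknown table id {table_id!r}; choose from {FIXTURE_IDS}")
    ref = resources.files("astromarkers.data") / f"{table_id}.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0)
    groups = pd.Series(
        {**{s: ASTRO_GROUP for s in ASTRO_SAMPLES}, **{s: NSC_GROUP for s in NSC_SAMPLES}},
        name="group",
    )
    return ExpressionMatrix(df.astype(float), groups)
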