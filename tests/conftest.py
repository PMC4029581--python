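import numpy as np
import pandas as pd
import pytest

from astromarkers.matrix import ExpressionMatrix

ASTRO = "fetal_astrocyte"
NSC = "nsc"


def make_matrix(rows: dict[str, list[float]], groups: dict[str, str] | None = None,
                samples: list[str] | None = None) -> ExpressionMatrix:
    """Four-column (2 astro + 2 NSC) matrix unless samples/groups given."""
    if samples is None:
        samples = ["ast_1", "ast_2", "nsc_1", "nsc_2"]
    if groups is None:
        groups = {s: (ASTRO if s.startswith("ast") else NSC) for s in samples}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    return ExpressionMatrix(df, pd.Series(groups))


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    return make_matrix(
        {
            "GFAP": [3280, 1456, 8, 1],
            "FLAT": [100, 100, 100, 100],
            "LOW": [30, 40, 20, 10],
            "CLIP": [0.3, 60, 70, 80],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_clean_matrix(rng: np.random.Generator, n_genes: int = 50) -> ExpressionMatrix:
    """Random strictly-positive matrix ready for fold filtering."""
    vals = 2.0 ** rng.normal(7, 2, (n_genes, 4))
    rows = {f"G{i:03d}": list(np.maximum(vals[i], 1.0)) for i in range(n_genes)}
    return make_matrix(rows)
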