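import numpy as np
import pandas as pd
import pytest

from exoref.expression_io import ExpressionMatrix, SampleDesign

# Published ten-gene benchmark: feature -> (log2 expression, expression rank,
# CV, M, final stability rank as printed).
GENE_TABLE = {
    "OAZ1":    (9.289,  2, 0.405, 0.561, 1),
    "SERF2":   (8.608,  5, 0.492, 0.588, 2),
    "MPP1":    (7.748,  9, 0.460, 0.597, 3),
    "H3F3AP4": (7.750,  8, 0.654, 0.563, 4),
    "WIPF1":   (7.645, 10, 0.538, 0.626, 5),
    "PCMTD1":  (8.067,  6, 0.511, 0.704, 6),
    "ARF1":    (7.850,  7, 0.660, 0.564, 7),
    "SOD2":    (8.696,  4, 0.655, 0.725, 8),
    "B2M":     (12.826, 1, 0.688, 0.827, 9),
    "ITM2B":   (8.754,  3, 0.723, 0.934, 10),
}

# Published six-miRNA benchmark, same column layout.
MIRNA_TABLE = {
    "hsa-miR-4468":    (11.743, 4, 0.476, 0.304, 1),
    "hsa-miR-6835-3p": (12.208, 1, 0.498, 0.455, 2),
    "hsa-miR-192-3p":  (11.223, 5, 0.543, 0.340, 3),
    "hsa-miR-125a-5p": (11.102, 6, 0.557, 0.336, 4),
    "hsa-miR-4469":    (11.756, 3, 0.515, 0.521, 5),
    "hsa-miR-6731-5p": (12.087, 2, 0.667, 0.601, 6),
}


def table_series(table: dict, col: int) -> pd.Series:
    return pd.Series({k: v[col] for k, v in table.items()})


@pytest.fixture
def gene_cv():
    return table_series(GENE_TABLE, 2)


@pytest.fixture
def gene_m():
    return table_series(GENE_TABLE, 3)


@pytest.fixture
def mirna_cv():
    return table_series(MIRNA_TABLE, 2)


@pytest.fixture
def mirna_m():
    return table_series(MIRNA_TABLE, 3)


def make_matrix(arr, scale="count", features=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples), scale=scale)


def make_design(groups: dict[str, tuple[str, int]]) -> SampleDesign:
    """groups: label -> (condition, n_samples); samples named label_k."""
    rows = []
    for label, (condition, n) in groups.items():
        for k in range(n):
            rows.append({"sample": f"{label}_{k}", "group": label, "condition": condition})
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def two_group_design():
    return make_design({"T": ("case", 10), "HC": ("control", 10)})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
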