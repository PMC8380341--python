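from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cerna.diffexpr import CountMatrix
from cerna.synthdata import SimConfig, generate_dataset

RNA = "ACGU"


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA), size=length))


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_case=10,
        n_control=10,
        n_features={"mRNA": 40, "lncRNA": 16, "circRNA": 10, "miRNA": 12},
        n_planted_triads=4,
        de_fraction={"mRNA": 0.1, "lncRNA": 0.1, "circRNA": 0.1, "miRNA": 0.1},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture
def two_group_matrix():
    """2 case + 2 ctrl samples; feature fX has pooled counts 12 vs 3."""
    counts = pd.DataFrame(
        {
            "case_0": [6, 50],
            "case_1": [6, 50],
            "ctrl_0": [2, 50],
            "ctrl_1": [1, 50],
        },
        index=["fX", "fFlat"],
    )
    sample_map = {"case_0": "case", "case_1": "case", "ctrl_0": "control", "ctrl_1": "control"}
    totals = {s: 50_000.0 for s in counts.columns}
    return counts, sample_map, totals


def make_matrix(counts: pd.DataFrame, rna_class: str = "mRNA") -> CountMatrix:
    return CountMatrix(counts=counts, rna_class=rna_class)
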