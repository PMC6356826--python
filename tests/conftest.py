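import numpy as np
import pandas as pd
import pytest

from hybridity import CountMatrix, SimConfig, simulate_counts
from hybridity.pipeline import run_de_suite


@pytest.fixture
def tiny_counts():
    """2 genes x 4 samples (F, F, L, L) hand-written fixture."""
    counts = pd.DataFrame(
        {
            "F_1": [10, 0],
            "F_2": [12, 2],
            "L_1": [30, 8],
            "L_2": [28, 6],
        },
        index=pd.Index(["g1", "g2"], name="gene_id"),
    )
    groups = {"F_1": "F", "F_2": "F", "L_1": "L", "L_2": "L"}
    return CountMatrix(counts, groups)


@pytest.fixture(scope="session")
def balanced_sim():
    """One simulated dataset with all six modes equally represented."""
    props = {
        m: 1 / 6
        for m in (
            "null",
            "additive",
            "dominance_F",
            "dominance_L",
            "over_dominance",
            "under_dominance",
        )
    }
    cfg = SimConfig(n_genes=600, mode_proportions=props, seed=11)
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def balanced_suite(balanced_sim):
    cfg, cm, truth = balanced_sim
    suite = run_de_suite(cm, mpv_seed=11)
    return cm, truth, suite


def random_count_matrix(rng, n_genes=5, n_samples=3):
    counts = pd.DataFrame(
        rng.integers(1, 200, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    groups = {c: ("F" if j % 2 == 0 else "L") for j, c in enumerate(counts.columns)}
    return CountMatrix(counts, groups)
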