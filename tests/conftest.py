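import numpy as np
import pytest

from mintde import SimulationConfig, TimeCourseAssay, pair_assays, simulate_pair


@pytest.fixture
def tiny_assay():
    """2 genes x 3 times x 2 replicates, hand-constructed."""
    values = np.array(
        [
            [[0.0, 0.2], [1.0, 1.2], [2.0, 2.2]],
            [[0.1, -0.1], [0.5, 0.7], [-0.5, -0.3]],
        ]
    )
    return TimeCourseAssay(
        assay_name="toy",
        gene_ids=["gA", "gB"],
        times=np.array([0.0, 2.0, 4.0]),
        replicate_ids=["1", "2"],
        values=values,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-signal simulation shared across tests."""
    cfg = SimulationConfig(G=400, seed=11)
    pair, truth = simulate_pair(cfg)
    return pair, truth


@pytest.fixture(scope="session")
def null_pair():
    """Pure-noise pair (every gene in the null class), default shape."""
    cfg = SimulationConfig(
        G=2000,
        seed=7,
        class_fractions={
            "null": 1.0,
            "de_x_only": 0.0,
            "de_y_only": 0.0,
            "de_both_uncorrelated": 0.0,
            "de_both_correlated": 0.0,
            "correlated_moderate_de": 0.0,
        },
    )
    pair, _ = simulate_pair(cfg)
    return pair


def make_assay(values, times=None, name="a"):
    """Helper: assay from a (G, T+1, B) array with default labels."""
    values = np.asarray(values, dtype=float)
    G, nt, B = values.shape
    if times is None:
        times = np.arange(nt, dtype=float)
    return TimeCourseAssay(
        assay_name=name,
        gene_ids=[f"g{i}" for i in range(G)],
        times=np.asarray(times, dtype=float),
        replicate_ids=[str(b + 1) for b in range(B)],
        values=values,
    )


def make_pair(x_vals, y_vals, times=None):
    return pair_assays(
        make_assay(x_vals, times, "x"), make_assay(y_vals, times, "y"),
        join="strict",
    )
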