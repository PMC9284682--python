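import numpy as np
import pandas as pd
import pytest

from plowbatch.io_core import CountMatrix, SampleTable
from plowbatch.simulate import SimulationConfig, simulate_dataset


def make_table(p_low, groups, batches, ids=None):
    ids = ids or [f"s{i}" for i in range(len(p_low))]
    return SampleTable(
        pd.DataFrame({"sample_id": ids, "group": groups, "batch": batches, "p_low": p_low})
    )


def cells16(n=4):
    return {(g, b): n for g in ("g1", "g2") for b in ("b1", "b2")}


@pytest.fixture
def small_table():
    return make_table([0.1, 0.1, 0.9, 0.9], ["A", "B", "A", "B"], ["b1", "b1", "b2", "b2"])


@pytest.fixture
def tiny_counts():
    return CountMatrix(["g1", "g2"], ["s1", "s2"], np.array([[1, 2], [3, 4]]))


@pytest.fixture(scope="session")
def coupled_dataset():
    """Quality-coupled simulation at the compact 16-sample x 1000-gene design."""
    cfg = SimulationConfig(seed=7, n_genes=1000, samples_per_cell=cells16())
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Default 40-sample x 2000-gene quality-coupled simulation."""
    return simulate_dataset(SimulationConfig(seed=7))
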