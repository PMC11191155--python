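import numpy as np
import pandas as pd
import pytest

from consensig.core_types import CountMatrix, Dataset, SampleTable
from consensig.simulate import SimConfig, simulate_dataset


@pytest.fixture()
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(11)
    return CountMatrix(
        [f"g{i}" for i in range(20)],
        ["s1", "s2", "s3", "s4"],
        rng.integers(0, 500, size=(20, 4)),
    )


@pytest.fixture()
def small_table() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "class_label": [0, 1, 0, 1],
                "batch_id": ["b1", "b1", "b2", "b2"],
                "role": ["train"] * 4,
            }
        )
    )


@pytest.fixture(scope="session")
def sim_two_batch() -> tuple:
    """A modest two-batch simulated dataset shared across tests."""
    cfg = SimConfig(
        n_genes=300,
        n_batches=2,
        samples_per_batch=60,
        n_signal=10,
        signal_lfc=1.5,
        batch_logfc_sd=0.5,
        seed=21,
    )
    return simulate_dataset(cfg)
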