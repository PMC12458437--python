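import numpy as np
import pandas as pd
import pytest

from sridiff import CountTable, SimulationConfig, generate_paired_dataset


@pytest.fixture(scope="session")
def null_config():
    """Complete null: no differential taxa, no load shift."""
    return SimulationConfig(
        n_taxa=50, n_per_group=20, frac_diff=0.0, scale_shift_log2=0.0, seed=101
    )


@pytest.fixture(scope="session")
def null_dataset(null_config):
    return generate_paired_dataset(null_config)


@pytest.fixture(scope="session")
def spiked_dataset():
    """One strongly differential taxon (|effect| = 4 log2 units), N=30/group."""
    cfg = SimulationConfig(
        n_taxa=50,
        n_per_group=30,
        frac_diff=1 / 50,
        effect_log2=4.0,
        scale_shift_log2=0.0,
        seed=202,
    )
    return generate_paired_dataset(cfg)


@pytest.fixture
def tiny_counts():
    """A hand-sized count table: 4 taxa, 3+3 samples."""
    counts = pd.DataFrame(
        [
            [30, 20, 25, 40, 50, 45],
            [10, 15, 12, 5, 3, 4],
            [5, 8, 6, 7, 6, 5],
            [55, 57, 57, 48, 41, 46],
        ],
        index=["A", "B", "C", "D"],
        columns=[f"s{i}" for i in range(6)],
    )
    condition = pd.Series([0, 0, 0, 1, 1, 1], index=counts.columns)
    return CountTable(counts=counts, condition=condition)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
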