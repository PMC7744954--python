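import numpy as np
import pandas as pd
import pytest

from oomt.methylome import make_call_table
from oomt.synthetic_data import SimulationConfig, simulate_methylome_dataset


@pytest.fixture(scope="session")
def small_meth_config():
    """Small-genome methylome-only study conditions for fast pipeline tests:
    planted DMRs are the only age difference."""
    return SimulationConfig(
        seed=11,
        genome_length=5_000_000,
        n_true_dmrs=20,
        aged_shift_pp=0.0,
    )


@pytest.fixture(scope="session")
def small_meth_ds(small_meth_config):
    return simulate_methylome_dataset(small_meth_config)


@pytest.fixture
def three_cell_tables():
    """Three tiny call tables with overlapping positions for merge oracles."""
    t1 = make_call_table("chr1", [10, 20, 30], [1, 0, 1], [0, 1, 0])
    t2 = make_call_table("chr1", [20, 30, 40], [1, 1, 0], [0, 0, 1])
    t3 = make_call_table("chr1", [10, 40], [0, 1], [1, 0])
    return [t1, t2, t3]


@pytest.fixture
def domain_fixture():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [0, 100, 0],
            "end": [100, 200, 50],
            "class_label": ["hyper", "hypo", "inter"],
            "name": ["d1", "d2", "d3"],
        }
    )
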