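import numpy as np
import pandas as pd
import pytest

from scgrn import make_benchmark
from scgrn.synthetic import BenchmarkConfig


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced multi-condition benchmark for fast pipeline tests."""
    cfg = BenchmarkConfig(
        n_genes=60,
        n_tfs=8,
        n_conditions=2,
        cells_per_condition=120,
        targets_per_tf=8,
        depth_median=1200.0,
    )
    return make_benchmark(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_counts():
    return pd.DataFrame(
        [[4, 0, 2], [1, 3, 2], [0, 5, 2]],
        index=["c1", "c2", "c3"],
        columns=["g1", "g2", "g3"],
    )
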