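import numpy as np
import pytest

from emg_openset.grids import GridSpec
from emg_openset.synthetic import BenchmarkConfig, make_benchmark


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A small but complete 13-task benchmark (1 subject, short reps)."""
    cfg = BenchmarkConfig(
        n_subjects=1,
        reps=2,
        rep_duration_s=2.0,
        dynamic_duration_s=12.0,
        baseline_duration_s=5.0,
    )
    return cfg, make_benchmark(cfg, rng_seed=123)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
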