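import numpy as np
import pytest

from mips import ANNConfig, DGPConfig, ObservedData, simulate


@pytest.fixture(scope="session")
def bench_data():
    """A moderate sample from the benchmark generative process."""
    data, po = simulate(DGPConfig(n=400, seed=20240501))
    return data, po


@pytest.fixture()
def small_data():
    """A small sample for fast estimator checks."""
    data, _ = simulate(DGPConfig(n=80, seed=7))
    return data


@pytest.fixture()
def fast_ann():
    """A short-schedule network config for tests that only exercise plumbing."""
    return ANNConfig(epochs=200, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_data(y, a, x, columns=None):
    return ObservedData(
        y=np.asarray(y, float), a=np.asarray(a), x=np.asarray(x, float),
        columns=columns or [],
    )
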