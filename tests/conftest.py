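import numpy as np
import pytest

from spiketau.pipeline import BenchmarkConfig, run_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A 150-unit parametric benchmark over the full parameter grid with all
    four methods; shared by the QC-monotonicity and method-ordering tests."""
    cfg = BenchmarkConfig(n_units=150, seed=42)
    return run_benchmark(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_train(rng, n, length=600_000.0):
    """Sorted distinct uniform spike times on [0, length)."""
    t = np.sort(rng.uniform(0.0, length, size=n))
    t = t[np.concatenate(([True], np.diff(t) > 0))]
    return t
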