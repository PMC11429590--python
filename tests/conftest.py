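import numpy as np
import pytest

import segjoint as sj


@pytest.fixture(scope="session")
def cross_a_config():
    return sj.cross_config("A")


@pytest.fixture(scope="session")
def cross_b_config():
    return sj.cross_config("B")


@pytest.fixture(scope="session")
def cross_a_dataset(cross_a_config):
    """One simulated cross-A-shaped dataset (published sample sizes)."""
    return sj.simulate(cross_a_config.with_seed(20240))


@pytest.fixture(scope="session")
def cross_a_fit(cross_a_dataset):
    """MX2-A-AD fitted once to the shared cross-A dataset."""
    return sj.fit(cross_a_dataset, "MX2-A-AD",
                  sj.FitConfig(n_starts=6, seed=1))


@pytest.fixture
def tiny_dataset():
    """Minimal valid dataset: two observations per generation."""
    vals = {
        "P1": [120.0, 125.0], "P2": [70.0, 75.0], "F1": [100.0, 104.0],
        "F2": [85.0, 110.0], "BC1P1": [105.0, 130.0], "BC1P2": [80.0, 95.0],
    }
    return sj.SixGenDataset("toy", {
        g: sj.GenerationSample(g, np.array(v), "toy") for g, v in vals.items()
    })


def normal_dataset(mu=100.0, sigma=10.0, n=200, seed=0):
    """All six generations drawn from one normal distribution."""
    rng = np.random.default_rng(seed)
    return sj.SixGenDataset("null", {
        g: sj.GenerationSample(g, rng.normal(mu, sigma, n), "null")
        for g in sj.GENERATIONS
    })
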