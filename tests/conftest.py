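import numpy as np
import pytest

import anthospec as asp
from anthospec.spectra import (LeafSample, PigmentProfile, SpectralDataset,
                               SpectralGrid)


@pytest.fixture(scope="session")
def default_dataset():
    """One standard synthetic dataset: 210 leaves, 436-780 nm at 1 nm."""
    return asp.generate_dataset(asp.GeneratorConfig(n=210, seed=1))


@pytest.fixture(scope="session")
def default_folds(default_dataset):
    return asp.make_folds(len(default_dataset), 10, seed=1)


@pytest.fixture
def tiny_dataset():
    """3 samples on a 3-channel grid, hand-set reflectances."""
    grid = SpectralGrid(np.array([436.0, 437.0, 438.0]))
    samples = (
        LeafSample("a", PigmentProfile(10.0, 5.0, 3.0),
                   np.array([0.5, 0.4, 0.3])),
        LeafSample("b", PigmentProfile(20.0, 15.0, 6.0),
                   np.array([0.25, 0.2, 0.15])),
        LeafSample("c", PigmentProfile(1.0, 0.5, None),
                   np.array([0.9, 0.8, 0.7])),
    )
    return SpectralDataset(grid, samples, "reflectance")


def make_signal_dataset(seed, n=30, slope=0.05, noise=0.05):
    """3-channel absorbance set: channel 1 linear in content, 2-3 pure noise."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 30, n)
    X = np.empty((n, 3))
    X[:, 0] = slope * y + rng.normal(0, noise, n)
    X[:, 1] = rng.normal(0, 1, n)
    X[:, 2] = rng.normal(0, 1, n)
    grid = SpectralGrid(np.array([500.0, 600.0, 700.0]))
    samples = tuple(
        LeafSample(f"s{i}", PigmentProfile(10.0, float(y[i]), 3.0), X[i])
        for i in range(n)
    )
    return SpectralDataset(grid, samples, "absorbance")
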