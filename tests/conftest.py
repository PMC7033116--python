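import numpy as np
import pandas as pd
import pytest

from tumortraj import simdata


@pytest.fixture(scope="session")
def small_dataset():
    """Default-design dataset, scaled down for speed (26 samples x 40 cells)."""
    cfg = simdata.SimConfig(seed=11, cells_per_sample=40, n_genes=1500)
    counts, metadata, truth = simdata.simulate_dataset(cfg)
    return counts, metadata, truth


@pytest.fixture(scope="session")
def tumor_dataset():
    """12 tumor samples, ~800 tumor-lineage cells, for trajectory tests."""
    cfg = simdata.SimConfig(seed=3, n_samples_control=0, n_samples_mutant=12,
                            cells_per_sample=70, tumor_fraction=0.95,
                            genotype_effect=0.0)
    counts, metadata, truth = simdata.simulate_dataset(cfg)
    return counts, metadata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def blobs():
    """Three well-separated Gaussian blobs in 5D with labels."""
    r = np.random.default_rng(42)
    centers = np.array([[0, 0, 0, 0, 0], [20, 0, 0, 0, 0], [0, 20, 0, 0, 0]],
                       float)
    pts = np.concatenate([c + r.normal(0, 1.0, size=(60, 5)) for c in centers])
    labels = np.repeat([0, 1, 2], 60)
    return pd.DataFrame(pts), labels
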