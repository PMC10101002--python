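import numpy as np
import pandas as pd
import pytest

from fermnet import (
    AbundanceTable,
    GeneratorConfig,
    MetaboliteTable,
    SampleMetadata,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic dataset, seed 1 (shared: treat as read-only)."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Small, fast dataset with the planted module structure intact."""
    cfg = GeneratorConfig(n_bacteria=120, n_fungi=30,
                          depth_bacteria=8000, depth_fungi=8000,
                          n_modules=3, module_size=8, n_connectors=1,
                          selected_fraction=0.05, n_noise_metabolites=6)
    return generate_dataset(cfg, seed=3)


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[10, 0, 3], [5, 5, 0], [0, 5, 7]],
        index=["t1", "t2", "t3"], columns=["s1", "s2", "s3"], dtype=float)
    return AbundanceTable(counts, pd.Series("bacteria", index=counts.index),
                         False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
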