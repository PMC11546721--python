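import numpy as np
import pandas as pd
import pytest

from rhizolink.pipeline import bundle_from_dataset
from rhizolink.simulate import GeneratorParams, simulate_dataset, write_bundle


@pytest.fixture(scope="session")
def small_params():
    """One replicate per design cell: 126 samples, 120 ASVs."""
    return GeneratorParams(n_replicates=1, rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params)


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    return bundle_from_dataset(small_dataset)


@pytest.fixture()
def bundle_dir(small_dataset, tmp_path):
    write_bundle(small_dataset, tmp_path / "bundle")
    return tmp_path / "bundle"


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_counts():
    return pd.DataFrame(
        [[4, 4, 2], [10, 0, 0], [5, 5, 10]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3"],
    )
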