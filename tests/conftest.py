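import numpy as np
import pytest

from thermocanopy.synthetic import SceneSpec, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Feature table of the full study-condition dataset: 54 images per
    treatment at camera resolution, master seed 0."""
    return generate_dataset(n_per_class=54, seed=0)


@pytest.fixture(scope="session")
def small_spec():
    """Quarter-resolution scene geometry for fast unit tests."""
    return SceneSpec(height=96, width=128, leaf_blob_count=40,
                     blob_size_range=(6, 18))


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """A small-but-structured dataset for harness-level tests."""
    return generate_dataset(n_per_class=12, spec=small_spec, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
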