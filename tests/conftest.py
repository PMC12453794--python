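import numpy as np
import pytest

import ggenet as gg


@pytest.fixture(scope="session")
def small_dataset():
    """360 synthetic 64x64 images (60 per class) at default difficulty."""
    spec = gg.SyntheticSpec(n_per_class=60, seed=11)
    images, labels = gg.generate_arrays(spec)
    return images, labels


@pytest.fixture()
def toy_spec():
    """Smallest buildable network that still has all three attention depths."""
    return gg.ModelSpec(base_width=2, attention_r=2, spatial_k=3, input_size=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
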