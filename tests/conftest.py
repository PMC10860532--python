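import numpy as np
import pytest

from decontrast3d.phantom import default_clinical_spec, generate_phantom
from decontrast3d.volume import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clinical_phantom():
    """One default six-organ phantom pair (64x64x32) with its labels."""
    spec = default_clinical_spec(seed=7)
    ncect, cect, labels = generate_phantom(spec)
    return spec, ncect, cect, labels


def random_volume(rng, shape=(8, 9, 7), spacing=(1.0, 1.0, 1.0), lo=-500, hi=500):
    return Volume(rng.uniform(lo, hi, size=shape), spacing)
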