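import numpy as np
import pytest

from spectra_metrics.phantom import PhantomSpec, TissueProfile


def two_class_profiles(noise_sigma=0.02):
    """Minimal pair of tissue profiles sharing the amide scaffold but
    differing in one discriminating band."""
    common = ((1650.0, 1.0, 16.0), (1540.0, 0.6, 13.0), (1240.0, 0.3, 18.0))
    a = TissueProfile("A", common + ((1562.0, 0.2, 7.0),), (0.04, 0.02), noise_sigma)
    b = TissueProfile("B", common + ((1518.0, 0.2, 7.0),), (0.04, 0.02), noise_sigma)
    return (a, b)


@pytest.fixture
def two_class_spec():
    return PhantomSpec(class_profiles=two_class_profiles(), image_shape=(10, 10),
                       seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
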