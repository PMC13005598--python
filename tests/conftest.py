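import numpy as np
import pytest

from endoipl import CylinderGeometry, OpticalProperties


@pytest.fixture
def soft_tissue():
    """Typical soft-tissue optical properties at red wavelengths."""
    return OpticalProperties.from_reduced(mu_a=0.1, mu_s_reduced=22.0, g=0.9)


@pytest.fixture
def lumen_half_cm():
    return CylinderGeometry(r_inner=0.5, r_outer=5.5, axial_halfwidth=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
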