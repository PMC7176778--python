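import numpy as np
import pytest

from radialfill import Sinogram, make_phantom, sinogram_from_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_sinogram(rng):
    """Small random real sinogram with uniform 360° angular sampling."""
    n_radial, n_views = 32, 12
    values = rng.random((n_radial, n_views))
    angles = np.arange(n_views) * (360.0 / n_views)
    return Sinogram(values=values, angles_deg=angles, coverage_deg=360.0,
                    delta_gamma_deg=360.0 / n_views)


@pytest.fixture(scope="session")
def features_phantom():
    return make_phantom("rotating_features")


@pytest.fixture(scope="session")
def disk_sinogram_small():
    """Disk phantom sinogram at modest size (fast column-symmetry checks)."""
    return sinogram_from_phantom(make_phantom("disk"), 24, 360.0, 65)
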