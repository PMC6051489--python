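import numpy as np
import pytest

from pvr import ImageVolume, make_phantom


@pytest.fixture(scope="session")
def phantom48():
    return make_phantom((48, 48, 48), seed=7)


@pytest.fixture(scope="session")
def phantom_slice(phantom48):
    """A feature-rich in-plane slice of the session phantom."""
    return phantom48.voxels[:, :, 24].copy()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_volume():
    """16^3 volume with smooth structure and non-trivial geometry."""
    rng = np.random.default_rng(5)
    from scipy.ndimage import gaussian_filter
    vox = gaussian_filter(rng.random((16, 16, 16)) * 100.0, sigma=1.5)
    return ImageVolume(vox, spacing=(1.25, 1.25, 2.5), origin=(-3.0, 2.0, 1.0))
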