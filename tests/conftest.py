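import numpy as np
import pytest

from geldepot import PhantomSpec, PKTruth, make_depot_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_sphere_spec():
    """Noiseless uniform spherical depot, r = 10 mm, 1 mm grid."""
    return PhantomSpec(
        background_sd_hu=0.0,
        noise_sd=0.0,
        depot_semi_axes=(10.0, 10.0, 10.0),
        iodine_falloff="uniform",
        seed=0,
    )


@pytest.fixture
def clean_sphere_volume(clean_sphere_spec):
    return make_depot_phantom(clean_sphere_spec)


@pytest.fixture
def noiseless_truth():
    return PKTruth(cv_noise=0.0, seed=0)


def digital_ball(radius_vox: int, pad: int = 3) -> np.ndarray:
    """Boolean ball of the given voxel radius (voxel-center rule)."""
    n = 2 * radius_vox + 2 * pad + 1
    c = (n - 1) / 2
    zz, yy, xx = np.mgrid[:n, :n, :n]
    return (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= radius_vox ** 2


def digital_disk(radius_px: int, pad: int = 3) -> np.ndarray:
    n = 2 * radius_px + 2 * pad + 1
    c = (n - 1) / 2
    yy, xx = np.mgrid[:n, :n]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius_px ** 2
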