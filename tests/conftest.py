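import numpy as np
import pytest

from xpct.phantom import PhantomSpec, generate_cochlea_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """64-cube cochlea phantom shared by forward/recon/segment tests."""
    spec = PhantomSpec(shape_vox=(64, 64, 64), voxel_m=2.0e-6, n_blobs=12,
                       blob_radius_mean_m=6.0e-6, blob_radius_sd_m=1.0e-6,
                       seed=7)
    return generate_cochlea_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
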