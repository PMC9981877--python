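"""Shared fixtures: one phantom/stack/reconstruction reused across tests.

Everything is generated at run time from fixed seeds; grids are kept at
256x256 (50 nm pixels, Nyquist-valid for NA 0.65 at 275 nm) so the full
suite stays fast.
"""

import numpy as np
import pytest

from uvqdpc.forward import acquire_stack
from uvqdpc.optics import AcquisitionConfig, make_annular_pupil
from uvqdpc.phantom import make_bead_field, make_lsec_phantom
from uvqdpc.reconstruct import reconstruct_stack


@pytest.fixture(scope="session")
def config():
    return AcquisitionConfig(image_shape=(256, 256), pixel_size_sample=50.0)


@pytest.fixture(scope="session")
def small_config():
    return AcquisitionConfig(image_shape=(64, 64), pixel_size_sample=60.0)


@pytest.fixture(scope="session")
def pupil(config):
    return make_annular_pupil(config)


@pytest.fixture(scope="session")
def small_pupil(small_config):
    return make_annular_pupil(small_config)


@pytest.fixture(scope="session")
def lsec_phantom():
    return make_lsec_phantom(seed=3)


@pytest.fixture(scope="session")
def lsec_stack(lsec_phantom, config):
    return acquire_stack(lsec_phantom, config)


@pytest.fixture(scope="session")
def lsec_recon(lsec_stack, lsec_phantom):
    """Moderate-regularization reconstruction with the known sample thickness."""
    return reconstruct_stack(
        lsec_stack,
        tau_abs=300.0,
        tau_ph=300.0,
        path_length_nm=lsec_phantom.meta["membrane_thickness_nm"],
    )


@pytest.fixture(scope="session")
def bead_field():
    return make_bead_field(shape=(256, 256), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
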