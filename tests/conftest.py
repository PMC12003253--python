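import numpy as np
import pytest
from hypothesis import settings

import petphantomqa as qa

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Coarse analysis resolution used throughout the suite; keeps simulation
#: and metric computations fast while preserving every qualitative property.
COARSE_VOXELS = (3.3, 3.3, 3.0)


@pytest.fixture(scope="session")
def geometry():
    return qa.default_nema_geometry()


@pytest.fixture(scope="session")
def coarse_labels(geometry):
    grid = qa.default_grid(geometry, COARSE_VOXELS)
    return qa.rasterize(geometry, grid)


@pytest.fixture(scope="session")
def calibrated_setup(coarse_labels):
    """SBR4-thin setup with sensitivity calibrated to 35e6 counts at 180 s."""
    setup = qa.AcquisitionSetup(sbr=4.0)
    sens = qa.calibrate_sensitivity(coarse_labels, setup)
    return setup.with_sensitivity(sens)


@pytest.fixture(scope="session")
def coarse_activity(coarse_labels, calibrated_setup):
    return qa.activity_map(coarse_labels, calibrated_setup)


@pytest.fixture(scope="session")
def reference_scan(coarse_labels, calibrated_setup, coarse_activity):
    """The SBR4-thin ground-truth surrogate (180 s, PSF 4 mm, sampled)."""
    return qa.simulate(
        coarse_activity,
        calibrated_setup,
        180.0,
        coarse_labels.grid,
        psf_fwhm_mm=4.0,
        seed=2024,
    )


@pytest.fixture(scope="session")
def background_vois(coarse_labels):
    return qa.place_background_vois(coarse_labels)


@pytest.fixture(scope="session")
def voi_set(reference_scan, coarse_labels):
    return qa.build_voi_set(reference_scan, coarse_labels)
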