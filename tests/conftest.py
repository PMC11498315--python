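"""Shared fixtures: one simulated lesion scene reused across test modules."""

import numpy as np
import pytest

from gsnr import SpeckleSpec, build_roi, make_psf_image, simulate_speckle
from gsnr.experiments import background_patch


@pytest.fixture(scope="session")
def default_spec():
    """Reference study conditions: r=2 mm lesion at -4 dB, 0.133 mm^2 cell."""
    return SpeckleSpec()


@pytest.fixture(scope="session")
def lesion_scene(default_spec):
    """(image, roi, psf) for one realization of the reference scene."""
    img, _ = simulate_speckle(default_spec)
    roi = build_roi(default_spec)
    psf = make_psf_image(default_spec)
    return img, roi, psf


@pytest.fixture(scope="session")
def speckle_patch(default_spec, lesion_scene):
    """Homogeneous background speckle rectangle from the reference scene."""
    img, _, _ = lesion_scene
    return background_patch(img, default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
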