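"""Shared fixtures: small synthetic scenes and helper constructors."""

import numpy as np
import pytest

import flimox as fx
from flimox.decay import _basis


@pytest.fixture(scope="session")
def small_scene():
    """A 64x64 scene with known truth, generated once per session."""
    spec = fx.SceneSpec(image_height=64, image_width=64, mito_count=8,
                        mito_radius_range=(2.0, 3.5), seed=11)
    image, truth = fx.generate_decay_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_scene_fit(small_scene):
    """The small scene fitted with the standard low-count settings."""
    spec, image, truth = small_scene
    fit = fx.fit_image(image, spatial_binning=3, channel_rebin=4)
    return spec, image, truth, fit


def noiseless_histogram(tau1, tau2, a1, n_photons, n_channels=256, window=12.5):
    """Exact expected channel counts of the truncated biexponential model."""
    edges = np.linspace(0.0, window, n_channels + 1)
    b1 = _basis(np.array([tau1]), edges)[0]
    b2 = _basis(np.array([tau2]), edges)[0]
    weights = a1 * b1 + (1.0 - a1) * b2
    return n_photons * weights / weights.sum()


@pytest.fixture
def truth_calib():
    return fx.CalibrationFit(K=15.0, tau_max=2.5)
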