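"""Shared fixtures: small synthetic optical configurations and PSFs.

The test configurations are deliberately small (5×5 views, 32.5-µm pitch)
so the full wave-optics chain runs in seconds; the design/acceptance checks
that concern the real instruments use the shipped inverted (63×/1.4, 13×13)
and upright (25×/1.05, 21×21) configurations.
"""

import numpy as np
import pytest

from cslfm import (ConfocalConfig, OpticalConfig, build_spatial_angular_psf,
                   compute_native_field, compute_sensor_psf, native_grid_spec,
                   realign_psf, inverted_config, airy_unit)


def _small(mag=20.0, scan_s=3, **kw):
    d = dict(na=0.8, mag_objective=mag, mag_relay=1.0, wavelength_nm=520.0,
             refr_index=1.0, mla_pitch_um=32.5, mla_focal_um=800.0,
             pixel_size_um=6.5, n_views=5, scan_s=scan_s)
    d.update(kw)
    return OpticalConfig(**d)


@pytest.fixture(scope="session")
def small_config():
    return _small()


@pytest.fixture(scope="session")
def small_depths():
    return np.arange(-3.0, 3.1, 1.0)


@pytest.fixture(scope="session")
def small_chain(small_config, small_depths):
    """(native field, sensor PSF, realigned PSF) for the small config."""
    grid = native_grid_spec(small_config, small_depths)
    fld = compute_native_field(small_config, small_depths, grid)
    hs = compute_sensor_psf(fld, small_config)
    hp = realign_psf(hs, small_config)
    return fld, hs, hp


@pytest.fixture(scope="session")
def small_psf(small_chain):
    return small_chain[2]


@pytest.fixture(scope="session")
def recon_config():
    # fine grid 32.5/(40*3) = 0.27 µm oversamples the 0.33-µm diffraction
    # FWHM, so reconstruction resolution is measurable on the grid
    return _small(mag=40.0)


@pytest.fixture(scope="session")
def recon_psf(recon_config):
    return build_spatial_angular_psf(recon_config, np.arange(-2.0, 2.1, 1.0))


@pytest.fixture(scope="session")
def extended_config():
    # unscanned lattice: energy bookkeeping over a deep background slab
    return _small(scan_s=1)


@pytest.fixture(scope="session")
def extended_psf(extended_config):
    return build_spatial_angular_psf(
        extended_config, np.arange(-40.0, 40.1, 2.0),
        oversample_grid=1.0, chunk_depths=8)


@pytest.fixture(scope="session")
def inverted_cfg():
    return inverted_config()


@pytest.fixture(scope="session")
def inverted_focus_psf(inverted_cfg):
    """63×/1.4 PSF around the focal plane (±2 µm, 0.5-µm steps)."""
    return build_spatial_angular_psf(
        inverted_cfg, np.arange(-2.0, 2.01, 0.5), n_lens=13)


@pytest.fixture(scope="session")
def inverted_dof_psf(inverted_cfg):
    """63×/1.4 PSF over the design DOF (±7.5 µm, 1.5-µm steps)."""
    return build_spatial_angular_psf(
        inverted_cfg, np.arange(-7.5, 7.51, 1.5))


@pytest.fixture(scope="session")
def slit_11au(inverted_cfg):
    return ConfocalConfig.from_au(inverted_cfg, 11.0)
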