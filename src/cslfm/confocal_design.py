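"""Line-confocal modulation model and confocality design calculators.

In csLFM an axially elongated line illumination (slit width ``w_s`` at the
conjugate image plane) is scanned in step with the camera rolling shutter
(active window height ``h_r``).  Integrating the product of the two sliding
rectangular windows over the sweep yields a static modulation of the
spatial-angular PSF: a triangle ``tri(ybar / w_s)`` when ``w_s = h_r`` (the
default conjugate design), a trapezoid otherwise.  This module implements
that model together with the design calculators used to choose the slit
size: Airy-unit conversion, per-view normalized energy maps (background
suppression), photon efficiency and axial coverage.

Both ``w_s`` and ``h_r`` are expressed in µm at the conjugate image plane
(the MLA plane); the MLA-to-camera relay is a fixed rescaling that the
effective-pixel convention of :mod:`cslfm.optics_core` already absorbs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .optics_core import OpticalConfig, SpatialAngularPSF

__all__ = [
    "ConfocalConfig",
    "EnergyMap",
    "tri_weight",
    "confocal_weight_general",
    "apply_confocal",
    "airy_unit",
    "normalized_energy_map",
    "photon_efficiency",
    "axial_coverage_profile",
    "design_report",
]


@dataclass(frozen=True)
class ConfocalConfig:
    """Confocal geometry: slit width and rolling-shutter height (conjugate
    image-plane µm) and the axial extent over which the elongated
    illumination is treated as uniform (object-space µm, default 15)."""

    slit_width_um: float
    shutter_height_um: float | None = None
    illum_axial_extent_um: float = 15.0

    def __post_init__(self):
        if self.slit_width_um <= 0:
            raise ValueError("slit_width_um must be positive")
        if self.shutter_height_um is None:
            object.__setattr__(self, "shutter_height_um", self.slit_width_um)
        if self.shutter_height_um <= 0:
            raise ValueError("shutter_height_um must be positive")

    @classmethod
    def from_au(cls, optical: OpticalConfig, slit_au: float,
                **kw) -> "ConfocalConfig":
        return cls(slit_width_um=slit_au * airy_unit(optical, "full"), **kw)

    def slit_au(self, optical: OpticalConfig) -> float:
        return self.slit_width_um / airy_unit(optical, "full")


def tri_weight(ybar_um, ws_um: float):
    """Triangle window ``tri(ybar/ws) = max(0, 1 - |ybar/ws|)``."""
    if ws_um <= 0:
        raise ValueError("ws_um must be positive")
    return np.maximum(0.0, 1.0 - np.abs(np.asarray(ybar_um, float) / ws_um))


def confocal_weight_general(ybar_um, ws_um: float, hr_um: float,
                            mag: float = 1.0):
    """Peak-normalized sweep integral of the two rectangular windows.

    The inner integral of the sweep model is the convolution of a
    rect of width ``ws`` (illumination slit, referred to the image plane)
    with a rect of width ``hr`` (shutter window): a trapezoid with plateau
    half-width ``|ws - hr|/2`` and base half-width ``(ws + hr)/2``, which
    degenerates to ``tri(ybar/ws)`` when ``ws == hr``.  ``mag`` is the
    magnification carried by the object-space substitution; it cancels under
    peak normalization but must be positive.
    """
    if ws_um <= 0 or hr_um <= 0 or mag <= 0:
        raise ValueError("ws_um, hr_um and mag must be positive")
    y = np.abs(np.asarray(ybar_um, float))
    if not (np.isfinite(ws_um) and np.isfinite(hr_um)):
        return np.ones_like(y)   # infinitely wide slit: no modulation
    base = (ws_um + hr_um) / 2.0
    return np.clip((base - y) / min(ws_um, hr_um), 0.0, 1.0)


def _modulation_weight(psf: SpatialAngularPSF, confocal: ConfocalConfig,
                       exact_offset: bool) -> np.ndarray:
    """Broadcastable weight over (v, u, ybar, xbar); uniform along xbar."""
    ybar = psf.spatial_coords_um()
    ws = confocal.slit_width_um
    hr = confocal.shutter_height_um
    if exact_offset:
        v_um = psf.view_offsets_um()          # sensor offset of view v, µm
        arg = ybar[None, :] + v_um[:, None]   # (v, ybar)
        w = confocal_weight_general(arg, ws, hr)
        return w[:, None, :, None]            # (v, u=1, ybar, xbar=1)
    w = confocal_weight_general(ybar, ws, hr)
    return w[None, None, :, None]


def apply_confocal(psf: SpatialAngularPSF, confocal: ConfocalConfig,
                   exact_offset: bool = False) -> SpatialAngularPSF:
    """Confocal modulation of the spatial-angular PSF:
    ``hp'(ybar, xbar, u, v, z) = hp * g_p``.

    Default mode neglects the view offset (``g_p = tri(ybar/w_s)``, valid for
    ``|v| << w_s``); ``exact_offset=True`` keeps it
    (``g_p = tri((ybar + v)/w_s)``).  Refuses already-modulated input.
    """
    if psf.modulated:
        raise ValueError("PSF is already confocal-modulated; double "
                         "modulation refused")
    w = _modulation_weight(psf, confocal, exact_offset)
    return psf.with_data(psf.data * w[None], ws_um=confocal.slit_width_um,
                         exact_offset=exact_offset)


def airy_unit(config: OpticalConfig, mode: str = "full",
              kappa: float = 1.0) -> float:
    """One Airy unit at the conjugate image plane, µm.

    ``mode="full"``: ``1.22 * lambda * M / NA`` of the whole objective.
    ``mode="sub"``: per-view NA after pupil segmentation by the MLA; one
    microlens pitch subtends ``kappa / n_views`` of the pupil diameter, so
    ``NA_sub = NA * kappa / n_views``.
    """
    au = 1.22 * config.wavelength_um * config.magnification / config.na
    if mode == "full":
        return au
    if mode == "sub":
        return au * config.n_views / kappa
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class EnergyMap:
    """Normalized per-view energy Ebar'[iz, v, u] = E'(p_z, u, w_s)/E_0(u),
    the background-suppression curve of the confocal modulation."""

    ebar: np.ndarray
    e0: np.ndarray
    z_um: np.ndarray
    ws_um: float

    def central_view(self) -> np.ndarray:
        c = self.ebar.shape[1] // 2
        return self.ebar[:, c, c]


def _truncation_check(psf: SpatialAngularPSF, tol: float = 0.01) -> None:
    """Warn when the stored support clips > tol of any plane's energy,
    estimated from the outer one-pitch border of the deepest plane."""
    s = psf.config.scan_s
    border = max(s, 1)
    for iz in (0, len(psf.z_um) - 1):
        plane = psf.data[iz].sum(axis=(0, 1))
        total = plane.sum()
        if total <= 0:
            continue
        inner = plane[border:-border, border:-border].sum()
        if (total - inner) / total > tol:
            warnings.warn(
                f"PSF support truncation: >{tol:.0%} of plane energy at "
                f"z={psf.z_um[iz]:g} µm sits in the outer border",
                stacklevel=3)
            return


def normalized_energy_map(psf_unmod: SpatialAngularPSF,
                          confocal: ConfocalConfig,
                          exact_offset: bool = False) -> EnergyMap:
    """Per-view energies of the modulated PSF normalized by the in-focus
    unmodulated energy: ``Ebar'(p_z, u, w_s) = E'(p_z, u, w_s) / E_0(u)``
    with all integrals over the stored (xbar, ybar) support."""
    if psf_unmod.modulated:
        raise ValueError("normalized_energy_map expects the unmodulated PSF")
    z = np.asarray(psf_unmod.z_um)
    iz0 = int(np.argmin(np.abs(z)))
    if abs(z[iz0]) > 1e-6:
        raise ValueError("depth list must contain the focal plane p_z = 0")
    _truncation_check(psf_unmod)
    e0 = psf_unmod.data[iz0].sum(axis=(2, 3))
    w = _modulation_weight(psf_unmod, confocal, exact_offset)
    emod = (psf_unmod.data * w[None]).sum(axis=(3, 4))
    return EnergyMap(ebar=emod / e0[None], e0=e0, z_um=z,
                     ws_um=confocal.slit_width_um)


def photon_efficiency(psf_unmod: SpatialAngularPSF,
                      psf_mod: SpatialAngularPSF | ConfocalConfig,
                      z_window_um=2.0) -> float:
    """Fraction of sLFM-collected energy retained by the confocal modulation
    for emitters uniformly distributed over the depth window.

    ``z_window_um`` is either a half-width (scalar ``w`` meaning ±w) or an
    explicit ``(lo, hi)`` range; depths of the PSF inside the window enter
    with equal weight (the "same fixed cell within the DOF" scenario).
    """
    if isinstance(psf_mod, ConfocalConfig):
        psf_mod = apply_confocal(psf_unmod, psf_mod)
    if not psf_mod.modulated:
        raise ValueError("psf_mod must be confocal-modulated")
    z = np.asarray(psf_unmod.z_um)
    if not np.allclose(z, psf_mod.z_um):
        raise ValueError("PSFs do not share a depth grid")
    if psf_unmod.data.shape != psf_mod.data.shape:
        raise ValueError("PSFs do not share a sampling grid")
    if np.isscalar(z_window_um):
        lo, hi = -float(z_window_um), float(z_window_um)
    else:
        lo, hi = map(float, z_window_um)
    if lo < z.min() - 1e-9 or hi > z.max() + 1e-9:
        raise ValueError(
            f"z_window [{lo}, {hi}] extends outside the PSF depth list "
            f"[{z.min()}, {z.max()}]")
    sel = (z >= lo - 1e-9) & (z <= hi + 1e-9)
    e_un = psf_unmod.data[sel].sum()
    e_mod = psf_mod.data[sel].sum()
    return float(e_mod / e_un)


def axial_coverage_profile(psf: SpatialAngularPSF,
                           threshold: float = 0.5) -> dict:
    """Per-depth total collected energy and its half-energy width.

    Returns ``z_um``, ``energy`` (normalized to the in-focus value) and
    ``halfenergy_width_um``: the depth range over which the energy stays at
    or above ``threshold`` times the in-focus value (linear-interpolated
    crossings; the operational depth-of-field definition used here).
    """
    z = np.asarray(psf.z_um, float)
    e = psf.data.sum(axis=(1, 2, 3, 4))
    iz0 = int(np.argmin(np.abs(z)))
    e_n = e / e[iz0]
    lo = hi = None
    for i in range(iz0, 0, -1):
        if e_n[i - 1] < threshold <= e_n[i]:
            lo = np.interp(threshold, [e_n[i - 1], e_n[i]], [z[i - 1], z[i]])
            break
    for i in range(iz0, len(z) - 1):
        if e_n[i + 1] < threshold <= e_n[i]:
            hi = np.interp(threshold, [e_n[i + 1], e_n[i]], [z[i + 1], z[i]])
            break
    if lo is None:
        lo = z[0]
    if hi is None:
        hi = z[-1]
    return {"z_um": z, "energy": e_n, "halfenergy_width_um": float(hi - lo),
            "threshold": threshold}


def design_report(optical: OpticalConfig,
                  confocal: ConfocalConfig,
                  psf_unmod: SpatialAngularPSF | None = None,
                  z_window_um=2.0,
                  exact_offset: bool = False) -> dict:
    """Structured confocality design report (JSON-serializable).

    Geometry entries are analytic; photon efficiency, axial coverage and the
    energy-decay map are filled in only when an unmodulated PSF is supplied.
    """
    au_full = airy_unit(optical, "full")
    report = {
        "au_full_um": au_full,
        "au_sub_um": airy_unit(optical, "sub"),
        "slit_um": confocal.slit_width_um,
        "slit_au": confocal.slit_width_um / au_full,
        "px_per_lens": int(round(optical.mla_pitch_um
                                 * optical.relay_mla_to_sensor
                                 / optical.pixel_size_um)),
        "n_views": optical.n_views,
        "magnification": optical.magnification,
        "optical_config": optical.to_dict(),
        "confocal_config": asdict(confocal),
        "photon_efficiency": None,
        "axial_halfenergy_um": None,
        "energy_map": None,
    }
    if psf_unmod is not None:
        psf_mod = apply_confocal(psf_unmod, confocal,
                                 exact_offset=exact_offset)
        report["photon_efficiency"] = photon_efficiency(
            psf_unmod, psf_mod, z_window_um)
        prof = axial_coverage_profile(psf_mod)
        report["axial_halfenergy_um"] = prof["halfenergy_width_um"]
        emap = normalized_energy_map(psf_unmod, confocal, exact_offset)
        report["energy_map"] = {
            "z_um": list(map(float, emap.z_um)),
            "ebar_central_view": list(map(float, emap.central_view())),
            "ws_um": emap.ws_um,
        }
    return report
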