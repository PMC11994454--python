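"""Wave-optics engine for scanning light-field microscopy (sLFM) PSFs.

The model follows the classic image-plane light-field geometry: an isotropic
point emitter is focused by an aplanatic high-NA objective, the scalar Debye
diffraction integral gives the complex field at the native image plane, a
microlens array (MLA) at that plane segments the pupil, and the camera one
microlens focal length behind records the spatial-angular intensity pattern.
Periodic sub-pitch drifting of the image plane (the "scan") restores
diffraction-limited spatial sampling; pixel realignment reindexes the scanned
frames into per-angle views on a fine spatial grid.

All sensor-plane coordinates are expressed in micrometres at the conjugate
(native) image plane where the MLA sits.  A relay between MLA and camera only
rescales the physical pixel pitch; it is folded into the effective pixel size
``mla_pitch / n_views`` so that each microlens covers exactly
``n_views × n_views`` pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import simpson
from scipy.special import j0

__all__ = [
    "OpticalConfig",
    "GridSpec",
    "NativeField",
    "SensorPSF",
    "SpatialAngularPSF",
    "native_grid_spec",
    "compute_native_field",
    "compute_sensor_psf",
    "realign_psf",
    "build_spatial_angular_psf",
    "inverted_config",
    "upright_config",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalConfig:
    """Instrument geometry: objective, relay, microlens array and camera.

    Parameters
    ----------
    na : objective numerical aperture.
    mag_objective, mag_relay : objective magnification and the relay between
        the objective image and the MLA plane; total magnification
        ``M = mag_objective * mag_relay``.
    wavelength_nm : emission wavelength in nm.
    refr_index : immersion refractive index (``na <= refr_index``).
    mla_pitch_um, mla_focal_um : microlens pitch and focal length, µm.
    pixel_size_um : physical camera pixel, µm.
    n_views : angular samples per axis; one microlens covers exactly
        ``n_views × n_views`` camera pixels (odd).
    scan_s : scan lattice side; the image plane drifts over ``s × s``
        sub-pitch positions per period (``s = 1`` is unscanned cLFM-style
        sampling).
    mag_relay_mla_to_sensor : relay between MLA and camera.  ``None`` derives
        it from the pixels-per-microlens constraint.
    """

    na: float
    mag_objective: float
    mag_relay: float
    wavelength_nm: float
    refr_index: float
    mla_pitch_um: float
    mla_focal_um: float
    pixel_size_um: float
    n_views: int
    scan_s: int = 3
    mag_relay_mla_to_sensor: float | None = None

    def __post_init__(self):
        if not self.na > 0:
            raise ValueError("na must be positive")
        if self.na > self.refr_index:
            raise ValueError(
                f"na={self.na} exceeds immersion index {self.refr_index}")
        if self.n_views % 2 != 1 or self.n_views < 1:
            raise ValueError("n_views must be a positive odd integer")
        if self.magnification <= 0:
            raise ValueError("total magnification must be positive")
        if self.scan_s < 1:
            raise ValueError("scan_s must be >= 1")
        if self.scan_s % 2 != 1:
            raise ValueError("scan_s must be odd (symmetric drift lattice)")
        relay = self.mag_relay_mla_to_sensor
        if relay is not None:
            ppl = self.mla_pitch_um * relay / self.pixel_size_um
            if round(ppl) != self.n_views:
                raise ValueError(
                    f"mla_pitch*relay/pixel = {ppl:.3f} px per microlens, "
                    f"inconsistent with n_views={self.n_views}")

    # -- derived quantities ------------------------------------------------
    @property
    def magnification(self) -> float:
        return self.mag_objective * self.mag_relay

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def relay_mla_to_sensor(self) -> float:
        if self.mag_relay_mla_to_sensor is not None:
            return self.mag_relay_mla_to_sensor
        return self.n_views * self.pixel_size_um / self.mla_pitch_um

    @property
    def pixel_mla_um(self) -> float:
        """Effective sensor pixel referred to the MLA plane (µm)."""
        return self.mla_pitch_um / self.n_views

    @property
    def sin_alpha(self) -> float:
        return self.na / self.refr_index

    @property
    def nyquist_step_um(self) -> float:
        """Native-image-plane step at 2x the diffraction Nyquist rate."""
        return self.wavelength_um * self.magnification / (4.0 * self.na)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        d = dict(d)
        scan = d.pop("scan", None)
        if scan is not None:
            d["scan_s"] = int(scan["s"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "OpticalConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml
        d = self.to_dict()
        d["scan"] = {"s": d.pop("scan_s")}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def inverted_config(scan_s: int = 3) -> OpticalConfig:
    """63x/1.4 oil inverted system: 100-µm MLA imaged at 0.845x onto 6.5-µm
    pixels, 13×13 views."""
    return OpticalConfig(
        na=1.4, mag_objective=63.0, mag_relay=1.0, wavelength_nm=525.0,
        refr_index=1.518, mla_pitch_um=100.0, mla_focal_um=2100.0,
        pixel_size_um=6.5, n_views=13, scan_s=scan_s,
        mag_relay_mla_to_sensor=0.845)


def upright_config(scan_s: int = 3) -> OpticalConfig:
    """25x/1.05 water upright system: 136.5-µm MLA, 1:1 relay, 21×21 views;
    an extra 1.64x relay gives total magnification 41x."""
    return OpticalConfig(
        na=1.05, mag_objective=25.0, mag_relay=1.64, wavelength_nm=525.0,
        refr_index=1.33, mla_pitch_um=136.5, mla_focal_um=2800.0,
        pixel_size_um=6.5, n_views=21, scan_s=scan_s,
        mag_relay_mla_to_sensor=1.0)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Native-image-plane sampling commensurate with the MLA and the scan
    lattice: ``samples_per_lens = scan_s * k`` samples per pitch (odd), over
    an odd number of microlenses."""

    step_um: float
    samples_per_lens: int
    n_lens: int

    @property
    def n_samples(self) -> int:
        return self.samples_per_lens * self.n_lens

    def coords(self) -> np.ndarray:
        n = self.n_samples
        return (np.arange(n) - (n - 1) / 2.0) * self.step_um


def native_grid_spec(config: OpticalConfig,
                     depths_um: Sequence[float],
                     n_lens: int | None = None,
                     oversample: float = 2.0) -> GridSpec:
    """Choose a grid step <= lambda*M/(4*NA*oversample) that divides the
    microlens pitch into ``scan_s * k`` (odd) samples, and a lens support
    wide enough to hold the defocus cone of the deepest requested plane.
    """
    target = config.nyquist_step_um / oversample
    s = config.scan_s
    k = max(1, int(np.ceil(config.mla_pitch_um / (s * target))))
    if (s * k) % 2 == 0:
        k += 1
    ppl = s * k
    step = config.mla_pitch_um / ppl
    if n_lens is None:
        sin_a = config.sin_alpha
        tan_a = sin_a / np.sqrt(1.0 - sin_a ** 2)
        zmax = max(abs(float(z)) for z in depths_um) if len(depths_um) else 0.0
        airy_obj = 0.61 * config.wavelength_um / config.na
        half_obj = zmax * tan_a + 10.0 * airy_obj
        half_img = half_obj * config.magnification
        n_lens = int(np.ceil(2.0 * half_img / config.mla_pitch_um))
        n_lens = max(n_lens, 5)
    if n_lens % 2 == 0:
        n_lens += 1
    return GridSpec(step_um=step, samples_per_lens=ppl, n_lens=n_lens)


# --------------------------------------------------------------------------
# native field (Debye integral)
# --------------------------------------------------------------------------

@dataclass
class NativeField:
    """Complex emitter field at the native image plane, one plane per depth.

    ``data[iz, y, x]`` on a square grid of step ``step_um`` (image-plane µm),
    for an emitter on the optical axis at object depth ``z_um[iz]``.
    """

    data: np.ndarray
    step_um: float
    z_um: np.ndarray
    config: OpticalConfig

    def coords(self) -> np.ndarray:
        n = self.data.shape[-1]
        return (np.arange(n) - (n - 1) / 2.0) * self.step_um

    def plane_energy(self) -> np.ndarray:
        return (np.abs(self.data) ** 2).sum(axis=(1, 2)) * self.step_um ** 2


def compute_native_field(config: OpticalConfig,
                         depths_um: Sequence[float],
                         grid: GridSpec | None = None,
                         n_theta: int = 257) -> NativeField:
    """Scalar Debye diffraction integral of an isotropic point emitter
    focused by an aplanatic objective (apodization sqrt(cos theta)),
    evaluated at the native image plane for each object defocus p_z.

    The lateral image coordinate is the magnified object coordinate; defocus
    enters through the ``exp(i k p_z cos theta)`` phase with
    ``k = 2 pi n / lambda`` in the immersion medium.  Aperture quadrature is
    Simpson's rule over ``n_theta`` nodes (odd, >= 257 by default).
    """
    if grid is None:
        grid = native_grid_spec(config, depths_um)
    if grid.step_um > config.nyquist_step_um * (1 + 1e-9):
        raise ValueError(
            f"grid step {grid.step_um:.3f} µm coarser than the Nyquist bound "
            f"{config.nyquist_step_um:.3f} µm = lambda*M/(4*NA)")
    if n_theta % 2 == 0:
        n_theta += 1

    depths = np.asarray(depths_um, dtype=float)
    alpha = np.arcsin(config.sin_alpha)
    theta = np.linspace(0.0, alpha, n_theta)
    k = 2.0 * np.pi * config.refr_index / config.wavelength_um
    apod = np.sqrt(np.cos(theta)) * np.sin(theta)

    xs = grid.coords()
    yy, xx = np.meshgrid(xs, xs, indexing="ij")
    r_img = np.hypot(yy, xx)
    r_obj = r_img / config.magnification
    rmax = float(r_obj.max())
    # radial lookup table, fine enough to resolve the fastest Bessel fringe
    nr = max(512, int(np.ceil(rmax / (grid.step_um / config.magnification)
                              * 4)) + 1)
    r_tab = np.linspace(0.0, rmax * (1 + 1e-12), nr)
    bess = j0(np.outer(k * np.sin(theta), r_tab))  # (ntheta, nr)

    data = np.empty((len(depths), len(xs), len(xs)), dtype=np.complex128)
    for iz, z in enumerate(depths):
        phase = np.exp(1j * k * z * np.cos(theta))
        integrand = (apod * phase)[:, None] * bess
        u_tab = simpson(integrand, x=theta, axis=0)
        u_plane = (np.interp(r_obj.ravel(), r_tab, u_tab.real)
                   + 1j * np.interp(r_obj.ravel(), r_tab, u_tab.imag))
        data[iz] = u_plane.reshape(r_obj.shape)
    return NativeField(data=data, step_um=grid.step_um, z_um=depths,
                       config=config)


# --------------------------------------------------------------------------
# sensor PSF
# --------------------------------------------------------------------------

def scan_offsets_um(config: OpticalConfig) -> np.ndarray:
    """Image-drift offsets of the scan lattice, symmetric about zero (µm)."""
    s = config.scan_s
    g = config.mla_pitch_um / s
    return (np.arange(s) - (s - 1) / 2.0) * g


@dataclass
class SensorPSF:
    """Pixel-integrated sensor intensity of a point emitter.

    ``data[iz, my, mx, row, col]``: sensor image for object depth
    ``z_um[iz]`` and scan phase ``(my, mx)`` — the emitter's image displaced
    by ``phase_offsets_um[my|mx]`` along y|x.  Rows/cols are effective sensor
    pixels at the MLA plane (``pixel_mla_um`` pitch, ``n_lens * n_views`` per
    axis).  Normalized so the in-focus pattern of one scan phase sums to 1.
    """

    data: np.ndarray
    z_um: np.ndarray
    phase_offsets_um: np.ndarray
    pixel_um: float
    n_lens: int
    config: OpticalConfig

    def pixel_coords(self) -> np.ndarray:
        n = self.data.shape[-1]
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_um


def _integer_shift2d(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift a 2-D array by whole samples with zero fill."""
    out = np.zeros_like(a)
    ny, nx = a.shape
    ys = slice(max(dy, 0), min(ny, ny + dy))
    yo = slice(max(-dy, 0), min(ny, ny - dy))
    xs = slice(max(dx, 0), min(nx, nx + dx))
    xo = slice(max(-dx, 0), min(nx, nx - dx))
    out[ys, xs] = a[yo, xo]
    return out


def compute_sensor_psf(field: NativeField,
                       config: OpticalConfig,
                       phases: np.ndarray | None = None,
                       oversample_px: int = 3,
                       normalize: bool = True) -> SensorPSF:
    """Microlens modulation and propagation to the camera.

    For every depth and scan phase the (shifted) native field is tiled into
    square microlens apertures; each aperture is Fourier-propagated one
    microlens focal length (the quadratic lens/Fresnel phases cancel in the
    focal-plane geometry and drop out of the squared modulus), sampled at
    ``oversample_px`` sub-samples per camera pixel and box-integrated over
    the pixel aperture.  Output normalized so the in-focus pattern of a
    single scan phase sums to 1.
    """
    ny = field.data.shape[-1]
    step = field.step_um
    ppl = int(round(config.mla_pitch_um / step))
    if abs(ppl * step - config.mla_pitch_um) > 1e-6 * config.mla_pitch_um:
        raise ValueError("field grid step is not commensurate with the "
                         "microlens pitch")
    if ny % ppl != 0:
        raise ValueError("field grid does not tile whole microlenses")
    n_lens = ny // ppl
    if n_lens < 3:
        raise ValueError("field must cover at least 3 microlens pitches")

    if phases is None:
        phases = scan_offsets_um(config)
    phases = np.asarray(phases, dtype=float)
    shifts = phases / step
    if np.max(np.abs(shifts - np.round(shifts))) > 1e-6:
        raise ValueError("scan-phase offsets are not commensurate with the "
                         "field sampling grid")
    shifts = np.round(shifts).astype(int)

    osf = int(oversample_px)
    if osf < 1 or osf % 2 == 0:
        raise ValueError("oversample_px must be a positive odd integer")
    nout = config.n_views * osf
    sub = config.pixel_mla_um / osf
    x_out = (np.arange(nout) - (nout - 1) / 2.0) * sub
    x_in = (np.arange(ppl) - (ppl - 1) / 2.0) * step
    kf = 2.0 * np.pi * config.refr_index / (config.wavelength_um
                                            * config.mla_focal_um)
    dft = np.exp(-1j * kf * np.outer(x_out, x_in)) * step

    s = len(phases)
    nz = len(field.z_um)
    npix = n_lens * config.n_views
    data = np.empty((nz, s, s, npix, npix), dtype=np.float64)
    for iz in range(nz):
        u0 = field.data[iz]
        for my in range(s):
            for mx in range(s):
                u = u0
                if shifts[my] or shifts[mx]:
                    u = _integer_shift2d(u0, shifts[my], shifts[mx])
                tiles = (u.reshape(n_lens, ppl, n_lens, ppl)
                          .transpose(0, 2, 1, 3))
                g = dft @ tiles @ dft.T          # (Ly, Lx, nout, nout)
                inten = (g.real ** 2 + g.imag ** 2)
                img = inten.transpose(0, 2, 1, 3).reshape(
                    n_lens * nout, n_lens * nout)
                px = img.reshape(npix, osf, npix, osf).sum(axis=(1, 3))
                data[iz, my, mx] = px * sub * sub

    if normalize:
        iz0 = int(np.argmin(np.abs(field.z_um)))
        norm = data[iz0].sum() / (s * s)
        if norm <= 0:
            raise ValueError("degenerate PSF: zero in-focus energy")
        data /= norm
    return SensorPSF(data=data, z_um=np.asarray(field.z_um, float),
                     phase_offsets_um=phases, pixel_um=config.pixel_mla_um,
                     n_lens=n_lens, config=config)


# --------------------------------------------------------------------------
# realignment into the spatial-angular domain
# --------------------------------------------------------------------------

@dataclass
class SpatialAngularPSF:
    """Spatial-angular PSF hp (or hp' once confocal-modulated).

    ``data[iz, v, u, ybar, xbar]``: view indices ``(v, u)`` run over the
    pixel offset within one microlens, centered at 0; ``(ybar, xbar)`` is
    the realigned fine spatial grid of step ``mla_pitch / scan_s`` at the
    MLA plane (object-referred step ``step_obj_um``).  ``ws_um`` is the slit
    width of the applied confocal modulation, ``None`` when unmodulated.
    """

    data: np.ndarray
    z_um: np.ndarray
    step_um: float
    config: OpticalConfig
    ws_um: float | None = None
    exact_offset: bool = False

    @property
    def n_views(self) -> int:
        return self.data.shape[1]

    @property
    def step_obj_um(self) -> float:
        return self.step_um / self.config.magnification

    @property
    def modulated(self) -> bool:
        return self.ws_um is not None

    def view_indices(self) -> np.ndarray:
        c = (self.n_views - 1) // 2
        return np.arange(self.n_views) - c

    def view_offsets_um(self) -> np.ndarray:
        """Pixel offset of each view from the microlens center (MLA-plane µm)."""
        return self.view_indices() * self.config.pixel_mla_um

    def spatial_coords_um(self) -> np.ndarray:
        n = self.data.shape[-1]
        return (np.arange(n) - (n - 1) / 2.0) * self.step_um

    def energy(self) -> float:
        return float(self.data.sum())

    def with_data(self, data, **kw) -> "SpatialAngularPSF":
        d = dict(z_um=self.z_um, step_um=self.step_um, config=self.config,
                 ws_um=self.ws_um, exact_offset=self.exact_offset)
        d.update(kw)
        return SpatialAngularPSF(data=data, **d)

    def provenance(self) -> str:
        tag = "unmodulated" if not self.modulated else (
            f"ws_um={self.ws_um:g}" + ("/exact" if self.exact_offset else ""))
        return (f"SpatialAngularPSF({tag}, n_views={self.n_views}, "
                f"nz={len(self.z_um)}, step_um={self.step_um:g})")


def realign_frames(frames: np.ndarray, n_views: int) -> np.ndarray:
    """Pixel-realignment permutation (the "dimension exchange").

    ``frames[..., my, mx, row, col]`` (one full scan lattice of sensor
    frames) is reindexed so the pixel offset within each microlens becomes
    the view index and the microlens center minus the image-drift offset
    becomes the fine spatial coordinate:
    output ``[..., v, u, ybar, xbar]`` with fine grid step ``pitch / s``.
    Pure permutation — no interpolation, energy conserved exactly.
    """
    *lead, s, s2, npix, npix2 = frames.shape
    if s != s2 or npix != npix2:
        raise ValueError("anisotropic scan lattice / sensor not supported")
    if npix % n_views:
        raise ValueError("sensor size is not a whole number of microlenses")
    nl = npix // n_views
    a = frames.reshape(*lead, s, s, nl, n_views, nl, n_views)
    nd = a.ndim
    # reverse phase axes: fine position within a lens is -offset, descending
    # in the phase index, so phase index my maps to sub-cell (s-1)-my
    a = np.flip(a, axis=(nd - 6, nd - 5))
    # [..., my', mx', iy, a, ix, b] -> [..., a, b, iy, my', ix, mx']
    perm = tuple(range(nd - 6)) + (nd - 3, nd - 1, nd - 4, nd - 6,
                                   nd - 2, nd - 5)
    a = a.transpose(perm)
    return np.ascontiguousarray(a.reshape(*lead, n_views, n_views,
                                          nl * s, nl * s))


def realign_psf(sensor_psf: SensorPSF,
                config: OpticalConfig) -> SpatialAngularPSF:
    """Reindex the scanned sensor PSF into spatial-angular views via
    :func:`realign_frames`; energy is conserved exactly."""
    data = sensor_psf.data
    nz, s = data.shape[0], data.shape[1]
    expected = scan_offsets_um(config)
    if (len(expected) != s or
            np.max(np.abs(np.asarray(sensor_psf.phase_offsets_um)
                          - expected)) > 1e-9):
        raise ValueError("sensor PSF does not cover the configured scan "
                         "lattice phases")
    hp = realign_frames(data, config.n_views)
    g = config.mla_pitch_um / s
    return SpatialAngularPSF(data=hp, z_um=sensor_psf.z_um, step_um=g,
                             config=config)


def build_spatial_angular_psf(config: OpticalConfig,
                              depths_um: Sequence[float],
                              n_lens: int | None = None,
                              oversample_px: int = 3,
                              n_theta: int = 257,
                              oversample_grid: float = 2.0,
                              chunk_depths: int | None = None
                              ) -> SpatialAngularPSF:
    """Convenience chain: Debye field -> sensor PSF -> realigned views.

    ``chunk_depths`` processes the depth list in batches to bound memory for
    coarse extended-z PSFs (e.g. background simulation over ±40 µm); the
    grid and the in-focus normalization are shared across batches.
    """
    depths = np.asarray(depths_um, dtype=float)
    grid = native_grid_spec(config, depths, n_lens=n_lens,
                            oversample=oversample_grid)
    if chunk_depths is None or chunk_depths >= len(depths):
        fld = compute_native_field(config, depths, grid, n_theta=n_theta)
        hs = compute_sensor_psf(fld, config, oversample_px=oversample_px)
        return realign_psf(hs, config)
    parts = []
    for lo in range(0, len(depths), chunk_depths):
        sub = depths[lo:lo + chunk_depths]
        fld = compute_native_field(config, sub, grid, n_theta=n_theta)
        hs = compute_sensor_psf(fld, config, oversample_px=oversample_px,
                                normalize=False)
        parts.append(realign_psf(hs, config))
    data = np.concatenate([p.data for p in parts], axis=0)
    iz0 = int(np.argmin(np.abs(depths)))
    s2 = config.scan_s ** 2
    norm = data[iz0].sum() / s2
    if norm <= 0:
        raise ValueError("degenerate PSF: zero in-focus energy")
    data /= norm
    return SpatialAngularPSF(data=data, z_um=depths,
                             step_um=config.mla_pitch_um / config.scan_s,
                             config=config)
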