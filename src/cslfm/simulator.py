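"""Phantom generation and forward simulation of sLFM / cLFM / csLFM.

Two forward routes are provided, mirroring the two levels of the acquisition
model:

* :func:`forward_views` — view-space model on the realigned fine grid: each
  angular view is the depth-sum of the object convolved with the
  corresponding spatial-angular PSF slice.  With a confocal-modulated PSF
  this is the csLFM model, with an unmodulated PSF the sLFM model.  Works on
  dense volumes.

* :func:`simulate_raw_scan` — raw sensor-level model: an explicit
  rolling-shutter sweep in which an illumination line excites a strip of the
  object while only a shutter window of rows is active, accumulated over the
  sweep for every scan phase.  This is the physical process the view-space
  triangle modulation is derived from, kept as an independent executable
  check of that derivation.  Operates on sparse emitter volumes (nonzero
  voxels on the fine lattice).

Phantoms emulate the bead-in-scattering-slab samples used for
characterization (sub-µm fluorescent beads in an intralipid/agarose slab),
dense neurite-like tangles, and uniform background slabs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .confocal_design import ConfocalConfig
from .optics_core import (OpticalConfig, SensorPSF, SpatialAngularPSF,
                          scan_offsets_um)

__all__ = [
    "PhantomSpec",
    "VolumeGrid",
    "RawScanSequence",
    "MultiViewStack",
    "generate_phantom",
    "forward_views",
    "simulate_raw_scan",
    "add_noise",
    "extract_clfm_frame",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """3-D intensity volume, photons/voxel.  ``data[z, y, x]`` with depth
    list ``z_um`` (object µm, 0 at the focal plane) and lateral voxel size
    ``voxel_xy_um``; the lateral grid is centered on the optical axis."""

    data: np.ndarray
    z_um: np.ndarray
    voxel_xy_um: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.z_um):
            raise ValueError("volume shape inconsistent with depth list")
        if np.any(self.data < 0):
            raise ValueError("volume intensity must be nonnegative")

    @property
    def voxel_z_um(self) -> float:
        if len(self.z_um) < 2:
            return 0.0
        return float(self.z_um[1] - self.z_um[0])

    def lateral_coords_um(self, axis: int = 1) -> np.ndarray:
        n = self.data.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_xy_um


@dataclass
class MultiViewStack:
    """Pixel-realigned angular views on the fine spatial grid.

    ``data[v, u, y, x]``, fine grid step ``step_um`` at the MLA plane
    (object-referred ``step_um / M``); ``mode`` records provenance."""

    data: np.ndarray
    step_um: float
    config: OpticalConfig
    mode: str = "slfm"
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("views must be indexed [v][u][y][x]")
        if np.any(self.data < 0):
            raise ValueError("views must be nonnegative")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    @property
    def step_obj_um(self) -> float:
        return self.step_um / self.config.magnification

    def central_view(self) -> np.ndarray:
        c = self.n_views // 2
        return self.data[c, c]


@dataclass
class RawScanSequence:
    """Rolling-shutter sensor frames, one per periodic scan position.

    ``data[my, mx, row, col]`` in photons; ``phase_offsets_um`` are the
    image-drift offsets of the scan lattice; ``mode`` is ``"slfm"``,
    ``"cslfm"`` or ``"clfm"`` (extracted single frame)."""

    data: np.ndarray
    phase_offsets_um: np.ndarray
    pixel_um: float
    config: OpticalConfig
    mode: str
    confocal: ConfocalConfig | None = None
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def frames(self) -> np.ndarray:
        """Frames flattened to [phase, row, col], phase = my * s + mx."""
        s1, s2, r, c = self.data.shape
        return self.data.reshape(s1 * s2, r, c)


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Synthetic sample description; ``seed`` fixes all randomness.

    ``kind``: ``beads`` (sub-µm spheres, Poisson count), ``slab_background``
    (uniform random emitters across a slab — the distributed-background
    proxy for intralipid scattering), ``neurites`` (smoothed random-walk
    tubes), or ``composite`` (beads + slab + offset)."""

    kind: str
    shape: tuple
    voxel_xy_um: float
    z_um: tuple
    bead_radius_um: float = 0.25
    bead_density_per_um3: float = 0.0
    bead_brightness: float = 1.0
    slab_thickness_um: float | None = None
    slab_emitter_density_per_um3: float = 0.0
    slab_brightness: float = 0.02
    n_neurites: int = 0
    neurite_radius_um: float = 0.4
    autofluorescence: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.voxel_xy_um <= 0:
            raise ValueError("voxel size must be positive")
        for d in (self.bead_density_per_um3,
                  self.slab_emitter_density_per_um3):
            if d < 0:
                raise ValueError("densities must be nonnegative")


def _splat_sphere(vol: np.ndarray, center_vox, radius_vox, amp,
                  subsamples: int = 3):
    """Rasterize a sphere with partial-voxel antialiasing (sub-voxel
    occupancy on a ``subsamples**3`` lattice)."""
    cz, cy, cx = center_vox
    r = radius_vox
    lo = [max(0, int(np.floor(c - r - 1))) for c in center_vox]
    hi = [min(n, int(np.ceil(c + r + 2)))
          for c, n in zip(center_vox, vol.shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    off = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    zz = np.arange(lo[0], hi[0])[:, None, None]
    yy = np.arange(lo[1], hi[1])[None, :, None]
    xx = np.arange(lo[2], hi[2])[None, None, :]
    frac = np.zeros((hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2]))
    for oz in off:
        for oy in off:
            for ox in off:
                d2 = ((zz + oz - cz) ** 2 + (yy + oy - cy) ** 2
                      + (xx + ox - cx) ** 2)
                frac += d2 <= r * r
    frac /= subsamples ** 3
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * frac


def generate_phantom(spec: PhantomSpec) -> VolumeGrid:
    """Render the phantom volume described by ``spec``; deterministic under
    ``spec.seed`` (same spec, identical volume)."""
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    z = np.asarray(spec.z_um, float)
    if len(z) != nz:
        raise ValueError("shape[0] must match the depth list length")
    dz = float(z[1] - z[0]) if nz > 1 else spec.voxel_xy_um
    vol = np.zeros(spec.shape, dtype=np.float64)
    dv = spec.voxel_xy_um
    vol_um3 = nz * dz * ny * dv * nx * dv

    if spec.kind in ("beads", "composite"):
        if spec.bead_radius_um < dv / 2:
            warnings.warn("bead radius below half a voxel; beads render as "
                          "single voxels", stacklevel=2)
        n_beads = rng.poisson(spec.bead_density_per_um3 * vol_um3)
        for _ in range(n_beads):
            cz = rng.uniform(0, nz)
            cy = rng.uniform(0, ny)
            cx = rng.uniform(0, nx)
            # isotropic radius in µm; anisotropic voxels handled by the
            # lateral rasterization radius (axial extent ~1 voxel for thin z)
            _splat_sphere(vol, (cz, cy, cx), spec.bead_radius_um / dv,
                          spec.bead_brightness)

    if spec.kind in ("slab_background", "composite"):
        thick = spec.slab_thickness_um
        if thick is None:
            thick = nz * dz
        zsel = np.abs(z - z.mean()) <= thick / 2
        n_emit = rng.poisson(spec.slab_emitter_density_per_um3
                             * thick * ny * nx * dv * dv)
        if n_emit and zsel.any():
            iz = rng.choice(np.where(zsel)[0], size=n_emit)
            iy = rng.integers(0, ny, size=n_emit)
            ix = rng.integers(0, nx, size=n_emit)
            np.add.at(vol, (iz, iy, ix), spec.slab_brightness)

    if spec.kind == "neurites":
        for _ in range(spec.n_neurites):
            npts = 4 * max(ny, nx)
            steps = rng.normal(0, 1.0, size=(npts, 3))
            path = np.cumsum(steps, axis=0)
            path = gaussian_filter(path, sigma=(8, 0))
            path -= path.mean(axis=0)
            path *= np.array([nz / 6, ny / 3, nx / 3]) / (
                np.abs(path).max(axis=0) + 1e-12)
            path += np.array([nz / 2, ny / 2, nx / 2])
            for p in path[::2]:
                _splat_sphere(vol, p, spec.neurite_radius_um / dv, 0.5,
                              subsamples=1)

    if spec.autofluorescence:
        vol += spec.autofluorescence
    return VolumeGrid(data=vol, z_um=z, voxel_xy_um=dv)


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def _match_depths(vol_z: np.ndarray, psf_z: np.ndarray) -> np.ndarray:
    idx = np.empty(len(vol_z), dtype=int)
    for i, z in enumerate(vol_z):
        j = int(np.argmin(np.abs(psf_z - z)))
        if abs(psf_z[j] - z) > 1e-6:
            raise ValueError(f"volume depth {z} µm not in the PSF depth list")
        idx[i] = j
    return idx


def forward_views(volume: VolumeGrid,
                  psf: SpatialAngularPSF) -> MultiViewStack:
    """Linear shift-invariant view-space model on the fine grid:
    each view is ``sum_z volume[z] * hp[z, v, u]`` (2-D convolution).
    A modulated PSF yields csLFM views, an unmodulated one sLFM views."""
    if abs(volume.voxel_xy_um - psf.step_obj_um) > 1e-6 * psf.step_obj_um:
        raise ValueError(
            f"volume lateral voxel {volume.voxel_xy_um:.4f} µm does not "
            f"match the PSF fine grid {psf.step_obj_um:.4f} µm")
    idx = _match_depths(volume.z_um, psf.z_um)
    nv = psf.n_views
    ny, nx = volume.data.shape[1:]
    out = np.zeros((nv, nv, ny, nx))
    for i, j in enumerate(idx):
        plane = volume.data[i]
        if not plane.any():
            continue
        for v in range(nv):
            for u in range(nv):
                out[v, u] += fftconvolve(plane, psf.data[j, v, u],
                                         mode="same")
    np.maximum(out, 0.0, out=out)
    mode = "cslfm" if psf.modulated else "slfm"
    return MultiViewStack(data=out, step_um=psf.step_um, config=psf.config,
                          mode=mode, meta={"psf": psf.provenance()})


def _shift2d_zero(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    from .optics_core import _integer_shift2d
    return _integer_shift2d(a, dy, dx)


def simulate_raw_scan(volume: VolumeGrid,
                      sensor_psf: SensorPSF,
                      optical: OpticalConfig,
                      confocal: ConfocalConfig | None = None,
                      mode: str = "cslfm",
                      sweep_steps: int | None = None) -> RawScanSequence:
    """Raw sensor frames with an explicit rolling-shutter sweep.

    For each scan phase, each of ``sweep_steps`` illumination-line positions
    excites the object rows within the slit strip (uniform over the
    illumination's axial extent) while only sensor rows inside the
    shutter window centered on the line's image position are active; the
    masked images are accumulated over the sweep (rectangle rule).  sLFM
    mode applies neither strip nor mask.  The volume must be sparse on the
    fine lattice (nonzero voxels are treated as point emitters).
    """
    if mode not in ("slfm", "cslfm"):
        raise ValueError("mode must be 'slfm' or 'cslfm'")
    if mode == "cslfm" and confocal is None:
        raise ValueError("cslfm mode needs a ConfocalConfig")
    s = optical.scan_s
    g = optical.mla_pitch_um / s
    fine_obj = g / optical.magnification
    if abs(volume.voxel_xy_um - fine_obj) > 1e-6 * fine_obj:
        raise ValueError("volume lateral voxel must equal the fine lattice "
                         f"pitch/(M*s) = {fine_obj:.4f} µm")
    zidx = _match_depths(volume.z_um, sensor_psf.z_um)
    offsets = scan_offsets_um(optical)
    if (len(sensor_psf.phase_offsets_um) != s or
            np.max(np.abs(sensor_psf.phase_offsets_um - offsets)) > 1e-9):
        raise ValueError("sensor PSF phases do not match the scan lattice")

    npix = sensor_psf.data.shape[-1]
    rows = sensor_psf.pixel_coords()
    nv = optical.n_views
    emitters = np.argwhere(volume.data > 0)
    amps = volume.data[tuple(emitters.T)]
    ny, nx = volume.data.shape[1:]
    if ny % 2 == 0 or nx % 2 == 0:
        raise ValueError("raw-scan volumes need odd lateral dimensions "
                         "(lattice centered on the optical axis)")
    cy, cx = (ny - 1) // 2, (nx - 1) // 2

    if mode == "cslfm":
        ws = confocal.slit_width_um
        hr = confocal.shutter_height_um
        span_lo = rows[0] - (ws + hr) / 2
        span_hi = rows[-1] + (ws + hr) / 2
        if sweep_steps is None:
            sweep_steps = int(np.ceil((span_hi - span_lo) / (hr / 32.0)))
        step_line = (span_hi - span_lo) / sweep_steps
        if step_line > hr / 4.0:
            warnings.warn(f"sweep step {step_line:.1f} µm exceeds h_r/4; "
                          "the shutter sweep is undersampled", stacklevel=2)
        y_line = span_lo + (np.arange(sweep_steps) + 0.5) * step_line
        z_extent = confocal.illum_axial_extent_um / 2.0

    data = np.zeros((s, s, npix, npix))
    for my in range(s):
        for mx in range(s):
            frame = data[my, mx]
            for (eiz, eiy, eix), amp in zip(emitters, amps):
                jz = zidx[eiz]
                if mode == "cslfm" and abs(volume.z_um[eiz]) > z_extent:
                    continue  # outside the elongated illumination sheet
                jy, jx = int(eiy - cy), int(eix - cx)  # fine-lattice steps
                # stored phase whose emitter image matches modulo one pitch
                mpy = (my + jy) % s
                mpx = (mx + jx) % s
                shift_y = (jy + my - mpy) // s * nv
                shift_x = (jx + mx - mpx) // s * nv
                pat = sensor_psf.data[jz, mpy, mpx]
                if shift_y or shift_x:
                    pat = _shift2d_zero(pat, shift_y, shift_x)
                if mode == "slfm":
                    frame += amp * pat
                    continue
                q_y = jy * g + offsets[my]   # emitter image row position
                strip = (np.abs(y_line - q_y) < ws / 2.0).astype(float)
                active = (np.abs(rows[None, :] - y_line[:, None])
                          < hr / 2.0).astype(float)
                w_rows = (step_line / ws) * (strip @ active)
                frame += amp * (w_rows[:, None] * pat)

    meta = {"sweep_steps": None if mode == "slfm" else sweep_steps}
    return RawScanSequence(data=data, phase_offsets_um=offsets,
                           pixel_um=sensor_psf.pixel_um, config=optical,
                           mode=mode, confocal=confocal, meta=meta)


def add_noise(measurement: np.ndarray, photon_scale: float = 1.0,
              read_noise_e: float = 1.6, seed: int | None = None
              ) -> np.ndarray:
    """Poisson photon noise at ``photon_scale`` photons per intensity unit
    plus Gaussian read noise (e-, camera gain 1 e-/count); seeded and
    returned on the input intensity scale."""
    x = np.asarray(measurement, dtype=float)
    if np.any(x < 0):
        raise ValueError("measurement must be nonnegative")
    if photon_scale <= 0:
        raise ValueError("photon_scale must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(x * photon_scale).astype(float)
    counts += rng.normal(0.0, read_noise_e, size=x.shape)
    return counts / photon_scale


def extract_clfm_frame(seq: RawScanSequence, phase_index: int
                       ) -> RawScanSequence:
    """Single light-field frame at one scan position, for cLFM processing.

    ``phase_index`` flattens the lattice as ``my * s + mx``.  The returned
    sequence is marked unscanned (``s = 1``); the sub-pitch drift offset of
    the chosen phase is recorded in the metadata (it is below the coarse
    pitch sampling of an unscanned frame).
    """
    s = seq.data.shape[0]
    if not (0 <= phase_index < s * s):
        raise ValueError(f"phase_index {phase_index} out of range "
                         f"[0, {s * s})")
    my, mx = divmod(phase_index, s)
    frame = seq.data[my, mx].copy()
    meta = dict(seq.meta)
    meta.update({"source_phase": (my, mx),
                 "source_offsets_um": (float(seq.phase_offsets_um[my]),
                                       float(seq.phase_offsets_um[mx])),
                 "unscanned": True})
    return RawScanSequence(data=frame[None, None], mode="clfm",
                           phase_offsets_um=np.zeros(1),
                           pixel_um=seq.pixel_um, config=seq.config,
                           confocal=seq.confocal, meta=meta)
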