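"""Reconstruction: pixel realignment, cLFM upsampling, multi-view iterative
tomography (Richardson–Lucy-type) and simplified digital adaptive optics.

The reconstruction solves the phase-space imaging model
``views[v,u] = sum_z volume[z] * hp[z,v,u]`` by multiplicative updates

    volume <- volume * backproject(measured / forward) / backproject(1)

summed over views, which preserves nonnegativity and monotonically decreases
the Poisson data fidelity.  Digital adaptive optics (DAO) is simplified to
per-view rigid disparities estimated by subpixel phase correlation against
the central view and applied by shifting the PSF kernels, keeping the
forward model consistent.  The full wavefront (Zernike) estimation of the
original sLFM framework is an extension point, not re-derived here.

The reconstruction path is fully deterministic given its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .optics_core import OpticalConfig, SpatialAngularPSF, realign_frames, \
    scan_offsets_um
from .simulator import MultiViewStack, RawScanSequence, VolumeGrid

__all__ = [
    "ShiftMap",
    "ReconResult",
    "pixel_realign",
    "clfm_upsample",
    "dao_estimate",
    "iterative_tomography",
    "reconstruct_pipeline",
]


@dataclass
class ShiftMap:
    """Per-view lateral disparity relative to the central (reference) view,
    object-space µm; ``dy_um[v, u]``/``dx_um[v, u]`` with the reference
    entry identically zero."""

    dy_um: np.ndarray
    dx_um: np.ndarray
    reference: tuple
    max_shift_um: float = 2.0

    def __post_init__(self):
        r = self.reference
        if abs(self.dy_um[r]) > 1e-12 or abs(self.dx_um[r]) > 1e-12:
            raise ValueError("reference-view shift must be zero")

    def magnitude_um(self) -> np.ndarray:
        return np.hypot(self.dy_um, self.dx_um)


@dataclass
class ReconResult:
    """Volume estimate plus the run's bookkeeping."""

    volume: VolumeGrid
    n_iter: int
    fidelity: list
    shifts: ShiftMap | None
    psf_provenance: str
    log: dict = dc_field(default_factory=dict)


# --------------------------------------------------------------------------
# realignment / upsampling
# --------------------------------------------------------------------------

def pixel_realign(seq: RawScanSequence,
                  optical: OpticalConfig) -> MultiViewStack:
    """Realign a raw scan sequence into angular views on the fine grid —
    the same lossless permutation applied to the PSF."""
    s = seq.data.shape[0]
    if seq.mode == "clfm" or s == 1:
        if s != 1:
            raise ValueError("clfm sequences must hold a single phase")
        expected = np.zeros(1)
    else:
        if s != optical.scan_s:
            raise ValueError("sequence scan lattice does not match config")
        expected = scan_offsets_um(optical)
    if np.max(np.abs(np.asarray(seq.phase_offsets_um) - expected)) > 1e-9:
        raise ValueError("incomplete or mismatched scan lattice")
    views = realign_frames(seq.data, optical.n_views)
    step = optical.mla_pitch_um / s
    return MultiViewStack(data=views, step_um=step, config=optical,
                          mode=seq.mode, meta=dict(seq.meta))


def clfm_upsample(views: MultiViewStack, factor: int) -> MultiViewStack:
    """Cubic interpolation of unscanned (single-phase) views onto the fine
    grid of an ``s``-scanned stack, matching its sampling exactly."""
    if factor < 1:
        raise ValueError("upsampling factor must be >= 1")
    if views.mode not in ("clfm",) and not views.meta.get("unscanned"):
        raise ValueError("clfm_upsample expects views from an unscanned "
                         "(single-phase) frame")
    if factor == 1:
        return views
    nv, _, ny, nx = views.data.shape
    nyf, nxf = ny * factor, nx * factor
    # coarse grid: x = (i - (n-1)/2) * pitch; fine: (j - (N-1)/2) * pitch/s
    jy = (np.arange(nyf) - (nyf - 1) / 2.0) / factor + (ny - 1) / 2.0
    jx = (np.arange(nxf) - (nxf - 1) / 2.0) / factor + (nx - 1) / 2.0
    cy, cx = np.meshgrid(jy, jx, indexing="ij")
    out = np.empty((nv, nv, nyf, nxf))
    for v in range(nv):
        for u in range(nv):
            out[v, u] = ndimage.map_coordinates(
                views.data[v, u], [cy, cx], order=3, mode="nearest")
    np.maximum(out, 0.0, out=out)
    meta = dict(views.meta)
    meta["upsampled"] = factor
    return MultiViewStack(data=out, step_um=views.step_um / factor,
                          config=views.config, mode=views.mode, meta=meta)


# --------------------------------------------------------------------------
# digital adaptive optics (simplified: per-view rigid disparity)
# --------------------------------------------------------------------------

def _psf_parallax_um(psf: SpatialAngularPSF) -> tuple:
    """Intrinsic in-focus centroid disparity of each view relative to the
    central view (object µm); ~0 for a symmetric in-focus PSF."""
    z0 = int(np.argmin(np.abs(psf.z_um)))
    nv = psf.n_views
    coords = psf.spatial_coords_um() / psf.config.magnification
    cy = np.empty((nv, nv))
    cx = np.empty((nv, nv))
    for v in range(nv):
        for u in range(nv):
            k = psf.data[z0, v, u]
            tot = k.sum()
            cy[v, u] = (k.sum(axis=1) @ coords) / tot
            cx[v, u] = (k.sum(axis=0) @ coords) / tot
    c = nv // 2
    return cy - cy[c, c], cx - cx[c, c]


def dao_estimate(views: MultiViewStack,
                 psf: SpatialAngularPSF | None = None,
                 upsample: int = 20,
                 max_shift_um: float = 2.0,
                 var_threshold: float = 1e-12) -> ShiftMap:
    """Estimate per-view disparities by subpixel phase correlation of each
    view against the central view, compensating the PSF's intrinsic
    in-focus parallax when a PSF is supplied.

    Sign convention: the returned shift is the displacement of the view's
    content relative to the central view, i.e. ``view ≈ central shifted by
    (+dy, +dx)``.  Featureless views (variance below threshold) get zero
    shift with a warning.
    """
    nv = views.n_views
    if nv < 3:
        raise ValueError("need >= 3 views per axis for disparity estimation")
    c = nv // 2
    ref = views.data[c, c]
    step = views.step_obj_um
    dy = np.zeros((nv, nv))
    dx = np.zeros((nv, nv))
    if ref.var() < var_threshold:
        warnings.warn("featureless central view; returning zero shifts",
                      stacklevel=2)
        return ShiftMap(dy, dx, (c, c), max_shift_um)
    nonzero = 0
    for v in range(nv):
        for u in range(nv):
            if (v, u) == (c, c):
                continue
            mov = views.data[v, u]
            if mov.var() < var_threshold:
                continue
            nonzero += 1
            shift, _, _ = phase_cross_correlation(
                ref, mov, upsample_factor=upsample, normalization=None)
            # pcc returns the offset of `mov` relative to `ref` negated
            dy[v, u] = -shift[0] * step
            dx[v, u] = -shift[1] * step
    if nonzero < 4:
        warnings.warn("fewer than 5 views with content; DAO estimate is "
                      "unreliable", stacklevel=2)
    if psf is not None:
        py, px = _psf_parallax_um(psf)
        dy -= py
        dx -= px
        dy[c, c] = dx[c, c] = 0.0
    mag = np.hypot(dy, dx)
    if np.any(mag > max_shift_um):
        warnings.warn("DAO shifts clipped to the configured maximum",
                      stacklevel=2)
        scale = np.minimum(1.0, max_shift_um / np.maximum(mag, 1e-30))
        dy *= scale
        dx *= scale
    return ShiftMap(dy, dx, (c, c), max_shift_um)


# --------------------------------------------------------------------------
# iterative tomography
# --------------------------------------------------------------------------

class _FFTProjector:
    """Precomputed FFT kernels for the multi-view forward/backward model
    (linear convolution via zero padding, cropped to 'same')."""

    def __init__(self, kernels: np.ndarray, img_shape: tuple):
        nz, nv, nu, ky, kx = kernels.shape
        ny, nx = img_shape
        self.shape = (ny + ky - 1, nx + kx - 1)
        self.crop = (slice((ky - 1) // 2, (ky - 1) // 2 + ny),
                     slice((kx - 1) // 2, (kx - 1) // 2 + nx))
        self.kf = np.fft.rfft2(kernels, self.shape)
        self.ksum = kernels.sum(axis=(3, 4))
        self.nz, self.nv, self.nu = nz, nv, nu
        self.img_shape = img_shape

    def forward(self, volume: np.ndarray) -> np.ndarray:
        vf = np.fft.rfft2(volume, self.shape)          # (nz, Fy, Fx)
        acc = np.einsum("zab,zvuab->vuab", vf, self.kf)
        out = np.fft.irfft2(acc, self.shape)
        return np.maximum(out[(slice(None), slice(None)) + self.crop], 0.0)

    def backward(self, ratio: np.ndarray) -> np.ndarray:
        # adjoint of forward: correlation, cyclic indices rolled so the
        # outputs n = -(k-1)//2 ... line up with the 'same' crop
        rf = np.fft.rfft2(ratio, self.shape)           # (nv, nu, Fy, Fx)
        acc = np.einsum("vuab,zvuab->zab", rf, np.conj(self.kf))
        out = np.fft.irfft2(acc, self.shape)
        ny, nx = self.img_shape
        ky = self.shape[0] - ny + 1
        kx = self.shape[1] - nx + 1
        out = np.roll(out, ((ky - 1) // 2, (kx - 1) // 2), axis=(1, 2))
        return out[:, :ny, :nx]


def _shift_kernels(psf: SpatialAngularPSF, shifts: ShiftMap) -> np.ndarray:
    """Shift each view's PSF kernels by the estimated disparity (linear
    interpolation, clipped nonnegative)."""
    step = psf.step_obj_um
    out = np.empty_like(psf.data)
    for v in range(psf.n_views):
        for u in range(psf.n_views):
            sy = shifts.dy_um[v, u] / step
            sx = shifts.dx_um[v, u] / step
            if abs(sy) < 1e-9 and abs(sx) < 1e-9:
                out[:, v, u] = psf.data[:, v, u]
                continue
            for iz in range(len(psf.z_um)):
                out[iz, v, u] = ndimage.shift(
                    psf.data[iz, v, u], (-sy, -sx), order=1, mode="constant")
    np.maximum(out, 0.0, out=out)
    return out


def iterative_tomography(views: MultiViewStack,
                         psf: SpatialAngularPSF,
                         n_iter: int = 30,
                         shifts: ShiftMap | None = None,
                         init: str = "uniform",
                         eps_rel: float = 1e-9) -> ReconResult:
    """Multi-view multiplicative (Richardson–Lucy-type) deconvolution.

    ``volume <- volume * [sum_views backproject(measured / forward)] /
    [sum_views backproject(1)]`` with an optional per-view shift correction
    applied to the PSF kernels.  Returns the nonnegative volume and the
    per-iteration Poisson data-fidelity log.

    Reconstructing confocal (csLFM) data with an unmodulated PSF is
    permitted but flagged: the mismatch produces artifacts at the
    out-of-focus planes.
    """
    if views.n_views != psf.n_views:
        raise ValueError("view count mismatch between measurement and PSF")
    if abs(views.step_um - psf.step_um) > 1e-6 * psf.step_um:
        raise ValueError("fine-grid step mismatch between views and PSF")
    if views.mode == "cslfm" and not psf.modulated:
        warnings.warn("reconstructing csLFM data with an unmodulated PSF; "
                      "expect artifacts at the out-of-focus planes",
                      stacklevel=2)
    kernels = psf.data if shifts is None else _shift_kernels(psf, shifts)
    meas = views.data
    proj = _FFTProjector(kernels, meas.shape[2:])
    eps = eps_rel * float(meas.max() if meas.size else 1.0)
    if eps <= 0:
        eps = eps_rel

    norm = proj.backward(np.ones_like(meas))
    np.maximum(norm, eps, out=norm)
    nz = len(psf.z_um)
    if init == "uniform":
        mean_per_z = float(meas.sum()) / max(
            meas.shape[0] * meas.shape[1], 1) / meas.shape[2] / \
            meas.shape[3] / nz
        vol = np.full((nz,) + meas.shape[2:], max(mean_per_z, eps))
    elif init == "backproject":
        vol = proj.backward(meas) / norm
        np.maximum(vol, eps, out=vol)
    else:
        raise ValueError("init must be 'uniform' or 'backproject'")

    fidelity = []
    for _ in range(int(n_iter)):
        fwd = proj.forward(vol)
        fidelity.append(float((fwd - meas * np.log(fwd + eps)).sum()))
        ratio = meas / (fwd + eps)
        vol = vol * (proj.backward(ratio) / norm)
        np.maximum(vol, 0.0, out=vol)

    volume = VolumeGrid(data=vol, z_um=psf.z_um,
                        voxel_xy_um=psf.step_obj_um)
    return ReconResult(volume=volume, n_iter=int(n_iter), fidelity=fidelity,
                       shifts=shifts, psf_provenance=psf.provenance(),
                       log={"mode": views.mode, "eps": eps, "init": init})


def reconstruct_pipeline(data,
                         psf: SpatialAngularPSF,
                         optical: OpticalConfig | None = None,
                         dao: bool = False,
                         n_iter: int = 30,
                         init: str = "uniform") -> ReconResult:
    """Realign (raw sequences), optionally upsample cLFM frames and estimate
    DAO disparities, then run iterative tomography; every resolved parameter
    is logged on the result."""
    optical = optical or psf.config
    if isinstance(data, RawScanSequence):
        views = pixel_realign(data, optical)
        if views.mode == "clfm":
            views = clfm_upsample(views, optical.scan_s)
    elif isinstance(data, MultiViewStack):
        views = data
    else:
        raise TypeError("data must be a RawScanSequence or MultiViewStack")
    shifts = dao_estimate(views, psf) if dao else None
    result = iterative_tomography(views, psf, n_iter=n_iter, shifts=shifts,
                                  init=init)
    result.log.update({
        "pipeline": True,
        "dao": dao,
        "n_iter": n_iter,
        "psf": psf.provenance(),
        "ws_um": psf.ws_um,
        "mode": views.mode,
    })
    return result
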