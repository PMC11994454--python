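"""Quantitative evaluation: image metrics (SBR, SNR, 3-D SSIM, FWHM, FRC),
cluster separability (Calinski–Harabasz score, class distances) and
functional-trace analysis (ΔF/F₀, spike detection for calcium and voltage
indicators, visual-response ratio and orientation selectivity).

Conventions used throughout: SBR is the 10-fold log ratio of the signal
maximum to the background mean; ΔF/F₀ normalizes to the ROI's time-mean
baseline; spikes are strict local maxima above a modality threshold (40 %
for calcium, 2 % for voltage after subtracting a 130-ms running median);
OSI = (R_pref − R_orth)/(R_pref + R_orth) from 8-direction responses with
R > 3 defining visual responsiveness.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.metrics import structural_similarity

__all__ = [
    "TraceSet",
    "TuningResult",
    "sbr",
    "snr",
    "ssim3d",
    "fwhm",
    "frc_curve",
    "frc_resolution",
    "checkerboard_split",
    "ch_score",
    "class_distances",
    "dff",
    "detect_spikes",
    "tuning_analysis",
]

CALCIUM_SPIKE_THRESHOLD = 0.40   # ΔF/F0 local-peak threshold, calcium
VOLTAGE_SPIKE_THRESHOLD = 0.02   # ΔF/F0 threshold after median subtraction
VOLTAGE_MEDIAN_WINDOW_S = 0.130  # running-median window, voltage traces
RESPONSE_RATIO_THRESHOLD = 3.0   # R > 3 defines a visually responsive ROI
HIGH_OSI_THRESHOLD = 0.8
FRC_THRESHOLD = 1.0 / 7.0


# --------------------------------------------------------------------------
# image metrics
# --------------------------------------------------------------------------

def sbr(image: np.ndarray, signal_mask: np.ndarray,
        background_mask: np.ndarray) -> float:
    """Signal-to-background ratio, dB:
    ``10 log10(max(area_S) / mean(area_B))``."""
    image = np.asarray(image, float)
    sm = np.asarray(signal_mask, bool)
    bm = np.asarray(background_mask, bool)
    if not sm.any() or not bm.any():
        raise ValueError("signal and background masks must be nonempty")
    if np.any(sm & bm):
        raise ValueError("signal and background masks must be disjoint")
    bg = image[bm].mean()
    if bg <= 0:
        raise ValueError("background mean must be positive")
    return float(10.0 * np.log10(image[sm].max() / bg))


def snr(reference: np.ndarray, estimate: np.ndarray) -> float:
    """``10 log10(||X||² / ||X − Y||²)``; +inf sentinel for an exact match."""
    x = np.asarray(reference, float)
    y = np.asarray(estimate, float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    num = float((x ** 2).sum())
    if num == 0:
        raise ValueError("all-zero reference")
    den = float(((x - y) ** 2).sum())
    if den == 0:
        return float("inf")
    return float(10.0 * np.log10(num / den))


def ssim3d(reference: np.ndarray, estimate: np.ndarray,
           sigma: float = 1.5) -> float:
    """Mean structural similarity with 3-D local Gaussian windows
    (σ = 1.5 voxels, constants (0.01·L)² and (0.03·L)²).

    Both volumes are normalized by their own maxima first, so ``L = 1`` (the
    maximum of the normalized reference) and a global rescaling of either
    input does not change the score.
    """
    x = np.asarray(reference, float)
    y = np.asarray(estimate, float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if x.max() <= 0:
        raise ValueError("all-zero reference")
    x = x / x.max()
    y = y / y.max() if y.max() > 0 else y
    return float(structural_similarity(
        x, y, data_range=1.0, gaussian_weights=True, sigma=sigma,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def _gauss(x, a, mu, sig, off):
    return a * np.exp(-0.5 * ((x - mu) / sig) ** 2) + off


def fwhm(profile: np.ndarray, step_um: float = 1.0,
         mode: str = "interp") -> float:
    """Full width at half maximum of a 1-D intensity profile, µm.

    ``mode="interp"``: linear-interpolated half-maximum crossings around the
    peak.  ``mode="gaussian"``: least-squares Gaussian fit (the convention
    used for sizing near-diffraction-limit structures), width
    ``2 sqrt(2 ln 2) σ``.
    """
    p = np.asarray(profile, float)
    if p.ndim != 1 or len(p) < 5:
        raise ValueError("profile must be 1-D with >= 5 samples")
    x = np.arange(len(p)) * float(step_um)
    if mode == "gaussian":
        i0 = int(np.argmax(p))
        p0 = [p.max() - p.min(), x[i0], max(step_um, x[-1] / 10), p.min()]
        popt, _ = curve_fit(_gauss, x, p, p0=p0, maxfev=10000)
        return float(2.0 * np.sqrt(2.0 * np.log(2.0)) * abs(popt[2]))
    i0 = int(np.argmax(p))
    half = p[i0] / 2.0
    left = right = None
    for i in range(i0, 0, -1):
        if p[i - 1] <= half <= p[i]:
            left = np.interp(half, [p[i - 1], p[i]], [x[i - 1], x[i]])
            break
    for i in range(i0, len(p) - 1):
        if p[i + 1] <= half <= p[i]:
            right = np.interp(half, [p[i + 1], p[i]], [x[i + 1], x[i]])
            break
    if left is None or right is None:
        raise ValueError("no half-maximum crossing within the support")
    return float(right - left)


def checkerboard_split(image: np.ndarray) -> tuple:
    """Split one image into two half-images with independent noise by
    checkerboard subsampling (even/odd pixel parity), each filled onto the
    full grid by averaging with nearest neighbors of its own parity."""
    img = np.asarray(image, float)
    yy, xx = np.indices(img.shape)
    par = (yy + xx) % 2
    a = img.copy()
    b = img.copy()
    # replace the other parity by the 4-neighbor mean of the kept parity
    k = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
    neigh = ndimage.convolve(img, k / 4.0, mode="nearest")
    a[par == 1] = neigh[par == 1]
    b[par == 0] = neigh[par == 0]
    return a, b


def frc_curve(image_a: np.ndarray, image_b: np.ndarray) -> tuple:
    """Fourier ring correlation between two equal-shape half-images; returns
    (spatial frequencies in cycles/pixel, FRC values per ring)."""
    a = np.asarray(image_a, float)
    b = np.asarray(image_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("need two equal-shape 2-D images")
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    ny, nx = a.shape
    yy, xx = np.indices(a.shape)
    ry = (yy - ny // 2) / ny
    rx = (xx - nx // 2) / nx
    r = np.hypot(ry, rx)
    nbins = min(ny, nx) // 2
    edges = np.linspace(0, 0.5, nbins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, nbins - 1)
    num = np.bincount(idx.ravel(), (fa * np.conj(fb)).real.ravel(), nbins)
    da = np.bincount(idx.ravel(), np.abs(fa).ravel() ** 2, nbins)
    db = np.bincount(idx.ravel(), np.abs(fb).ravel() ** 2, nbins)
    denom = np.sqrt(da * db)
    frc = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    freqs = 0.5 * (edges[:-1] + edges[1:])
    return freqs, frc


def frc_resolution(image_a: np.ndarray, image_b: np.ndarray,
                   pixel_size_um: float,
                   threshold: float = FRC_THRESHOLD) -> float:
    """Resolution (µm) at the fixed-threshold crossing (default 1/7) of the
    FRC curve.  Identical inputs never cross; the sampling limit
    (2 × pixel) is returned in that case."""
    freqs, frc = frc_curve(image_a, image_b)
    if frc[0] < threshold:
        raise ValueError("FRC below threshold at the lowest ring; inputs "
                         "share no correlated signal")
    below = np.where(frc < threshold)[0]
    if len(below) == 0:
        return float(2.0 * pixel_size_um)  # never crosses: Nyquist limit
    i = below[0]
    fc = np.interp(threshold, [frc[i], frc[i - 1]], [freqs[i], freqs[i - 1]])
    return float(pixel_size_um / fc)


# --------------------------------------------------------------------------
# cluster separability
# --------------------------------------------------------------------------

def _check_labels(features, labels):
    x = np.asarray(features, float)
    y = np.asarray(labels)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be (N, d) with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    k, n = len(classes), len(y)
    if k < 2 or k >= n:
        raise ValueError("need 2 <= k < N classes")
    return x, y, classes, counts


def ch_score(features: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz score
    ``(SS_B / SS_W) · (N − k)/(k − 1)`` with Euclidean centroid sums of
    squares; an infinity sentinel when every class is internally identical
    (SS_W = 0)."""
    x, y, classes, counts = _check_labels(features, labels)
    n, k = len(y), len(classes)
    c_all = x.mean(axis=0)
    ss_b = 0.0
    ss_w = 0.0
    for cls, nq in zip(classes, counts):
        xq = x[y == cls]
        cq = xq.mean(axis=0)
        ss_b += nq * float(((cq - c_all) ** 2).sum())
        ss_w += float(((xq - cq) ** 2).sum())
    if ss_w == 0.0:
        return float("inf")
    return float(ss_b / ss_w * (n - k) / (k - 1))


def class_distances(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Symmetric k×k matrix of mean pairwise Euclidean distances: diagonal
    entries are intra-class (all N_q² ordered pairs), off-diagonal entries
    inter-class."""
    x, y, classes, _ = _check_labels(features, labels)
    k = len(classes)
    groups = [x[y == cls] for cls in classes]
    out = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            a, b = groups[i], groups[j]
            d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
            out[i, j] = out[j, i] = d.mean()
    return out


# --------------------------------------------------------------------------
# functional traces
# --------------------------------------------------------------------------

@dataclass
class TraceSet:
    """Per-ROI fluorescence time series ``f[roi, t]`` with frame interval in
    seconds and an optional 8-direction stimulus schedule (direction label
    per time bin, −1 for blank periods)."""

    f: np.ndarray
    frame_interval_s: float
    stimulus: np.ndarray | None = None

    def __post_init__(self):
        self.f = np.atleast_2d(np.asarray(self.f, float))
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        if self.stimulus is not None:
            self.stimulus = np.asarray(self.stimulus)
            if len(self.stimulus) != self.f.shape[1]:
                raise ValueError("stimulus schedule length mismatch")

    @property
    def f0(self) -> np.ndarray:
        """Baseline per ROI: the time-mean fluorescence (recomputed)."""
        return self.f.mean(axis=1)


@dataclass
class TuningResult:
    """Per-ROI orientation tuning summary."""

    direction_responses: np.ndarray   # (n_roi, 8) mean ΔF/F0 per direction
    response_ratio: np.ndarray        # R = mean(stim)/mean(blank)
    responsive: np.ndarray            # R > 3
    r_pref: np.ndarray
    r_orth: np.ndarray
    osi: np.ndarray
    pref_direction: np.ndarray
    high_osi_fraction: float = np.nan  # responsive ROIs with OSI > 0.8


def dff(traces: TraceSet) -> np.ndarray:
    """ΔF/F₀ = (F − F₀)/F₀ with F₀ the per-ROI time mean; exact zero time
    mean by construction."""
    f0 = traces.f0
    bad = np.where(f0 <= 0)[0]
    if len(bad):
        raise ValueError(f"nonpositive baseline F0 for ROI(s) {bad.tolist()}")
    return (traces.f - f0[:, None]) / f0[:, None]


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima (greater than both neighbors); plateaus take the
    leftmost sample."""
    idx = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[j]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def detect_spikes(trace: np.ndarray, modality: str,
                  frame_interval_s: float) -> list:
    """Spike detection on a ΔF/F₀ trace.

    calcium: strict local maxima with peak > 0.40.
    voltage: subtract the running median over a 130-ms window (length in
    frames rounded, forced odd), then strict local maxima with peak > 0.02.
    Returns ``[(index, amplitude), ...]`` with amplitude = |peak value|.
    """
    x = np.asarray(trace, float)
    if frame_interval_s <= 0:
        raise ValueError("frame interval must be positive")
    if modality == "calcium":
        work = x
        thr = CALCIUM_SPIKE_THRESHOLD
    elif modality == "voltage":
        win = int(round(VOLTAGE_MEDIAN_WINDOW_S / frame_interval_s))
        win = max(win, 1)
        if win % 2 == 0:
            win += 1
        if win > len(x):
            raise ValueError("median window longer than the trace")
        work = x - ndimage.median_filter(x, size=win, mode="nearest")
        thr = VOLTAGE_SPIKE_THRESHOLD
    else:
        raise ValueError("modality must be 'calcium' or 'voltage'")
    peaks = _local_maxima(work)
    return [(int(i), float(abs(work[i]))) for i in peaks if work[i] > thr]


def tuning_analysis(traces: TraceSet,
                    n_directions: int = 8) -> TuningResult:
    """Direction tuning from 8-direction moving-grating responses.

    Per-direction responses are the mean ΔF/F₀ over that direction's
    stimulus bins; R = mean ΔF/F₀ with stimuli / mean ΔF/F₀ during blanks
    (blank bins pooled over the run); responsive ⇔ R > 3; R_orth is the
    mean response of the two directions orthogonal to the preferred one;
    OSI = (R_pref − R_orth)/(R_pref + R_orth).
    """
    if traces.stimulus is None:
        raise ValueError("tuning analysis needs a stimulus schedule")
    stim = np.asarray(traces.stimulus, int)
    if not np.any(stim < 0):
        raise ValueError("no blank periods in the schedule; the response "
                         "ratio R is undefined")
    d = dff(traces)
    n_roi = d.shape[0]
    resp = np.empty((n_roi, n_directions))
    for k in range(n_directions):
        sel = stim == k
        if not sel.any():
            raise ValueError(f"direction {k} missing from the schedule")
        resp[:, k] = d[:, sel].mean(axis=1)
    blank = d[:, stim < 0].mean(axis=1)
    stim_mean = d[:, stim >= 0].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = stim_mean / blank
    responsive = ratio > RESPONSE_RATIO_THRESHOLD

    pref = resp.argmax(axis=1)
    r_pref = resp.max(axis=1)
    orth = np.stack([(pref + n_directions // 4) % n_directions,
                     (pref - n_directions // 4) % n_directions], axis=1)
    r_orth = np.take_along_axis(resp, orth, axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        osi = np.where(r_pref + r_orth != 0,
                       (r_pref - r_orth) / (r_pref + r_orth), 0.0)
    n_resp = int(responsive.sum())
    frac = (float((osi[responsive] > HIGH_OSI_THRESHOLD).sum()) / n_resp
            if n_resp else np.nan)
    return TuningResult(direction_responses=resp, response_ratio=ratio,
                        responsive=responsive, r_pref=r_pref, r_orth=r_orth,
                        osi=osi, pref_direction=pref,
                        high_osi_fraction=frac)
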