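"""Resting-state preprocessing chain.

Fixed stage order: motion-stable epoch selection -> in-plane (2-D)
Gaussian smoothing -> per-voxel Fourier low-pass -> global-signal
regression, with temporal SNR computed on the raw epoch as quality
control.  Smoothing never crosses slices or time; the low-pass is a
brick-wall filter that preserves the DC component.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage

from .io import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "select_stable_epoch",
    "smooth_inplane",
    "lowpass_fourier",
    "regress_global_signal",
    "compute_tsnr",
    "preprocess_series",
]

#: defaults from the acquisition protocol: 15 min stable window at TR 1 s,
#: <0.2 mm translation and <0.3 deg rotation range per axis
DEFAULT_WINDOW_VOLUMES = 900
DEFAULT_TRANS_THRESH_MM = 0.2
DEFAULT_ROT_THRESH_DEG = 0.3


@dataclasses.dataclass(frozen=True)
class Epoch:
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.length <= 0:
            raise ValueError("epoch start must be >= 0 and length positive")

    @property
    def stop(self) -> int:
        return self.start + self.length


def select_stable_epoch(
    motion: np.ndarray,
    window_volumes: int = DEFAULT_WINDOW_VOLUMES,
    trans_thresh_mm: float = DEFAULT_TRANS_THRESH_MM,
    rot_thresh_deg: float = DEFAULT_ROT_THRESH_DEG,
    fallback_first: bool = True,
) -> Epoch:
    """Earliest continuous window whose per-axis motion range stays below
    threshold.

    A window qualifies when max - min over the window is below
    ``trans_thresh_mm`` on each of the three translation axes and below
    ``rot_thresh_deg`` on each rotation axis (thresholds applied per axis).
    When no window qualifies the first window is returned with a warning
    (``fallback_first``), or ``ValueError`` raised.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (n_volumes, 6)")
    n = motion.shape[0]
    if window_volumes > n:
        raise ValueError(f"window of {window_volumes} exceeds trace length {n}")
    windows = np.lib.stride_tricks.sliding_window_view(motion, window_volumes, axis=0)
    rng = windows.max(axis=2) - windows.min(axis=2)  # (n_windows, 6)
    ok = np.all(rng[:, :3] < trans_thresh_mm, axis=1) & np.all(
        rng[:, 3:] < rot_thresh_deg, axis=1
    )
    hits = np.nonzero(ok)[0]
    if hits.size:
        return Epoch(int(hits[0]), window_volumes)
    if fallback_first:
        logger.warning(
            "no motion-stable window of %d volumes; falling back to the first window",
            window_volumes,
        )
        return Epoch(0, window_volumes)
    raise ValueError("no motion-stable window found")


def _gaussian_kernel_2d(fwhm_mm: float, pixel_mm: tuple[float, float], size: int = 3) -> np.ndarray:
    sigma_mm = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = size // 2
    ax = np.arange(-half, half + 1)
    gx = np.exp(-0.5 * (ax * pixel_mm[0] / sigma_mm) ** 2)
    gy = np.exp(-0.5 * (ax * pixel_mm[1] / sigma_mm) ** 2)
    k = np.outer(gx, gy)
    return k / k.sum()


def smooth_inplane(series: Volume, fwhm_mm: float = 0.6, kernel_px: int = 3) -> Volume:
    """2-D Gaussian smoothing of each slice of each volume.

    Truncated ``kernel_px`` x ``kernel_px`` kernel of sigma =
    fwhm / (2 sqrt(2 ln 2)) mm converted to pixels, normalised to unit
    sum.  Outside the image the data is treated as absent: the kernel is
    renormalised over its in-image support (normalised convolution), so a
    constant image stays constant up to the border.
    """
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    data = np.asarray(series.data, dtype=float)
    kernel = _gaussian_kernel_2d(fwhm_mm, series.spacing[:2], kernel_px)
    k4 = kernel[:, :, None, None] if data.ndim == 4 else kernel[:, :, None]
    num = ndimage.convolve(data, k4, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(data), k4, mode="constant", cval=0.0)
    return Volume(data=num / den, spacing=series.spacing, tr=series.tr, affine=series.affine)


def lowpass_fourier(series: Volume, cutoff_hz: float = 0.1, tr: float | None = None) -> Volume:
    """Brick-wall temporal low-pass: per-voxel FFT, coefficients at
    frequencies strictly above ``cutoff_hz`` zeroed, inverse FFT.  The DC
    term (mean) always passes."""
    tr = tr if tr is not None else series.tr
    if tr is None or tr <= 0:
        raise ValueError("series needs a positive TR")
    nyquist = 0.5 / tr
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist {nyquist} Hz")
    data = np.asarray(series.data, dtype=float)
    if data.ndim != 4:
        raise ValueError("low-pass expects a 4-D series")
    n = data.shape[3]
    spec = np.fft.rfft(data, axis=3)
    freqs = np.fft.rfftfreq(n, d=tr)
    spec[..., freqs > cutoff_hz] = 0.0
    out = np.fft.irfft(spec, n=n, axis=3)
    return Volume(data=out, spacing=series.spacing, tr=tr, affine=series.affine)


def regress_global_signal(series: Volume, brain_mask: np.ndarray) -> Volume:
    """Regress the in-mask global mean time course out of every voxel.

    Per voxel, an ordinary least-squares fit on [intercept, global mean];
    the residuals are returned (out-of-mask voxels zeroed).
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    data = np.asarray(series.data, dtype=float)
    if data.ndim != 4:
        raise ValueError("global-signal regression expects a 4-D series")
    g = data[mask].mean(axis=0)
    if g.std() == 0:
        raise ValueError("global signal has zero variance")
    # near-zero global variance (e.g. data already regressed) would make
    # the fit ill-conditioned; fall back to intercept-only, which keeps
    # the operation idempotent
    if g.std() < 1e-8 * (1.0 + np.abs(data).max()):
        X = np.ones((g.size, 1))
    else:
        X = np.column_stack([np.ones_like(g), g])  # (n_t, 2)
    Y = data[mask].T  # (n_t, n_vox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = np.zeros_like(data)
    out[mask] = resid.T
    return Volume(data=out, spacing=series.spacing, tr=series.tr, affine=series.affine)


def compute_tsnr(series: Volume, roi_mask: np.ndarray) -> float:
    """Temporal SNR over an ROI: mean over ROI voxels of temporal mean /
    temporal SD (SD with the n-1 denominator).

    Computed on the raw (pre-filter) epoch — filtering would inflate the
    estimate and defeat its QC purpose.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    data = np.asarray(series.data, dtype=float)
    if data.ndim != 4 or data.shape[3] < 2:
        raise ValueError("tSNR needs a 4-D series of length >= 2")
    vox = data[mask]
    sd = vox.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero temporal SD in ROI voxel(s): tSNR undefined")
    return float(np.mean(vox.mean(axis=1) / sd))


def preprocess_series(
    series: Volume,
    motion: np.ndarray,
    brain_mask: np.ndarray,
    window_volumes: int | None = None,
    fwhm_mm: float = 0.6,
    cutoff_hz: float = 0.1,
) -> tuple[Volume, Epoch, float]:
    """Full chain: epoch -> smooth -> low-pass -> global-signal
    regression.  Returns (processed series, epoch used, raw-epoch tSNR
    over the brain mask)."""
    n = series.data.shape[3]
    window = min(window_volumes or DEFAULT_WINDOW_VOLUMES, n)
    epoch = select_stable_epoch(motion, window)
    cropped = Volume(
        data=series.data[..., epoch.start : epoch.stop],
        spacing=series.spacing, tr=series.tr, affine=series.affine,
    )
    tsnr = compute_tsnr(cropped, brain_mask)
    out = smooth_inplane(cropped, fwhm_mm)
    out = lowpass_fourier(out, cutoff_hz)
    out = regress_global_signal(out, brain_mask)
    return out, epoch, tsnr
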