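"""Smooth background estimation and dF / dFF correction.

The background model assumes that, once transient calcium events are masked
out, the remaining fluorescence varies smoothly in space and time (uneven
illumination, bleaching).  Per-pixel peaks are masked (:func:`mask_peaks`),
the video is spatially downscaled, and a radial-basis-function interpolant is
fitted to the unmasked (t, y, x) samples and evaluated everywhere — masked
voxels are predicted, unmasked voxels re-predicted for smoothness.  The
result is upscaled back and subtracted either directly (dF) or divided out
(dFF = (F - bg) / max(bg, floor)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks, peak_widths
from skimage.transform import resize

from .errors import DegenerateTraceError, InterpolationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PeakMaskConfig:
    prominence: float = 0.1
    wlen: Optional[int] = None
    distance: Optional[int] = None
    width: int = 1
    rel_height: float = 0.9

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise ValidationError("prominence must be > 0")
        if not (0 < self.rel_height <= 1):
            raise ValidationError("rel_height must be in (0, 1]")
        if self.width < 1:
            raise ValidationError("width must be >= 1")


@dataclass
class RbfConfig:
    neighbors: int = 50
    smoothing: float = 0.0
    kernel: str = "thin_plate_spline"
    epsilon: Optional[float] = None
    degree: Optional[int] = 1

    def __post_init__(self) -> None:
        if self.neighbors < 1:
            raise ValidationError("neighbors must be >= 1")
        if self.smoothing < 0:
            raise ValidationError("smoothing must be >= 0")


@dataclass
class BackgroundResult:
    background: np.ndarray
    corrected: np.ndarray
    method: str


def peak_intervals(trace: np.ndarray, cfg: PeakMaskConfig) -> list[tuple[int, int]]:
    """Inclusive frame intervals covered by detected peaks (at rel_height)."""
    peaks, _props = find_peaks(
        trace,
        prominence=cfg.prominence,
        wlen=cfg.wlen,
        distance=cfg.distance,
        width=cfg.width,
    )
    if len(peaks) == 0:
        return []
    _, _, left, right = peak_widths(
        trace, peaks, rel_height=cfg.rel_height, wlen=cfg.wlen
    )
    # round the interpolated extent outward to whole frames
    return [
        (int(np.floor(lo)), int(np.ceil(hi))) for lo, hi in zip(left, right)
    ]


def mask_peaks(trace: np.ndarray, cfg: PeakMaskConfig) -> np.ndarray:
    """Replace frames inside each peak's extent with NaN."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or len(trace) < 3:
        raise ValidationError("trace must be 1D with length >= 3")
    if not np.all(np.isfinite(trace)):
        raise ValidationError("trace must be finite")
    out = trace.copy()
    for lo, hi in peak_intervals(trace, cfg):
        out[lo : hi + 1] = np.nan
    if np.all(np.isnan(out)):
        raise DegenerateTraceError("peak masking removed every frame")
    return out


def _downscale(video: np.ndarray, scale_factor: float) -> np.ndarray:
    if scale_factor == 1.0:
        return video
    T, H, W = video.shape
    h, w = max(2, round(H * scale_factor)), max(2, round(W * scale_factor))
    return resize(video, (T, h, w), order=1, anti_aliasing=False, mode="edge")


def estimate_background(
    video: np.ndarray,
    scale_factor: float = 0.25,
    blur_sigma: float = 0.0,
    blur_radius: int = 2,
    peaks: Optional[PeakMaskConfig] = None,
    rbf: Optional[RbfConfig] = None,
    time_scale: float = 1.0,
) -> np.ndarray:
    """Estimate a smooth background stack with the same shape as ``video``.

    Pipeline: spatial downscale -> optional per-frame Gaussian blur ->
    per-pixel peak masking -> RBF interpolation over (t, y, x) with time
    treated as a third coordinate scaled by ``time_scale`` -> per-frame
    bilinear upscale back to full resolution.
    """
    video = np.asarray(video, dtype=float)
    if video.ndim != 3:
        raise ValidationError("video must be a (T, H, W) stack")
    if not np.all(np.isfinite(video)):
        raise ValidationError("video must be finite")
    if not (0 < scale_factor <= 1):
        raise ValidationError("scale_factor must be in (0, 1]")
    peaks = peaks or PeakMaskConfig()
    rbf = rbf or RbfConfig()

    small = _downscale(video, scale_factor)
    if blur_sigma > 0:
        truncate = max(blur_radius, 1) / blur_sigma
        small = gaussian_filter(small, sigma=(0, blur_sigma, blur_sigma), truncate=truncate)
    T, h, w = small.shape

    masked = np.empty_like(small)
    for y in range(h):
        for x in range(w):
            try:
                masked[:, y, x] = mask_peaks(small[:, y, x], peaks)
            except DegenerateTraceError:
                logger.warning(
                    "pixel (%d, %d): all frames masked; using unmasked trace", y, x
                )
                masked[:, y, x] = small[:, y, x]

    tt, yy, xx = np.mgrid[0:T, 0:h, 0:w].astype(float)
    tt *= time_scale
    coords = np.column_stack([tt.ravel(), yy.ravel(), xx.ravel()])
    values = masked.ravel()
    keep = np.isfinite(values)
    n_keep = int(keep.sum())
    if n_keep < max(4, min(rbf.neighbors, len(values)) // 2):
        raise InterpolationError(
            f"only {n_keep} unmasked samples remain; relax the peak-mask "
            "parameters (larger prominence) or reduce the neighborhood"
        )
    interp = RBFInterpolator(
        coords[keep],
        values[keep],
        neighbors=min(rbf.neighbors, n_keep),
        smoothing=rbf.smoothing,
        kernel=rbf.kernel,
        epsilon=rbf.epsilon,
        degree=rbf.degree,
    )
    bg_small = interp(coords).reshape(T, h, w)

    if (h, w) == video.shape[1:]:
        return bg_small
    return resize(
        bg_small, video.shape, order=1, anti_aliasing=False, mode="edge"
    )


def subtract_background(
    video: np.ndarray,
    background: np.ndarray,
    method: str = "dF",
    floor: Optional[float] = None,
) -> BackgroundResult:
    """Apply dF (subtract) or dFF (subtract then divide) correction."""
    video = np.asarray(video, dtype=float)
    background = np.asarray(background, dtype=float)
    if video.shape != background.shape:
        raise ValidationError("video and background shapes must match")
    if method == "dF":
        corrected = video - background
    elif method == "dFF":
        if floor is None:
            floor = 1e-6 * float(np.abs(background).max() or 1.0)
        corrected = (video - background) / np.maximum(background, floor)
    else:
        raise ValidationError(f"method must be 'dF' or 'dFF', got {method!r}")
    return BackgroundResult(background=background, corrected=corrected, method=method)


def background_qc(video: np.ndarray, masked_fraction: float) -> dict:
    """Small QC summary surfaced instead of auto-tuning guards."""
    curvature = float(np.mean(np.abs(np.diff(video, n=2, axis=0))))
    return {"masked_fraction": float(masked_fraction), "background_curvature": curvature}
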