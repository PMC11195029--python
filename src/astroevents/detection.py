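"""Spatiotemporal calcium-event detection.

Events are found by combining two independent sources of evidence on a
(smoothed) fluorescence stack:

* **spatial thresholding** — per rolling window of ``z_depth`` frames an
  intensity cutoff is selected automatically (quantile scan); a frame's
  pixels above the cutoff are accepted only if the mean fluorescence of
  active pixels exceeds ``min_ratio`` times the mean of inactive pixels,
  which suppresses frames that contain nothing but noise;
* **temporal thresholding** — each pixel's time series is scanned for peaks
  with a minimum prominence; frames inside each peak's extent (measured at
  ``rel_height`` of the prominence) are marked active.

The two boolean masks are merged (union) or intersected, cleaned up
morphologically (2D hole filling per frame, 3D small-object removal), and
the surviving voxels are labelled as 3D connected components — one label per
event.  Each event is summarised by its bounding box, footprint (time-max
projection), per-frame mean-fluorescence trace and an SNR estimate, and the
whole collection is written to a ``.roi`` directory that round-trips
losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.signal import find_peaks, peak_widths
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_holes, remove_small_objects

from .errors import ValidationError
from .io_store import VideoStore

logger = logging.getLogger(__name__)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

#: quantile grid scanned when auto-selecting the spatial cutoff
_CUTOFF_QUANTILES = np.linspace(0.50, 0.995, 40)


@dataclass
class DetectionConfig:
    """Parameters of the detection pipeline (defaults suit dF-corrected data)."""

    sigma: float = 1.0
    radius: int = 3
    min_ratio: float = 1.3
    z_depth: int = 1
    prominence: float = 2.0
    width: int = 3
    rel_height: float = 0.7
    wlen: Optional[int] = 101
    combine_mode: str = "union"
    area_threshold: int = 10
    min_size: int = 20
    connectivity: int = 26
    exclude_border: int = 0
    halo: int = 100  # extra frames read around each time chunk
    split_events: bool = False

    def __post_init__(self) -> None:
        if self.min_ratio < 1:
            raise ValidationError("min_ratio must be >= 1")
        if self.z_depth < 1:
            raise ValidationError("z_depth must be >= 1")
        if self.combine_mode not in ("union", "intersection"):
            raise ValidationError("combine_mode must be 'union' or 'intersection'")
        if self.min_size < 1:
            raise ValidationError("min_size must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValidationError("connectivity must be 6, 18 or 26")
        if self.split_events:
            raise ValidationError("--split-events is unsupported")


def smooth(video: np.ndarray, sigma: float, radius: int = 3) -> np.ndarray:
    """Spatial-only Gaussian blur per frame; ``sigma=0`` returns the input."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if radius < 1:
        raise ValidationError("radius must be >= 1")
    video = np.asarray(video, dtype=float)
    if sigma == 0:
        return video
    return ndimage.gaussian_filter(
        video, sigma=(0, sigma, sigma), truncate=radius / sigma
    )


def _select_cutoff(window: np.ndarray, min_ratio: float) -> Optional[float]:
    """Auto cutoff for one spatial-threshold window, or None if no cutoff
    passes the active/inactive mean-ratio test.

    Candidates are the window's intensity quantiles (q = 0.50 … 0.995, 40
    steps).  The smallest qualifying cutoff is chosen; with ``min_ratio <= 1``
    every candidate qualifies and the Otsu-style cutoff (maximal
    between-class variance) is taken instead.  The ratio test requires a
    positive inactive mean — a window of zero-mean noise never qualifies.
    """
    values = np.sort(window.ravel())
    n = len(values)
    cumsum = np.concatenate([[0.0], np.cumsum(values)])
    total = cumsum[-1]
    cutoffs = np.unique(np.quantile(values, _CUTOFF_QUANTILES))

    idx = np.searchsorted(values, cutoffs, side="left")
    n_hi = n - idx
    valid = (n_hi > 0) & (idx > 0)
    if not valid.any():
        return None
    idx, n_hi, cutoffs = idx[valid], n_hi[valid], cutoffs[valid]
    mean_hi = (total - cumsum[idx]) / n_hi
    mean_lo = cumsum[idx] / idx

    if min_ratio > 1:
        ok = (mean_lo > 0) & (mean_hi >= min_ratio * mean_lo)
        if not ok.any():
            return None
        return float(cutoffs[np.argmax(ok)])  # smallest qualifying cutoff
    # min_ratio == 1: every cutoff qualifies; take maximal between-class variance
    w_hi = n_hi / n
    between = w_hi * (1 - w_hi) * (mean_hi - mean_lo) ** 2
    return float(cutoffs[np.argmax(between)])


def spatial_threshold(
    video: np.ndarray, min_ratio: float = 1.3, z_depth: int = 1
) -> np.ndarray:
    """Boolean mask from per-window auto-thresholding with a ratio guard."""
    if min_ratio < 1:
        raise ValidationError("min_ratio must be >= 1")
    video = np.asarray(video, dtype=float)
    T = video.shape[0]
    mask = np.zeros(video.shape, dtype=bool)
    half = z_depth // 2
    for t in range(T):
        lo = max(0, t - half)
        hi = min(T, lo + z_depth)
        lo = max(0, hi - z_depth)
        cutoff = _select_cutoff(video[lo:hi], min_ratio)
        if cutoff is not None:
            mask[t] = video[t] >= cutoff
    return mask


def _pixel_peak_frames(
    trace: np.ndarray,
    prominence: float,
    width: int,
    rel_height: float,
    wlen: Optional[int],
) -> list[tuple[int, int]]:
    peaks, _ = find_peaks(trace, prominence=prominence, width=width, wlen=wlen)
    if len(peaks) == 0:
        return []
    _, _, left, right = peak_widths(trace, peaks, rel_height=rel_height, wlen=wlen)
    return [(int(np.floor(lo)), int(np.ceil(hi))) for lo, hi in zip(left, right)]


def temporal_threshold(
    video: np.ndarray,
    prominence: float = 2.0,
    width: int = 3,
    rel_height: float = 0.7,
    wlen: Optional[int] = None,
) -> np.ndarray:
    """Boolean mask marking, per pixel, the frames inside prominent peaks."""
    if prominence <= 0:
        raise ValidationError("prominence must be > 0")
    video = np.asarray(video, dtype=float)
    T, H, W = video.shape
    mask = np.zeros(video.shape, dtype=bool)
    # a peak's prominence can never exceed the trace's total range
    candidates = np.ptp(video, axis=0) >= prominence
    for y, x in zip(*np.nonzero(candidates)):
        for lo, hi in _pixel_peak_frames(
            video[:, y, x], prominence, width, rel_height, wlen
        ):
            mask[lo : hi + 1, y, x] = True
    return mask


def combine_masks(
    spatial_mask: np.ndarray, temporal_mask: np.ndarray, combine_mode: str = "union"
) -> np.ndarray:
    if spatial_mask.shape != temporal_mask.shape:
        raise ValidationError("mask shapes must match")
    if combine_mode == "union":
        return spatial_mask | temporal_mask
    if combine_mode == "intersection":
        return spatial_mask & temporal_mask
    raise ValidationError(f"unknown combine_mode {combine_mode!r}")


def morphological_cleanup(
    mask: np.ndarray,
    area_threshold: int = 10,
    min_size: int = 20,
    connectivity: int = 26,
) -> np.ndarray:
    """2D hole filling per frame, then 3D small-component removal."""
    rank = _CONNECTIVITY_RANK[connectivity]
    out = np.empty_like(mask)
    for t in range(mask.shape[0]):
        # holes of area <= area_threshold are filled
        out[t] = remove_small_holes(mask[t], max_size=area_threshold)
    # components with voxel count < min_size are removed
    return remove_small_objects(out, max_size=min_size - 1, connectivity=rank)


def exclude_border(mask: np.ndarray, border_width: int) -> np.ndarray:
    if border_width < 0:
        raise ValidationError("border_width must be >= 0")
    H, W = mask.shape[1:]
    if border_width >= (min(H, W) + 1) // 2:
        raise ValidationError(
            f"border width {border_width} would clear the whole {H}x{W} frame"
        )
    if border_width == 0:
        return mask
    out = mask.copy()
    out[:, :border_width, :] = False
    out[:, -border_width:, :] = False
    out[:, :, :border_width] = False
    out[:, :, -border_width:] = False
    return out


def label_events(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """3D connected-component labels (0 = background)."""
    return sk_label(mask, connectivity=_CONNECTIVITY_RANK[connectivity]).astype(
        np.int32
    )


def _event_snr(
    video: np.ndarray, footprint_yx: tuple[np.ndarray, np.ndarray],
    z0: int, trace: np.ndarray,
) -> float:
    """Peak trace amplitude over a robust noise scale.

    Baseline region: the event's own pixels in the 5 frames before onset;
    when the event starts at the first frame, the first video frame serves
    as the reference region instead.
    """
    ys, xs = footprint_yx
    lo = max(0, z0 - 5)
    baseline_region = video[lo:z0, ys, xs] if z0 > 0 else video[0:1].ravel()
    baseline = float(np.median(baseline_region))
    mad = float(np.median(np.abs(baseline_region - baseline)))
    sigma = 1.4826 * mad
    peak = float(np.max(trace) - baseline)
    return peak / sigma if sigma > 0 else float("inf")


def extract_events(
    labels: np.ndarray,
    fluorescence_video: np.ndarray,
    output_dir: Union[str, Path],
    config: Optional[DetectionConfig] = None,
    source: Optional[dict] = None,
) -> "EventCollection":
    """Summarise every labelled component and write a ``.roi`` collection."""
    if labels.shape != fluorescence_video.shape:
        raise ValidationError("labels and video must share a shape")
    objects = ndimage.find_objects(labels)
    rows, traces, footprints = [], {}, {}
    for event_id, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        sub = labels[slc] == event_id
        z0, z1 = slc[0].start, slc[0].stop - 1
        y0, y1 = slc[1].start, slc[1].stop
        x0, x1 = slc[2].start, slc[2].stop
        footprint = sub.any(axis=0)
        sub_video = fluorescence_video[slc]
        trace = np.array(
            [sub_video[t][sub[t]].mean() for t in range(sub.shape[0])]
        )
        ys, xs = np.nonzero(footprint)
        snr = _event_snr(
            fluorescence_video, (ys + y0, xs + x0), z0, trace
        )
        rows.append(
            {
                "event_id": event_id,
                "z0": z0,
                "z1": z1,
                "dz": z1 - z0 + 1,
                "x0": x0,
                "y0": y0,
                "x1": x1,
                "y1": y1,
                "v_area": int(footprint.sum()),
                "n_voxels": int(sub.sum()),
                "v_signal_to_noise_ratio": snr,
            }
        )
        traces[event_id] = trace
        footprints[event_id] = footprint
    if not rows:
        logger.warning("no events detected; writing an empty collection")
    events = pd.DataFrame(
        rows,
        columns=[
            "event_id", "z0", "z1", "dz", "x0", "y0", "x1", "y1",
            "v_area", "n_voxels", "v_signal_to_noise_ratio",
        ],
    )
    return EventCollection.create(
        output_dir,
        events=events,
        traces=traces,
        footprints=footprints,
        labels=labels,
        config=config,
        source=source,
    )


class EventCollection:
    """On-disk ``.roi`` directory of detected events.

    Layout: ``events.csv`` (one row per event, scalar fields), ``traces.h5``
    (one ragged dataset per event id), ``footprints.h5`` (boolean bounding-box
    masks), ``labels.h5`` (the full label volume, when available) and
    ``config.yaml`` (provenance).
    """

    def __init__(self, directory: Union[str, Path]):
        self.directory = Path(directory)
        self.events = pd.read_csv(self.directory / "events.csv")

    # -- construction ------------------------------------------------------
    @classmethod
    def create(
        cls,
        directory: Union[str, Path],
        events: pd.DataFrame,
        traces: dict[int, np.ndarray],
        footprints: dict[int, np.ndarray],
        labels: Optional[np.ndarray] = None,
        config: Optional[DetectionConfig] = None,
        source: Optional[dict] = None,
    ) -> "EventCollection":
        directory = Path(directory)
        if directory.suffix != ".roi":
            directory = directory.with_suffix(".roi")
        directory.mkdir(parents=True, exist_ok=True)
        events.to_csv(directory / "events.csv", index=False)
        with h5py.File(directory / "traces.h5", "w") as fh:
            for eid, tr in traces.items():
                fh.create_dataset(f"traces/{eid}", data=np.asarray(tr, dtype=float))
        with h5py.File(directory / "footprints.h5", "w") as fh:
            for eid, fp in footprints.items():
                fh.create_dataset(f"footprints/{eid}", data=np.asarray(fp, dtype=bool))
        if labels is not None:
            with h5py.File(directory / "labels.h5", "w") as fh:
                fh.create_dataset("labels", data=labels, compression="gzip")
        provenance = {
            "config": None if config is None else asdict(config),
            "source": source or {},
            "n_events": int(len(events)),
        }
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(provenance, fh)
        return cls(directory)

    # -- access ------------------------------------------------------------
    def trace(self, event_id: int) -> np.ndarray:
        with h5py.File(self.directory / "traces.h5", "r") as fh:
            return fh[f"traces/{event_id}"][()]

    def footprint(self, event_id: int) -> np.ndarray:
        with h5py.File(self.directory / "footprints.h5", "r") as fh:
            return fh[f"footprints/{event_id}"][()]

    def label_volume(self) -> np.ndarray:
        path = self.directory / "labels.h5"
        if not path.exists():
            raise ValidationError(f"{self.directory} has no stored label volume")
        with h5py.File(path, "r") as fh:
            return fh["labels"][()]

    @property
    def provenance(self) -> dict:
        with open(self.directory / "config.yaml") as fh:
            return yaml.safe_load(fh)

    def to_table(self) -> pd.DataFrame:
        """Events as a DataFrame with an in-memory ragged ``trace`` column."""
        table = self.events.copy()
        table["trace"] = [self.trace(eid) for eid in table["event_id"]]
        table.attrs["provenance"] = [str(self.directory)]
        return table

    def __len__(self) -> int:
        return len(self.events)


def detect(
    video_store: Union[VideoStore, np.ndarray],
    cfg: Optional[DetectionConfig] = None,
    output_dir: Union[str, Path] = "events.roi",
    time_chunk: Optional[int] = None,
) -> EventCollection:
    """Full detection pipeline; chunk-wise over time with halo frames.

    Thresholding runs on the smoothed stack; event traces are extracted from
    the raw (un-smoothed) input.  With ``halo`` at least as large as the
    temporal-peak window and the longest event, results are independent of
    ``time_chunk``.
    """
    cfg = cfg or DetectionConfig()
    if isinstance(video_store, np.ndarray):
        full_video = np.asarray(video_store, dtype=float)
        reader = lambda lo, hi: full_video[lo:hi]  # noqa: E731
        T, H, W = full_video.shape
        source = {"video_shape": [int(T), int(H), int(W)]}
    else:
        T, H, W = video_store.shape
        reader = lambda lo, hi: np.asarray(  # noqa: E731
            video_store.read_window((lo, hi)), dtype=float
        )
        full_video = None
        source = {
            "video_path": str(video_store.path),
            "video_loc": video_store.loc,
            "video_shape": [int(T), int(H), int(W)],
        }

    chunk = T if time_chunk is None else int(time_chunk)
    mask = np.zeros((T, H, W), dtype=bool)
    for start in range(0, T, chunk):
        end = min(T, start + chunk)
        lo = max(0, start - cfg.halo)
        hi = min(T, end + cfg.halo)
        block = smooth(reader(lo, hi), cfg.sigma, cfg.radius)
        sp = spatial_threshold(block, cfg.min_ratio, cfg.z_depth)
        tp = temporal_threshold(
            block, cfg.prominence, cfg.width, cfg.rel_height, cfg.wlen
        )
        combined = combine_masks(sp, tp, cfg.combine_mode)
        mask[start:end] = combined[start - lo : end - lo]

    mask = morphological_cleanup(
        mask, cfg.area_threshold, cfg.min_size, cfg.connectivity
    )
    if cfg.exclude_border:
        mask = exclude_border(mask, cfg.exclude_border)
    labels = label_events(mask, cfg.connectivity)
    if full_video is None:
        full_video = reader(0, T)
    return extract_events(labels, full_video, output_dir, config=cfg, source=source)


def summarize_detection(collection: EventCollection) -> dict:
    """Event count plus duration/area/SNR quantiles (printable QC summary)."""
    ev = collection.events
    if len(ev) == 0:
        return {"n_events": 0}
    q = [0.05, 0.25, 0.5, 0.75, 0.95]
    snr = ev["v_signal_to_noise_ratio"].replace(np.inf, np.nan)
    return {
        "n_events": int(len(ev)),
        "dz_quantiles": {str(p): float(v) for p, v in zip(q, np.quantile(ev["dz"], q))},
        "area_quantiles": {
            str(p): float(v) for p, v in zip(q, np.quantile(ev["v_area"], q))
        },
        "snr_quantiles": {
            str(p): float(v) for p, v in zip(q, np.nanquantile(snr, q))
        },
    }
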