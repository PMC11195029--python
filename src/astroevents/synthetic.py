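"""Ground-truthed synthetic calcium-imaging data.

Every stage of the pipeline can be exercised without real recordings:
parametric event traces (:func:`generate_trace`), labelled event tables with
optional stimulus-locked timing (:func:`generate_event_table`), rendered noisy
videos with per-voxel ground truth (:func:`render_video`), and a detection
benchmark report (:func:`evaluate_detection`).

The canonical transient is a linear rise over ``rise_time`` frames to
``amplitude``, a plateau of ``plateau_duration`` frames, and an exponential
decay ``amplitude * exp(-b * t)`` followed until it falls below 1% of the
peak.  Each shape parameter is jittered per event by a multiplicative factor
``1 + eps`` with ``eps ~ Normal(0, parameter_fluctuations)``, and Gaussian
noise of scale ``noise_amplitude * amplitude`` is added to every frame.

Unless ``onset_jitter`` is disabled, the transient is placed at a uniformly
drawn onset inside the trace window (with a one-frame baseline margin), so
that traces of the same kind are *not* phase-aligned.  This emulates event
windows that capture transients at arbitrary phase — the property that makes
alignment-sensitive similarity measures (Pearson) uninformative while elastic
measures (DTW) still work, which is the point of the benchmark.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import PlacementError, ValidationError

logger = logging.getLogger(__name__)

#: fraction of an event's peak below which its noiseless contribution is no
#: longer counted as part of the event (trace tail cutoff and ground-truth
#: voxel support share this rule)
SUPPORT_FRACTION = 0.2
_DECAY_FLOOR = 0.01  # decay is rendered until it falls below 1% of peak


@dataclass
class SignalParams:
    """Parameters of one population of synthetic calcium transients."""

    trace_length: tuple[int, int] = (50, 50)
    noise_amplitude: float = 0.001
    parameter_fluctuations: float = 0.01
    b: float = 1.0
    plateau_duration: float = 1.0
    amplitude: float = 1.0
    rise_time: float = 3.0
    onset_jitter: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.trace_length
        if lo > hi or lo < 4:
            raise ValidationError("trace_length must satisfy 4 <= min <= max")
        if self.noise_amplitude < 0 or self.parameter_fluctuations < 0:
            raise ValidationError("noise and fluctuation scales must be >= 0")
        if self.b <= 0:
            raise ValidationError("decay rate b must be positive")


@dataclass
class SceneParams:
    """Layout of a synthetic experiment (event table and/or rendered video)."""

    num_rows: int = 100
    z_range: tuple[int, int] = (0, 10000)
    generators: Sequence[SignalParams] = field(default_factory=lambda: [SignalParams()])
    timings: Optional[Sequence[Optional[Sequence[int]]]] = None
    video_shape: tuple[int, int, int] = (500, 128, 128)
    blob_radius: float = 2.0
    background_level: float = 0.0
    pixel_noise: float = 0.0
    min_separation: Optional[float] = None  # default 4 * blob_radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_rows < 1:
            raise ValidationError("num_rows must be >= 1")
        if self.timings is not None:
            if len(self.timings) != len(self.generators):
                raise ValidationError("timings must match generators")
            z0, z1 = self.z_range
            for t in self.timings:
                if t is not None and any(not (z0 <= v <= z1) for v in t):
                    raise ValidationError("all timings must lie within z_range")


def _jitter(rng: np.random.Generator, value: float, sigma: float) -> float:
    return float(value * (1.0 + rng.normal(0.0, sigma))) if sigma > 0 else float(value)


def canonical_shape(
    b: float, plateau: int, rise: int, amplitude: float, max_len: int
) -> np.ndarray:
    """Noiseless transient: rise, plateau, exponential decay down to 1% of peak."""
    n_decay = int(np.ceil(np.log(1.0 / _DECAY_FLOOR) / b))
    n_decay = max(1, min(n_decay, max_len))
    rise_part = np.linspace(0.0, amplitude, rise, endpoint=False) + amplitude / rise
    decay_part = amplitude * np.exp(-b * np.arange(1, n_decay + 1))
    return np.concatenate([rise_part, np.full(plateau, amplitude), decay_part])


def generate_trace(
    params: SignalParams, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Draw one synthetic trace; returns (trace, ground-truth parameter record)."""
    lo, hi = params.trace_length
    length = int(rng.integers(lo, hi + 1))
    sig = params.parameter_fluctuations
    b = max(1e-6, _jitter(rng, params.b, sig))
    amplitude = _jitter(rng, params.amplitude, sig)
    rise = max(1, int(round(_jitter(rng, params.rise_time, sig))))
    plateau = max(0, int(round(_jitter(rng, params.plateau_duration, sig))))

    if rise + plateau > length:
        # keep the peak inside the window by shrinking rise/plateau proportionally
        scale = (length - 1) / (rise + plateau)
        rise = max(1, int(rise * scale))
        plateau = max(0, int(plateau * scale))
        warnings.warn(
            "rise_time + plateau_duration exceed trace length; rescaled",
            stacklevel=2,
        )

    core = canonical_shape(b, plateau, rise, amplitude, max_len=length)
    trace = np.zeros(length)
    max_onset = max(0, length - len(core) - 1)
    if params.onset_jitter and max_onset >= 1:
        onset = int(rng.integers(1, max_onset + 1))
    else:
        onset = 0
    segment = core[: length - onset]
    trace[onset : onset + len(segment)] = segment
    if params.noise_amplitude > 0:
        trace = trace + rng.normal(0.0, params.noise_amplitude * amplitude, length)
    record = {
        "length": length,
        "onset": onset,
        "b": b,
        "plateau": plateau,
        "rise": rise,
        "amplitude": amplitude,
    }
    return trace, record


def generate_event_table(scene: SceneParams) -> pd.DataFrame:
    """Event table with one row per synthetic event.

    Columns: ``event_id, group, z0, z1, dz, trace, truncated`` plus the drawn
    shape parameters.  Group ``g``'s onset frames come from ``timings[g]``
    (cycled when ``num_rows`` exceeds the list) or are uniform in ``z_range``.
    """
    rng = np.random.default_rng(scene.seed)
    z_lo, z_hi = scene.z_range
    rows = []
    eid = 0
    for g, gen in enumerate(scene.generators):
        timing = None if scene.timings is None else scene.timings[g]
        for k in range(scene.num_rows):
            trace, rec = generate_trace(gen, rng)
            if timing is None:
                z0 = int(rng.integers(z_lo, z_hi + 1))
            else:
                z0 = int(timing[k % len(timing)])
            truncated = False
            if z0 + len(trace) - 1 > z_hi:
                trace = trace[: z_hi - z0 + 1]
                truncated = True
            rows.append(
                {
                    "event_id": eid,
                    "group": f"group_{g + 1}",
                    "z0": z0,
                    "z1": z0 + len(trace) - 1,
                    "dz": len(trace),
                    "trace": trace,
                    "truncated": truncated,
                    **{k_: v for k_, v in rec.items() if k_ != "length"},
                }
            )
            eid += 1
    return pd.DataFrame(rows)


def two_group_scene(seed: int = 0, num_rows: int = 100) -> SceneParams:
    """The two-condition benchmark: fixed 50-frame traces whose groups differ
    in decay rate and plateau duration (b=1/plateau 1 vs b=2/plateau 6), with
    group 1 at random frames and group 2 locked to stimuli every 1000 frames."""
    group_1 = SignalParams(
        trace_length=(50, 50), noise_amplitude=0.001,
        parameter_fluctuations=0.01, b=1.0, plateau_duration=1,
    )
    group_2 = SignalParams(
        trace_length=(50, 50), noise_amplitude=0.001,
        parameter_fluctuations=0.01, b=2.0, plateau_duration=6,
    )
    z_range = (0, 10000)
    timings = [None, list(range(0, z_range[1], 1000))]
    return SceneParams(
        num_rows=num_rows, z_range=z_range, generators=[group_1, group_2],
        timings=timings, seed=seed,
    )


def detection_benchmark_scene(seed: int = 0, num_rows: int = 30) -> SceneParams:
    """Rendered-video benchmark: well-separated transients at peak-pixel
    SNR 5 (amplitude 5 over unit pixel noise) on a dim uniform background."""
    gen = SignalParams(
        trace_length=(20, 40), b=0.3, plateau_duration=5, amplitude=5.0,
        rise_time=3, onset_jitter=False,
    )
    return SceneParams(
        num_rows=num_rows, z_range=(0, 450), generators=[gen],
        video_shape=(500, 128, 128), blob_radius=2.0, background_level=5.0,
        pixel_noise=1.0, min_separation=12.0, seed=seed,
    )


def _place_centers(
    n: int,
    shape: tuple[int, int],
    min_sep: float,
    margin: float,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    centers: list[tuple[float, float]] = []
    h, w = shape
    for _ in range(n):
        for _attempt in range(max_tries):
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
                centers.append((y, x))
                break
        else:
            raise PlacementError(
                f"could not place {n} events with separation {min_sep:.1f} in a "
                f"{h}x{w} frame; use a larger frame or fewer events"
            )
    return np.asarray(centers)


def render_video(
    table: pd.DataFrame, scene: SceneParams
) -> tuple[np.ndarray, np.ndarray]:
    """Render an event table onto a noisy video; returns (video, label volume).

    Each event becomes an isotropic Gaussian blob (sigma = ``blob_radius``)
    scaled by its trace per frame, added onto ``background_level`` plus pixel
    noise.  The label volume marks voxels where an event's noiseless
    contribution exceeds ``SUPPORT_FRACTION`` of its peak (later events win
    ties by overwriting, which separated scenes never exercise).
    """
    T, H, W = scene.video_shape
    rng = np.random.default_rng(scene.seed + 1)
    sep = scene.min_separation if scene.min_separation is not None else 4 * scene.blob_radius
    margin = 3 * scene.blob_radius
    centers = _place_centers(len(table), (H, W), sep, margin, rng)

    video = np.full((T, H, W), float(scene.background_level))
    labels = np.zeros((T, H, W), dtype=np.int32)
    yy, xx = np.mgrid[0:H, 0:W]
    sig2 = scene.blob_radius**2
    for (cy, cx), (_, row) in zip(centers, table.iterrows()):
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig2))
        trace = np.asarray(row["trace"])
        peak = trace.max() * blob.max()
        z0 = int(row["z0"])
        for t_local, value in enumerate(trace):
            t = z0 + t_local
            if not (0 <= t < T):
                continue
            video[t] += value * blob
            support = value * blob >= SUPPORT_FRACTION * peak
            labels[t][support] = int(row["event_id"]) + 1
    if scene.pixel_noise > 0:
        video += rng.normal(0.0, scene.pixel_noise, video.shape)
    return video, labels


def _voxel_sets(labels: np.ndarray) -> dict[int, np.ndarray]:
    """Map label id -> flat voxel indices (labels > 0)."""
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    order = np.argsort(flat[nz], kind="stable")
    nz = nz[order]
    vals = flat[nz]
    out = {}
    for v, start, count in zip(*np.unique(vals, return_index=True, return_counts=True)):
        out[int(v)] = nz[start : start + count]
    return out


def match_labels_greedy(
    gt_labels: np.ndarray,
    det_labels: np.ndarray,
    iou_threshold: float = 0.3,
) -> list[dict]:
    """Greedy one-to-one matching of label volumes by descending voxel IoU."""
    gt_sets = _voxel_sets(gt_labels)
    det_sets = _voxel_sets(det_labels)
    pairs = []
    for g, gv in gt_sets.items():
        gs = set(gv.tolist())
        for d, dv in det_sets.items():
            inter = len(gs.intersection(dv.tolist()))
            if inter == 0:
                continue
            iou = inter / (len(gv) + len(dv) - inter)
            if iou >= iou_threshold:
                pairs.append((iou, g, d))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_g: set[int] = set()
    used_d: set[int] = set()
    matches = []
    for iou, g, d in pairs:
        if g in used_g or d in used_d:
            continue
        used_g.add(g)
        used_d.add(d)
        matches.append({"gt": g, "det": d, "iou": iou})
    return matches


def match_labels_optimal(
    gt_labels: np.ndarray, det_labels: np.ndarray, iou_threshold: float = 0.3
) -> list[dict]:
    """Optimal assignment (Hungarian) on the IoU matrix; test oracle for greedy."""
    gt_sets = _voxel_sets(gt_labels)
    det_sets = _voxel_sets(det_labels)
    g_ids = sorted(gt_sets)
    d_ids = sorted(det_sets)
    iou = np.zeros((len(g_ids), len(d_ids)))
    for i, g in enumerate(g_ids):
        gs = set(gt_sets[g].tolist())
        for j, d in enumerate(d_ids):
            inter = len(gs.intersection(det_sets[d].tolist()))
            if inter:
                iou[i, j] = inter / (len(gt_sets[g]) + len(det_sets[d]) - inter)
    ri, ci = linear_sum_assignment(-iou)
    return [
        {"gt": g_ids[i], "det": d_ids[j], "iou": iou[i, j]}
        for i, j in zip(ri, ci)
        if iou[i, j] >= iou_threshold
    ]


def evaluate_detection(
    ground_truth_labels: np.ndarray,
    detected,
    length_filter: tuple[int, int] = (5, 1000),
    iou_threshold: float = 0.3,
) -> dict:
    """Compare detected events against ground truth (benchmark report).

    ``detected`` is an :class:`~astroevents.detection.EventCollection` (its
    label volume and event durations are used).  Detected events with duration
    outside ``length_filter`` (inclusive) are dropped before matching.
    """
    det_labels = detected.label_volume()
    if det_labels.shape != ground_truth_labels.shape:
        raise ValidationError("label volumes must share the video shape")
    events = detected.events
    lo, hi = length_filter
    keep = set(events.loc[(events["dz"] >= lo) & (events["dz"] <= hi), "event_id"])
    det_labels = np.where(np.isin(det_labels, list(keep)), det_labels, 0)
    matches = match_labels_greedy(ground_truth_labels, det_labels, iou_threshold)
    n_generated = int(len(np.unique(ground_truth_labels)) - 1)
    return {
        "generated": n_generated,
        "detected": int(len(keep)),
        "matched": len(matches),
        "matches": matches,
        "recall": len(matches) / n_generated if n_generated else float("nan"),
    }
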