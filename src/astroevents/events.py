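"""Post-detection quality control on event tables.

An event table is a pandas DataFrame with one row per event, the scalar
attributes produced by detection (``z0``, ``dz``, ``v_area``, …), a ragged
``trace`` column (1D numpy arrays of per-event length) and, when several
experiments are merged, a ``group`` column.  Applied operations are recorded
in ``table.attrs["provenance"]``.

Normalization is instruction-driven: an ordered list of steps, each an
elementwise operation (``subtract``, ``divide``, ``diff``) with a statistic
mode (``mean``, ``median``, ``std``, ``min``, ``max``, ``first``) computed
either per event or pooled over the whole population (``population_wide``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .detection import EventCollection
from .errors import NormalizationError, ValidationError
from .io_store import VideoStore

logger = logging.getLogger(__name__)

_MODES = {
    "mean": np.mean,
    "median": np.median,
    "std": np.std,
    "min": np.min,
    "max": np.max,
    "first": lambda a: np.asarray(a).ravel()[0],
}


def _record(table: pd.DataFrame, entry: str) -> None:
    table.attrs.setdefault("provenance", [])
    table.attrs["provenance"] = list(table.attrs["provenance"]) + [entry]


def filter_events(
    table: pd.DataFrame, column_ranges: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Keep rows with ``low <= value <= high`` for every listed column."""
    for column in column_ranges:
        if column not in table.columns:
            raise ValidationError(f"unknown filter column {column!r}")
        if not np.issubdtype(np.asarray(table[column]).dtype, np.number):
            raise ValidationError(f"filter column {column!r} is not numeric")
    keep = pd.Series(True, index=table.index)
    for column, (low, high) in column_ranges.items():
        keep &= (table[column] >= low) & (table[column] <= high)
    out = table.loc[keep].copy()
    out.attrs = dict(table.attrs)
    if column_ranges:
        _record(out, f"filter_events({column_ranges})")
    return out


@dataclass
class NormalizationStep:
    operation: str  # subtract | divide | diff
    mode: Optional[str] = None  # unused for diff
    population_wide: bool = False

    def __post_init__(self) -> None:
        if self.operation not in ("subtract", "divide", "diff"):
            raise ValidationError(f"unknown operation {self.operation!r}")
        if self.operation == "diff":
            if self.mode is not None:
                raise ValidationError("diff takes no mode")
        elif self.mode not in _MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass
class NormalizationPlan:
    """Ordered normalization steps, applied strictly in listed order."""

    steps: Sequence[NormalizationStep] = field(default_factory=list)

    @classmethod
    def from_instructions(cls, instructions: dict) -> "NormalizationPlan":
        """Build from an instruction map ``{0: [op, kwargs], 1: ...}``."""
        steps = []
        for key in sorted(instructions):
            op, kwargs = instructions[key]
            steps.append(
                NormalizationStep(
                    operation=op,
                    mode=kwargs.get("mode"),
                    population_wide=bool(kwargs.get("population_wide", False)),
                )
            )
        return cls(steps)


def _apply_step(
    traces: list[np.ndarray], step: NormalizationStep, index: int
) -> list[np.ndarray]:
    if step.operation == "diff":
        # first-order difference, length kept by prepending 0
        return [np.concatenate([[0.0], np.diff(tr)]) for tr in traces]
    stat_fn = _MODES[step.mode]
    if step.population_wide:
        pooled = np.concatenate([np.ravel(tr) for tr in traces])
        stats = [float(stat_fn(pooled))] * len(traces)
    else:
        stats = [float(stat_fn(tr)) for tr in traces]
    if step.operation == "subtract":
        return [tr - s for tr, s in zip(traces, stats)]
    for s in stats:
        if s == 0 or not np.isfinite(s):
            raise NormalizationError(
                f"step {index} (divide, mode={step.mode!r}): zero or undefined "
                "denominator"
            )
    return [tr / s for tr, s in zip(traces, stats)]


def normalize_events(
    table: pd.DataFrame, plan: Union[NormalizationPlan, dict]
) -> pd.DataFrame:
    """Apply a normalization plan to the ``trace`` column."""
    if isinstance(plan, dict):
        plan = NormalizationPlan.from_instructions(plan)
    traces = [np.asarray(tr, dtype=float) for tr in table["trace"]]
    for i, step in enumerate(plan.steps):
        traces = _apply_step(traces, step, i)
    out = table.copy()
    out["trace"] = traces
    out.attrs = dict(table.attrs)
    out.attrs["normalized"] = True
    if plan.steps:
        _record(out, f"normalize_events({[s.operation for s in plan.steps]})")
    return out


def _footprint_mask(
    collection: EventCollection, row: pd.Series, use_footprint: bool
) -> np.ndarray:
    """Bounding-box-local sampling mask for event extension.

    ``use_footprint`` selects the time-max projection; otherwise the union of
    the first and last active frames' pixels is used.
    """
    if use_footprint:
        return collection.footprint(int(row["event_id"]))
    labels = collection.label_volume()
    eid = int(row["event_id"])
    slc = (
        slice(int(row["z0"]), int(row["z1"]) + 1),
        slice(int(row["y0"]), int(row["y1"])),
        slice(int(row["x0"]), int(row["x1"])),
    )
    sub = labels[slc] == eid
    return sub[0] | sub[-1]


def extend_events(
    table: pd.DataFrame,
    collection: EventCollection,
    video: Union[VideoStore, np.ndarray],
    extend: Union[int, tuple[int, int]] = 0,
    use_footprint: bool = True,
    enforce_length: Optional[int] = None,
) -> pd.DataFrame:
    """Regrow traces into adjacent frames and optionally fix their length.

    ``extend`` is symmetric when an int, ``(pre, post)`` when a tuple and
    spans the whole video when ``-1``.  Traces are re-sampled from the video
    over the event's footprint.  With ``enforce_length`` the trace is padded
    or truncated symmetrically around its peak; ties break to the earlier
    frame and padding samples the video (edge frames replicate at the video
    boundary).
    """
    if enforce_length is not None and enforce_length < 1:
        raise ValidationError("enforce_length must be >= 1")
    if isinstance(video, np.ndarray):
        T = video.shape[0]
        frame_block = lambda lo, hi: video[lo:hi]  # noqa: E731
    else:
        T = video.shape[0]
        frame_block = lambda lo, hi: video.read_window((lo, hi))  # noqa: E731

    if extend == -1:
        pre = post = T
    elif isinstance(extend, tuple):
        pre, post = extend
    else:
        pre = post = int(extend)
    if pre < 0 or post < 0:
        raise ValidationError("extend must be >= 0 (or -1 for the full video)")

    rows = []
    for _, row in table.iterrows():
        mask = _footprint_mask(collection, row, use_footprint)
        y0, y1 = int(row["y0"]), int(row["y1"])
        x0, x1 = int(row["x0"]), int(row["x1"])
        z0 = max(0, int(row["z0"]) - pre)
        z1 = min(T - 1, int(row["z1"]) + post)
        block = np.asarray(frame_block(z0, z1 + 1), dtype=float)[:, y0:y1, x0:x1]
        trace = block[:, mask].mean(axis=1)

        if enforce_length is not None:
            z0, z1, trace = _enforce_length(
                trace, z0, enforce_length, T,
                lambda lo, hi: np.asarray(frame_block(lo, hi), dtype=float)[
                    :, y0:y1, x0:x1
                ][:, mask].mean(axis=1),
            )
        new = row.copy()
        new["z0"], new["z1"], new["dz"] = z0, z1, z1 - z0 + 1
        new["trace"] = trace
        rows.append(new)
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.attrs = dict(table.attrs)
    _record(
        out,
        f"extend_events(extend={extend}, use_footprint={use_footprint}, "
        f"enforce_length={enforce_length})",
    )
    return out


def _enforce_length(trace, z0, L, T, sampler):
    """Center a trace on its peak at exactly L frames (ties to earlier frame)."""
    peak = int(np.argmax(trace))  # argmax takes the earliest maximum
    center = z0 + peak
    lo = center - (L - 1) // 2
    hi = lo + L  # half-open
    clip_lo, clip_hi = max(0, lo), min(T, hi)
    out = np.asarray(sampler(clip_lo, clip_hi), dtype=float)
    if clip_lo > lo:  # pad at the start by edge replication
        out = np.concatenate([np.full(clip_lo - lo, out[0]), out])
    if hi > clip_hi:
        out = np.concatenate([out, np.full(hi - clip_hi, out[-1])])
    return max(0, lo), min(T - 1, hi - 1), out


def merge_experiments(
    collections: Sequence[EventCollection],
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Concatenate several collections into one table with re-keyed ids."""
    if len(collections) == 0:
        raise ValidationError("need at least one collection")
    if groups is not None:
        if len(groups) != len(collections):
            raise ValidationError("groups length must match collections")
        if any(not g for g in groups):
            raise ValidationError("group labels must be non-empty")
    paths = [str(c.directory) for c in collections]
    if len(set(paths)) < len(paths):
        logger.warning("duplicate source paths in merge: %s", paths)
    parts = []
    for i, coll in enumerate(collections):
        part = coll.to_table()
        part["event_id"] = [f"{i}/{eid}" for eid in part["event_id"]]
        if groups is not None:
            part["group"] = groups[i]
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    out.attrs["provenance"] = paths
    return out
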