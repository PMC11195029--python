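"""Experiment-level analysis of event collections.

Pairwise event dissimilarities (Pearson-correlation distance or dynamic time
warping), agglomerative clustering with per-cluster consensus traces
(barycenters), condition classification, clustering-vs-condition scoring,
and coincidence detection against independent stimulus timings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    adjusted_rand_score,
    confusion_matrix,
    precision_recall_fscore_support,
    r2_score,
)
from sklearn.model_selection import train_test_split

from .errors import (
    DegenerateLabelError,
    UndefinedCorrelationError,
    ValidationError,
)

_CLASSIFIERS = {
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed),
    "logistic": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
}


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------
@njit(fastmath=False)
def _dtw_dp(x, y, window):  # pragma: no cover - exercised via wrapper
    n, m = len(x), len(y)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        if window < 0:
            j_lo, j_hi = 1, m
        else:
            j_lo = max(1, i - window)
            j_hi = min(m, i + window)
        for j in range(j_lo, j_hi + 1):
            cost = (x[i - 1] - y[j - 1]) ** 2
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost + best
    return np.sqrt(D[n, m])


def dtw_distance(
    x: np.ndarray, y: np.ndarray, window: Optional[int] = None
) -> float:
    """Classic DTW: sqrt of the minimal summed squared difference along a
    monotone alignment path, optionally constrained to a Sakoe–Chiba band."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    w = -1 if window is None else max(int(window), abs(len(x) - len(y)))
    return float(_dtw_dp(x, y, w))


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - r, truncating the longer trace to the shorter (start-aligned)."""
    n = min(len(x), len(y))
    x, y = np.asarray(x[:n], float), np.asarray(y[:n], float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError(
            "Pearson distance undefined for a zero-variance trace"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return min(max(1.0 - r, 0.0), 2.0)


@dataclass
class DistanceMatrix:
    values: np.ndarray
    method: str
    index: list = field(default_factory=list)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def pairwise_distance(
    traces: Sequence[np.ndarray],
    method: str = "dtw",
    dtw_window: Optional[int] = None,
    index: Optional[Sequence] = None,
) -> DistanceMatrix:
    """Symmetric zero-diagonal pairwise dissimilarity matrix."""
    n = len(traces)
    if n < 2:
        raise ValidationError("need at least two traces")
    traces = [np.asarray(t, dtype=float) for t in traces]
    D = np.zeros((n, n))
    if method == "dtw":
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = dtw_distance(traces[i], traces[j], dtw_window)
    elif method == "pearson":
        lengths = {len(t) for t in traces}
        if len(lengths) == 1:
            # fast path: one corrcoef call on the trace matrix
            X = np.asarray(traces)
            if np.any(X.std(axis=1) == 0):
                raise UndefinedCorrelationError(
                    "Pearson distance undefined for a zero-variance trace"
                )
            D = np.clip(1.0 - np.corrcoef(X), 0.0, 2.0)
            np.fill_diagonal(D, 0.0)
        else:
            for i in range(n):
                for j in range(i + 1, n):
                    D[i, j] = D[j, i] = pearson_distance(traces[i], traces[j])
    else:
        raise ValidationError(f"method must be 'pearson' or 'dtw', got {method!r}")
    return DistanceMatrix(
        values=D, method=method, index=list(index) if index is not None else list(range(n))
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------
@dataclass
class ClusterResult:
    cluster_lookup: dict
    barycenters: dict
    criterion: str
    cutoff: float
    labels: np.ndarray = field(default=None)


def _resample(trace: np.ndarray, length: int) -> np.ndarray:
    if len(trace) == length:
        return np.asarray(trace, float)
    xp = np.linspace(0, 1, len(trace))
    return np.interp(np.linspace(0, 1, length), xp, trace)


@njit(fastmath=False)
def _dtw_path(x, y):  # pragma: no cover - exercised via DBA
    n, m = len(x), len(y)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = (x[i - 1] - y[j - 1]) ** 2
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost + best
    # traceback
    path = np.empty((n + m, 2), dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 and j > 0:
        path[k, 0] = i - 1
        path[k, 1] = j - 1
        k += 1
        diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
        if diag <= up and diag <= left:
            i, j = i - 1, j - 1
        elif up <= left:
            i -= 1
        else:
            j -= 1
    return path[:k][::-1]


def dtw_barycenter(
    traces: Sequence[np.ndarray], iterations: int = 10
) -> np.ndarray:
    """DTW barycenter averaging: iterative alignment to a mean-initialised
    consensus of the members' median length."""
    traces = [np.asarray(t, float) for t in traces]
    length = int(np.median([len(t) for t in traces]))
    center = np.mean([_resample(t, length) for t in traces], axis=0)
    for _ in range(iterations):
        sums = np.zeros(length)
        counts = np.zeros(length)
        for tr in traces:
            path = _dtw_path(center, tr)
            for ci, ti in path:
                sums[ci] += tr[ti]
                counts[ci] += 1
        new_center = sums / np.maximum(counts, 1)
        if np.allclose(new_center, center):
            break
        center = new_center
    return center


def cluster_linkage(
    dist: DistanceMatrix,
    criterion: str = "maxclust",
    cutoff: float = 2,
    linkage_method: str = "average",
    traces: Optional[Sequence[np.ndarray]] = None,
) -> ClusterResult:
    """Agglomerative clustering on a precomputed distance matrix.

    ``criterion='maxclust'`` cuts the tree into at most ``cutoff`` flat
    clusters; ``criterion='distance'`` cuts at the given cophenetic height.
    When member traces are supplied, per-cluster barycenters are computed:
    pointwise means of resampled members for Pearson distances, DTW
    barycenter averaging for DTW.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    if criterion not in ("maxclust", "distance"):
        raise ValidationError("criterion must be 'maxclust' or 'distance'")
    Z = linkage(dist.condensed(), method=linkage_method)
    labels = fcluster(Z, t=cutoff, criterion=criterion)
    lookup = {eid: int(c) for eid, c in zip(dist.index, labels)}
    barycenters = {}
    if traces is not None:
        for c in np.unique(labels):
            members = [np.asarray(traces[i], float) for i in np.where(labels == c)[0]]
            if dist.method == "dtw":
                barycenters[int(c)] = dtw_barycenter(members)
            else:
                length = int(np.median([len(m) for m in members]))
                barycenters[int(c)] = np.mean(
                    [_resample(m, length) for m in members], axis=0
                )
    return ClusterResult(
        cluster_lookup=lookup,
        barycenters=barycenters,
        criterion=criterion,
        cutoff=cutoff,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------
@dataclass
class ScoreReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    classes: list
    agreement_index: Optional[float] = None  # adjusted Rand (clustering only)


def _score_labels(y_true, y_pred, classes) -> ScoreReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    acc = float(np.mean(y_true == y_pred))
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    return ScoreReport(
        accuracy=acc, precision=float(p), recall=float(r), f1=float(f1),
        confusion=cm, classes=list(classes),
    )


def match_cluster_scores(
    true_labels: Sequence, predicted_clusters: Sequence
) -> ScoreReport:
    """Optimally match cluster ids to condition labels, then score.

    The one-to-one matching maximises accuracy over all assignments
    (Hungarian algorithm on the contingency table); clusters left unmatched
    (more clusters than labels, or vice versa) count as errors.  The adjusted
    Rand index is reported alongside as a permutation-invariant agreement
    measure.
    """
    true_labels = np.asarray(true_labels)
    predicted_clusters = np.asarray(predicted_clusters)
    if len(true_labels) != len(predicted_clusters):
        raise ValidationError("label vectors must have equal length")
    classes = sorted(set(true_labels.tolist()))
    clusters = sorted(set(predicted_clusters.tolist()))
    contingency = np.zeros((len(clusters), len(classes)))
    for i, c in enumerate(clusters):
        for j, g in enumerate(classes):
            contingency[i, j] = np.sum((predicted_clusters == c) & (true_labels == g))
    ri, ci = linear_sum_assignment(-contingency)
    mapping = {clusters[i]: classes[j] for i, j in zip(ri, ci)}
    # scoring happens on stringified labels; a reserved token marks clusters
    # left unmatched so they never agree with any class
    unmatched = "__unmatched__"
    while any(str(c) == unmatched for c in classes):
        unmatched += "_"
    y_pred = np.array(
        [str(mapping[c]) if c in mapping else unmatched for c in predicted_clusters]
    )
    y_true = np.array([str(t) for t in true_labels])
    report = _score_labels(y_true, y_pred, [str(c) for c in classes])
    report.agreement_index = float(
        adjusted_rand_score(true_labels, predicted_clusters)
    )
    return report


# ---------------------------------------------------------------------------
# classification / coincidence
# ---------------------------------------------------------------------------
def train_discriminator(
    embedding: np.ndarray,
    categories: Sequence,
    classifier_name: str = "random_forest",
    split: float = 0.2,
    seed: int = 0,
):
    """Train a condition classifier on the embedding; score held-out data."""
    embedding = np.asarray(embedding)
    categories = np.asarray(categories)
    classes, counts = np.unique(categories, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValidationError("need >= 2 categories with >= 2 members each")
    if classifier_name not in _CLASSIFIERS:
        raise ValidationError(f"unknown classifier {classifier_name!r}")
    X_train, X_test, y_train, y_test = train_test_split(
        embedding, categories, test_size=split, stratify=categories,
        random_state=seed,
    )
    model = _CLASSIFIERS[classifier_name](seed)
    model.fit(X_train, y_train)
    report = _score_labels(y_test, model.predict(X_test), list(classes))
    return model, report


def default_coincidence_window(incidences: Sequence[int]) -> int:
    """Half the median inter-incidence gap, capped at 100 frames."""
    gaps = np.diff(sorted(incidences))
    if len(gaps) == 0:
        return 100
    return int(min(np.median(gaps) // 2, 100))


def coincidence_labels(
    z0: Sequence[int], incidences: Sequence[int], window: int
) -> np.ndarray:
    """True where an event's onset falls in ``[t, t + window]`` of a stimulus."""
    z0 = np.asarray(z0)
    out = np.zeros(len(z0), dtype=bool)
    for t in incidences:
        out |= (z0 >= t) & (z0 <= t + window)
    return out


def predict_coincidence(
    events_table: pd.DataFrame,
    incidences: Sequence[int],
    embedding: np.ndarray,
    window: Optional[int] = None,
    binary: bool = True,
    seed: int = 0,
):
    """Classify, from the embedding alone, whether each event coincides with
    a stimulus; returns (labels, ScoreReport on held-out data)."""
    incidences = sorted(incidences)
    if window is None:
        window = default_coincidence_window(incidences)
    labels = coincidence_labels(events_table["z0"], incidences, window)
    if labels.all() or not labels.any():
        raise DegenerateLabelError(
            "all events fall on one side of the coincidence window"
        )
    target = labels if binary else _nearest_incidence_index(
        events_table["z0"], incidences, window
    )
    _, report = train_discriminator(
        embedding, target.astype(str), classifier_name="random_forest",
        split=0.2, seed=seed,
    )
    return labels, report


def _nearest_incidence_index(z0, incidences, window):
    z0 = np.asarray(z0)
    out = np.full(len(z0), -1)
    for k, t in enumerate(incidences):
        hit = (z0 >= t) & (z0 <= t + window)
        out[hit] = k
    return out


def match_incidence_offset(
    z0: Sequence[int], incidences: Sequence[int]
) -> np.ndarray:
    """Offset of each onset from the nearest incidence at or before it."""
    incidences = np.asarray(sorted(incidences))
    z0 = np.asarray(z0)
    idx = np.searchsorted(incidences, z0, side="right") - 1
    if np.any(idx < 0):
        raise ValidationError("every coinciding event needs a preceding incidence")
    return z0 - incidences[idx]


def predict_incidence_location(
    coinciding_events: pd.DataFrame,
    incidences: Sequence[int],
    embedding: np.ndarray,
    seed: int = 0,
) -> dict:
    """Regress the onset-to-stimulus offset from the embedding.

    Returns held-out RMSE and R² of a random-forest regression predicting
    ``z0 - t_matched_incidence``.
    """
    if len(coinciding_events) < 10:
        raise ValidationError("need at least 10 coinciding events")
    target = match_incidence_offset(coinciding_events["z0"], incidences)
    X_train, X_test, y_train, y_test = train_test_split(
        np.asarray(embedding), target, test_size=0.2, random_state=seed
    )
    model = RandomForestRegressor(random_state=seed)
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    rmse = float(np.sqrt(np.mean((pred - y_test) ** 2)))
    return {"rmse": rmse, "r2": float(r2_score(y_test, pred)), "n_test": len(y_test)}


# ---------------------------------------------------------------------------
def run_replicates(fn, seeds: Sequence[int]) -> dict:
    """Run a seeded analysis several times; report per-seed, min and median."""
    values = [fn(seed) for seed in seeds]
    return {
        "values": values,
        "min": float(np.min(values)),
        "median": float(np.median(values)),
    }
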