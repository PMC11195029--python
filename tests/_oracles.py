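"""Independent reference implementations used as test oracles.

Deliberately naive (exhaustive enumeration, BFS flood fill, brute-force
scans) and written without reference to the package's implementation paths.
"""

from collections import deque
from itertools import permutations

import numpy as np


def brute_force_peak_extents(trace, prominence, rel_height, min_width=1.0):
    """From-scratch prominence/extent computation over all strict local maxima.

    A peak's bases are the minima between it and the nearest higher sample on
    each side (or the signal edge); prominence is the height above the higher
    base; the extent is where the signal crosses
    ``height - rel_height * prominence`` between the bases (interpolated,
    rounded outward to whole frames).  Peaks narrower than ``min_width`` at
    half prominence are discarded.
    """
    n = len(trace)
    extents = []
    for i in range(1, n - 1):
        if not (trace[i] > trace[i - 1] and trace[i] > trace[i + 1]):
            continue
        higher_left = [j for j in range(i) if trace[j] > trace[i]]
        lo = max(higher_left) if higher_left else 0
        left_base = lo + int(np.argmin(trace[lo : i + 1]))
        higher_right = [j for j in range(i + 1, n) if trace[j] > trace[i]]
        hi = min(higher_right) if higher_right else n - 1
        right_base = i + int(np.argmin(trace[i : hi + 1]))
        prom = trace[i] - max(trace[left_base], trace[right_base])
        if prom < prominence:
            continue

        def crossings(level):
            a = i
            while a > left_base and trace[a - 1] >= level:
                a -= 1
            if a > left_base and trace[a] > level:
                frac = (trace[a] - level) / (trace[a] - trace[a - 1])
                a_pos = a - frac
            else:
                a_pos = float(a)
            b = i
            while b < right_base and trace[b + 1] >= level:
                b += 1
            if b < right_base and trace[b] > level:
                frac = (trace[b] - level) / (trace[b] - trace[b + 1])
                b_pos = b + frac
            else:
                b_pos = float(b)
            return a_pos, b_pos

        half_lo, half_hi = crossings(trace[i] - 0.5 * prom)
        if half_hi - half_lo < min_width:
            continue
        a_pos, b_pos = crossings(trace[i] - rel_height * prom)
        extents.append((int(np.floor(a_pos)), int(np.ceil(b_pos))))
    return extents


_NEIGHBOURS = {
    6: [(dz, dy, dx)
        for dz, dy, dx in [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0),
                           (0, 0, -1), (0, 0, 1)]],
    18: [(dz, dy, dx)
         for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if 0 < abs(dz) + abs(dy) + abs(dx) <= 2],
    26: [(dz, dy, dx)
         for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def bfs_label(mask, connectivity=26):
    """Flood-fill 3D connected-component labelling (independent of skimage)."""
    offsets = _NEIGHBOURS[connectivity]
    T, H, W = mask.shape
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        labels[start] = current
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < T and 0 <= ny < H and 0 <= nx < W:
                    if mask[nz, ny, nx] and not labels[nz, ny, nx]:
                        labels[nz, ny, nx] = current
                        queue.append((nz, ny, nx))
    return labels


def partitions_equivalent(a, b) -> bool:
    """Two labelings induce the same partition of the foreground voxels."""
    if not np.array_equal(a > 0, b > 0):
        return False
    pairs = set(zip(a[a > 0].ravel(), b[b > 0].ravel()))
    a_ids = [p[0] for p in pairs]
    b_ids = [p[1] for p in pairs]
    return len(pairs) == len(set(a_ids)) == len(set(b_ids))


def dtw_brute_force(x, y):
    """Exhaustive enumeration of all monotone alignment paths (tiny inputs)."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, cost):
        cost += (x[i] - y[j]) ** 2
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return float(np.sqrt(best[0]))


def matched_accuracy_brute_force(true_labels, predicted_clusters):
    """Best accuracy over all injective cluster-to-label assignments."""
    true_labels = np.asarray(true_labels)
    predicted_clusters = np.asarray(predicted_clusters)
    classes = sorted(set(true_labels.tolist()))
    clusters = sorted(set(predicted_clusters.tolist()))
    best = 0
    if len(clusters) <= len(classes):
        for perm in permutations(classes, len(clusters)):
            mapping = dict(zip(clusters, perm))
            hits = sum(
                mapping[c] == t for c, t in zip(predicted_clusters, true_labels)
            )
            best = max(best, hits)
    else:
        for perm in permutations(clusters, len(classes)):
            mapping = {c: t for c, t in zip(perm, classes)}
            hits = sum(
                mapping.get(c) == t
                for c, t in zip(predicted_clusters, true_labels)
            )
            best = max(best, hits)
    return best / len(true_labels)
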