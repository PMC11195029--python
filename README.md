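# astroevents

Detection, embedding and analysis of astrocytic calcium events in
fluorescence video.

Astrocytes signal through localized, transient rises in intracellular
calcium that — unlike neuronal somatic activity — are not tied to fixed cell
bodies: events appear, spread and vanish anywhere in the field of view, and
their durations span an order of magnitude. `astroevents` treats a recording
as a 3D stack (time × height × width) and works event-first: it finds active
*voxels*, groups them into spatiotemporal events, and analyzes the resulting
variable-length event traces. It is aimed at neuroscientists and
bioinformaticians who process calcium-indicator (e.g. GCaMP6f) recordings of
astrocytes and want a scriptable, end-to-end path from raw video to
experiment-level statistics.

## What it does

1. **Ingest** (`io_store`) — convert TIFF / AVI / HDF5 videos into chunked
   HDF5 stores with lazy window reads; de-interleave multi-channel
   recordings; subtract a static camera background.
2. **Background correction** (`background`) — mask per-pixel fluorescence
   peaks, fit a radial-basis-function interpolant to the remaining samples
   over (t, y, x), and subtract the smooth background as ΔF or ΔF/F.
3. **Detection** (`detection`) — Gaussian smoothing; dual thresholding
   (a per-frame automatic intensity cutoff guarded by the active/inactive
   mean-fluorescence ratio, and per-pixel temporal peak prominence);
   morphological cleanup; 3D connected-component labelling. Each event gets
   a bounding box, footprint, per-frame mean trace and SNR, stored in a
   `.roi` directory.
4. **Quality control** (`events`) — attribute-range filtering, event
   extension into adjacent frames, fixed-length enforcement, and
   instruction-driven normalization (ordered subtract / divide / diff steps,
   per event or population-wide).
5. **Embedding** (`embedding`) — fixed-length vectors from variable-length
   traces: a frozen 14-feature summary, a 1D-convolutional autoencoder
   (fixed length), or a GRU autoencoder (ragged input, masked loss).
6. **Analysis** (`analysis`) — pairwise distances (Pearson `1 − r` or
   dynamic time warping), hierarchical clustering with per-cluster consensus
   traces (DTW barycenter averaging), condition classification,
   cluster-to-condition matched scoring, and coincidence detection /
   stimulus-timing regression against independent event timings.
7. **Synthetic data** (`synthetic`) — parametric calcium transients
   (rise, plateau, exponential decay `e^{-bt}`, per-event parameter jitter),
   labelled event tables with optional stimulus-locked timing, and rendered
   noisy videos with per-voxel ground truth, so every stage is testable
   without any download.

The core similarity used for clustering is classic DTW: for traces x, y the
dissimilarity is

    DTW(x, y) = sqrt( min_π Σ_{(i,j)∈π} (x_i − y_j)² )

over monotone alignment paths π (optionally banded), computed by dynamic
programming; cluster consensus shapes are DTW barycenters (iterative
alignment averaging).

## Worked example

The benchmark experiment builds two groups of 100 synthetic 50-frame event
traces that differ in kinetics — group 1: decay rate b = 1, plateau
1 frame; group 2: b = 2, plateau 6 frames (noise 0.001, parameter jitter
1%) — with each transient at a random onset inside its window, then asks
three analysis routes to recover the grouping:

```python
from astroevents.synthetic import two_group_scene, generate_event_table
from astroevents.analysis import (pairwise_distance, cluster_linkage,
                                  match_cluster_scores, train_discriminator)
from astroevents.embedding import extract_features

table = generate_event_table(two_group_scene(seed=1))
table = table[~table["truncated"]]          # keep the fixed-length design
traces, groups = list(table["trace"]), list(table["group"])

for method in ("pearson", "dtw"):
    dist = pairwise_distance(traces, method=method)
    clusters = cluster_linkage(dist, criterion="maxclust", cutoff=2)
    score = match_cluster_scores(groups, clusters.labels)
    print(f"{method:8s} matched accuracy: {score.accuracy:.3f}  "
          f"ARI: {score.agreement_index:.3f}")

features, names = extract_features(table)
_, report = train_discriminator(features, groups, seed=1)
print(f"fext+rf  held-out accuracy: {report.accuracy:.3f}")
```

prints

```
pearson  matched accuracy: 0.530  ARI: -0.001
dtw      matched accuracy: 1.000  ARI: 1.000
fext+rf  held-out accuracy: 1.000
```

The numbers tell the scientific story: Pearson correlation compares traces
frame-by-frame, so transients at different onsets decorrelate and the
clustering is at chance (0.5); DTW aligns the transients before comparing
shapes and separates the two kinetic types; a random forest on the
14-feature embedding does the same from summary statistics.

## Command line

A thin CLI wraps the library (`astroevents --help`): `convert-input`,
`subtract-background`, `detect-events`, `summarize-detection`,
`filter-events`, `normalize-events`, `embed`, `cluster`, `discriminate`,
`coincidence`, `simulate`, `evaluate-detection` and `run-pipeline`, all
configurable through a YAML file (`--config`) with flags taking precedence.

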