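# Methods

This note documents the models, algorithms and numerical choices behind
`astroevents`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic benchmarks do and do not
demonstrate.

## Data model

A recording is a 3D array ordered (T frames, H pixels, W pixels); all
coordinates are 0-based, all ranges half-open. A *calcium event* is a
maximal 3D-connected set of active voxels; its *trace* is the per-frame mean
fluorescence over the event's active pixels for the frames it spans, and its
*footprint* is the time-max projection of its voxels. Events are stored in a
`.roi` directory (`events.csv` scalar attributes, `traces.h5` ragged traces,
`footprints.h5` masks, `labels.h5` the full label volume, `config.yaml`
provenance); the layout is human-inspectable and round-trips losslessly.

## Background estimation

The background model assumes that, with transient activity removed,
fluorescence varies smoothly in space and time (uneven illumination,
bleaching, dark current). Per pixel, peaks are detected by prominence
(`prominence`, `wlen`, `distance`, `width`) and their extents at
`rel_height` of the prominence are set to missing. The video is spatially
downscaled (`scale_factor`, default 0.25; bilinear), optionally blurred, and
a scipy `RBFInterpolator` is fitted to the *unmasked* (t, y, x) samples and
evaluated everywhere — masked voxels are predicted, unmasked voxels
re-predicted, which smooths the whole field. Time enters as a third
coordinate with unit spacing scaled by `time_scale` (default 1.0; raise it
to make the background stiffer in time). Defaults: thin-plate-spline kernel
with a degree-1 polynomial tail (scale-free, no epsilon to tune),
50 neighbours, smoothing 0. The degree-1 tail makes the estimate exactly
equivariant under global affine shifts, which the tests assert.

Correction is `dF = F − bg` or `dFF = (F − bg) / max(bg, floor)` with
`floor` defaulting to 1e-6 of the global background maximum to avoid
division blow-ups. Peak masking that removes a pixel's entire trace falls
back to the unmasked trace with a warning rather than failing the fit. No
parametric bleaching model is fitted; the RBF surface is the only model.
Aggressive masking parameters can hallucinate structure (spurious events
after subtraction); rather than auto-tuning, the module surfaces a QC
summary (masked fraction, background curvature) and leaves judgement to the
analyst.

## Event detection

Detection runs on the spatially smoothed stack (per-frame Gaussian,
`sigma` = 1 px, truncated at `radius` = 3 px) but extracts traces from the
un-smoothed input, so trace amplitudes are not biased by the blur.

**Spatial threshold.** For each rolling window of `z_depth` frames, a cutoff
is chosen by scanning the window's intensity quantiles (q = 0.50 … 0.995,
40 steps — deterministic and scale-free). A candidate qualifies when
mean(active)/mean(inactive) ≥ `min_ratio` *and* the inactive mean is
positive; the smallest qualifying cutoff is used, and a window where none
qualifies yields an all-false frame. The positivity guard means a window of
zero-mean noise can never qualify, which is what makes the ratio test a
noise gate on ΔF data. With `min_ratio` = 1 every cutoff qualifies and the
Otsu-style cutoff (maximal between-class variance over the same candidates)
is taken instead. Default `min_ratio` = 1.3.

**Temporal threshold.** Each pixel's series is scanned for peaks with
prominence ≥ `prominence` (default 2, in the units of the corrected video)
and width ≥ `width` (default 3 frames); frames inside each peak's extent at
`rel_height` of the prominence are active. Pixels whose total range is below
the prominence are skipped (a peak's prominence cannot exceed the range),
which makes the scan cheap on quiet pixels. Default `rel_height` = 0.7:
prominence is measured down to the surrounding minima, so at 0.9 the extent
level can sit *below* the baseline mean and extents then grow until a random
noise crossing — event durations become noise-limited rather than
signal-limited. Cutting at 70% of the prominence keeps the rising and
falling shoulders while ending extents near 30% of peak-to-base, consistent
with the 20%-of-peak support rule used for synthetic ground truth.
`wlen` (default 101 frames) bounds the prominence window; it also bounds the
information any single frame's classification depends on, which is what
makes chunked processing exact (below).

**Combination and cleanup.** The two masks are merged by union (default;
either evidence source suffices — the right choice for dim or noisy data) or
intersection (both must agree — tighter event support on clean data).
2D holes of area ≤ `area_threshold` (10 px) are filled per frame — filling
in 2D avoids bridging temporally distinct events — then 3D components with
fewer than `min_size` (20) voxels are removed. Labelling uses full 26-
connectivity by default so diagonal motion does not split events; 6 and 18
are available. `exclude_border` clears a pixel margin in every frame (off by
default; useful against motion-correction edge artifacts — on synthetic
scenes the frame border is where Gaussian-smoothing edge effects concentrate
spurious single-pixel detections).

**SNR.** Per event: peak(trace − baseline)/σ, with baseline the median of
the event's own pixels over the 5 frames before onset (first frame of the
video when the event starts at frame 0) and σ the MAD-based robust scale of
that baseline region (×1.4826). σ = 0 maps to +inf.

**Chunked driver.** `detect()` processes time chunks with `halo` extra
frames (default 100) on each side, keeping only each chunk's centre. Results
are independent of chunk size provided halo ≥ (wlen−1)/2 plus the longest
peak extent; the defaults satisfy this for events up to ~50 frames, and the
acceptance suite asserts bit-identical event tables for chunk sizes 50
and 500. Morphology and labelling run on the assembled full-length mask
(a boolean volume, cheap relative to the video).

## Quality control and normalization

Filtering keeps rows inside inclusive `[low, high]` ranges per column, and
is idempotent and order-independent. Event extension resamples the video
over the event's footprint (time-max mask, or the union of first/last
active frames' pixels when `use_footprint=False` — the per-frame variant is
ambiguous in principle; this union is the frozen choice) across
`[z0 − pre, z1 + post]`, clipped at the video. Fixed-length enforcement
centres on the trace argmax (ties to the earlier frame) and pads by
sampling the video, edge-replicating at the boundaries; it distorts event
shape by construction and is only meant for encoders that require equal
lengths. Normalization applies ordered steps — `subtract`/`divide` with a
statistic (`mean, median, std, min, max, first`) computed per event or over
all samples of all traces pooled (`population_wide`), or `diff` —
first-order differencing that keeps length by prepending 0, so `dz`
bookkeeping survives. Division by a zero or non-finite denominator raises
an error naming the step.

## Embeddings

**Feature extraction** maps any-length traces to a frozen, documented
14-vector: mean, median, std, min, max, range, argmax fraction (peak
position / length), area under the curve per frame, skewness, kurtosis,
Shannon entropy of a 16-bin value histogram (bits; 0 for constant traces),
length, number of local maxima at prominence 0.1×range, and mean absolute
first difference.

**Autoencoders** are implemented on a small in-package reverse-mode autodiff
(numpy; gradients property-tested against central finite differences). The
CNN route (fixed length L, padded to a multiple of 4): conv(1→32, k5, s2) →
conv(32→64, k5, s2) → dense → latent, mirrored with nearest-neighbour
upsampling; ragged input is rejected. The RNN route: a GRU encoder whose
hidden state freezes past each sequence's end (the latent depends only on
real frames), a GRU decoder driven from the latent, and a masked MSE in
which padding provably contributes nothing (the padded-batch loss equals the
pooled per-sequence losses). Early stopping monitors validation loss with
`patience` (default 10) and restores the best checkpoint. Defaults:
latent 16 (the dimensionality is a free choice; 16 is small enough to force
compression of 50-frame traces and is exposed), hidden 32, Adam lr 1e-3,
batch 16, 25 epochs, seeded init. Encoders never re-normalize — that is the
caller's job. Training is single-threaded and deterministic under a seed;
this is slower than a GPU framework but removes a heavyweight dependency
and nondeterminism at the scales this package targets (≤ a few thousand
events).

## Analysis

**Distances.** DTW is the classic dynamic program on squared pointwise
differences (square root of the optimal path cost), with an optional
Sakoe–Chiba band; it is numba-compiled and verified against exhaustive path
enumeration for short traces. Pearson distance is `1 − r`, clipped to
[0, 2]; traces of unequal length are truncated to the shorter, aligned at
the start (the least-invention rule for a correlation between ragged
traces — documented, not hidden), and zero-variance traces raise an error
rather than returning NaN.

**Clustering.** Average-linkage agglomerative clustering on the precomputed
distance matrix (scipy), cut by `maxclust` or cophenetic `distance`.
Barycenters: pointwise means of members resampled to the cluster's median
length for Pearson; DTW barycenter averaging (10 iterations,
mean-initialised, deterministic) for DTW.

**Scoring.** Cluster ids are matched one-to-one to condition labels by the
assignment maximising accuracy (Hungarian algorithm on the contingency
table — equal to exhaustive permutation search, which the tests assert for
≤ 8 clusters); unmatched clusters count as errors. The adjusted Rand index
is reported alongside as a permutation-invariant agreement measure robust to
cluster-count mismatch. Classification uses a stratified 80/20 split and a
seeded random forest (logistic regression available as a baseline), reported
on held-out data with macro precision/recall/F1 and the confusion matrix.

**Coincidence detection.** An event coincides with a stimulus when its onset
falls in `[t, t + window]` for some incidence time t; the default window is
half the median inter-incidence gap, capped at 100 frames. A classifier then
predicts coincidence from the embedding alone. For coinciding events, a
random-forest regression predicts the offset `z0 − t` to the nearest
incidence at or before onset; held-out RMSE and R² are reported. Replicated
analyses report per-seed values plus min and median, since a single split
can flatter or punish a method.

## Synthetic data: what it emulates, and what it does not

The canonical transient is a linear rise over `rise_time` (3) frames to
`amplitude`, a plateau of `plateau_duration` frames, and an exponential
decay `amplitude·e^{−bt}` followed until 1% of peak; each shape parameter is
jittered per event by a factor `1 + ε`, ε ~ N(0, `parameter_fluctuations`),
and Gaussian noise of scale `noise_amplitude × amplitude` is added
per frame. Unless disabled, the transient is placed at a uniform random
onset inside the trace window (with a one-frame margin so the transient is
fully contained). This onset randomness is deliberate and load-bearing: it
emulates event windows that capture transients at arbitrary phase, and it is
exactly what makes frame-wise Pearson correlation uninformative (traces at
different onsets decorrelate) while elastic DTW alignment and
order-insensitive summary features still separate kinetic types. With
aligned onsets every route scores ~1.0 and the benchmark has no content.

The two-condition benchmark (`two_group_scene`) uses the printed study
conditions: 100 events per group, 50-frame windows, noise 0.001,
fluctuations 0.01, group 1 (b = 1, plateau 1) at uniform random frames in
(0, 10000) and group 2 (b = 2, plateau 6) locked to stimuli every 1000
frames. Events whose windows are cut off by the recording end carry a
`truncated` flag; the benchmark analyses drop them to preserve the
fixed-length design (a rare fragment otherwise dominates the DTW dendrogram
through its alignment boundary cost). Scores are reported as the minimum
over three seeded replicates — a lower bound, not an average.

The rendered-video benchmark (`detection_benchmark_scene`) plants 30
transients (b = 0.3, plateau 5, amplitude 5) as Gaussian blobs (σ = 2 px,
centres ≥ 12 px apart) on a uniform background of 5 with unit pixel noise —
peak-pixel SNR 5 — in a 500×128×128 stack. Ground-truth voxels are where an
event's noiseless contribution exceeds 20% of its peak (an exposed
parameter; synthetic support has no single right definition). Matching is
greedy one-to-one by descending voxel IoU at threshold 0.3, checked against
optimal assignment on small instances; detected-but-unmatched events are
reported separately because over-segmentation is the expected failure mode
and is preferable to missed events.

What the generator does **not** model: motion and warping (motion correction
is out of scope), optics beyond an isotropic Gaussian blob (no PSF
anisotropy), photobleaching trends, overlapping or merging events, cellular
morphology, and spatially correlated noise. Passing benchmarks on these
scenes therefore demonstrates the pipeline's correctness and its behaviour
at a known SNR, not performance on real recordings with drift, overlap or
structured background.

## Problem sizes and determinism

The shipped benchmarks run on one CPU in seconds to a couple of minutes:
200-trace distance matrices (19 900 DTW pairs), a 500×128×128 detection
scene, and autoencoder training on a few hundred short traces. All
randomness flows through explicit integer seeds (numpy `default_rng`;
scikit-learn `random_state`); identical seeds give bit-identical event
tables, videos and cluster assignments, which the acceptance suite asserts.

## Known limitations

- The spatial cutoff search assumes positive background in the corrected
  video; data centred on zero rely on the temporal threshold.
- Pearson on ragged traces is a truncation heuristic; DTW is the principled
  route for variable lengths.
- The AVI codec support is limited to uncompressed 8-bit grayscale (what the
  package itself writes); compressed AVIs need external conversion.
- Event splitting (watershed) and per-cell assignment are not implemented;
  the `--split-events` flag is rejected as unsupported.
- The autoencoders target method-development scale; training thousands of
  long traces would be markedly faster in a GPU framework.
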