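"""Distances, hierarchical clustering, scoring, discrimination and
coincidence detection."""

import numpy as np
import pandas as pd
import pytest
from _oracles import dtw_brute_force, matched_accuracy_brute_force

from astroevents.analysis import (
    cluster_linkage,
    coincidence_labels,
    default_coincidence_window,
    dtw_barycenter,
    dtw_distance,
    match_cluster_scores,
    match_incidence_offset,
    pairwise_distance,
    pearson_distance,
    predict_coincidence,
    predict_incidence_location,
    train_discriminator,
)
from astroevents.errors import (
    DegenerateLabelError,
    UndefinedCorrelationError,
    ValidationError,
)


class TestDtw:
    def test_identical_traces_distance_zero(self, rng):
        x = rng.normal(size=10)
        assert dtw_distance(x, x) == 0.0

    def test_equals_exhaustive_path_enumeration(self, rng):
        """All pairs of short traces (length <= 6): DP equals brute force."""
        traces = [rng.normal(size=n) for n in (3, 4, 4, 5, 6, 6)]
        for i in range(len(traces)):
            for j in range(i, len(traces)):
                expected = dtw_brute_force(traces[i], traces[j])
                assert dtw_distance(traces[i], traces[j]) == pytest.approx(expected)

    def test_symmetry_and_euclidean_upper_bound(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 12))
            d_xy = dtw_distance(x, y)
            assert d_xy == pytest.approx(dtw_distance(y, x))
            assert d_xy <= np.linalg.norm(x - y) + 1e-12

    def test_band_constraint_never_decreases_distance(self, rng):
        x, y = rng.normal(size=(2, 15))
        free = dtw_distance(x, y)
        banded = dtw_distance(x, y, window=2)
        assert banded >= free - 1e-12


class TestPearson:
    def test_affine_invariance_and_limits(self, rng):
        x = rng.normal(size=20)
        assert pearson_distance(x, 2 * x + 3) == pytest.approx(0.0, abs=1e-12)
        assert pearson_distance(x, -x) == pytest.approx(2.0)

    def test_zero_variance_trace_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_distance(np.ones(5), np.arange(5.0))

    def test_unequal_lengths_truncated_at_start(self, rng):
        x = rng.normal(size=30)
        assert pearson_distance(x, x[:20]) == pytest.approx(0.0, abs=1e-12)

    def test_matrix_properties(self, rng):
        traces = [rng.normal(size=15) for _ in range(6)]
        dist = pairwise_distance(traces, method="pearson")
        assert np.allclose(dist.values, dist.values.T, atol=1e-9)
        assert np.allclose(np.diag(dist.values), 0)
        assert dist.values.min() >= 0 and dist.values.max() <= 2

    def test_single_trace_rejected(self, rng):
        with pytest.raises(ValidationError):
            pairwise_distance([rng.normal(size=5)], method="dtw")


class TestClusterLinkage:
    def _bundles(self, rng):
        a = [np.sin(np.linspace(0, 6, 30)) + rng.normal(0, 0.05, 30) for _ in range(8)]
        b = [np.cos(np.linspace(0, 6, 30)) + 5 + rng.normal(0, 0.05, 30) for _ in range(8)]
        return a + b

    def test_two_far_bundles_split_cleanly(self, rng):
        traces = self._bundles(rng)
        dist = pairwise_distance(traces, method="dtw")
        result = cluster_linkage(dist, "maxclust", 2, traces=traces)
        labels = result.labels
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[8]
        assert set(result.barycenters) == set(labels)

    def test_maxclust_one_single_cluster(self, rng):
        traces = self._bundles(rng)
        dist = pairwise_distance(traces, method="dtw")
        result = cluster_linkage(dist, "maxclust", 1)
        assert len(set(result.labels)) == 1

    def test_distance_cutoff_below_minimum_gives_singletons(self, rng):
        traces = [rng.normal(size=10) for _ in range(5)]
        dist = pairwise_distance(traces, method="dtw")
        cutoff = dist.values[dist.values > 0].min() / 2
        result = cluster_linkage(dist, "distance", cutoff)
        assert len(set(result.labels)) == 5

    def test_deterministic_given_input(self, rng):
        traces = self._bundles(rng)
        dist = pairwise_distance(traces, method="pearson")
        a = cluster_linkage(dist, "maxclust", 3, traces=traces)
        b = cluster_linkage(dist, "maxclust", 3, traces=traces)
        assert np.array_equal(a.labels, b.labels)
        for c in a.barycenters:
            assert np.allclose(a.barycenters[c], b.barycenters[c])

    def test_invalid_cutoff_rejected(self, rng):
        dist = pairwise_distance([rng.normal(size=5) for _ in range(3)], "dtw")
        with pytest.raises(ValidationError):
            cluster_linkage(dist, "maxclust", 0)

    def test_dtw_barycenter_of_identical_traces_is_the_trace(self):
        trace = np.array([0.0, 1.0, 3.0, 1.0, 0.0])
        center = dtw_barycenter([trace, trace.copy(), trace.copy()])
        assert np.allclose(center, trace)


class TestMatchClusterScores:
    def test_relabelled_truth_scores_perfectly(self):
        truth = ["a"] * 5 + ["b"] * 5
        pred = [2] * 5 + [1] * 5
        report = match_cluster_scores(truth, pred)
        assert report.accuracy == 1.0
        assert report.agreement_index == pytest.approx(1.0)

    def test_single_cluster_on_balanced_classes_is_half(self):
        report = match_cluster_scores(["a"] * 10 + ["b"] * 10, [1] * 20)
        assert report.accuracy == 0.5

    def test_matches_exhaustive_permutation_search(self, rng):
        """Random labelings with up to 8 clusters: Hungarian matching equals
        enumerating every injective assignment."""
        for _ in range(30):
            n = int(rng.integers(5, 40))
            truth = rng.integers(0, rng.integers(2, 5), n)
            pred = rng.integers(0, rng.integers(2, 9), n)
            report = match_cluster_scores(truth, pred)
            assert report.accuracy == pytest.approx(
                matched_accuracy_brute_force(truth, pred)
            )

    def test_extra_clusters_count_as_errors(self):
        truth = ["a", "a", "b", "b"]
        pred = [1, 2, 3, 4]  # more clusters than labels
        report = match_cluster_scores(truth, pred)
        assert report.accuracy == 0.5

    def test_confusion_matrix_row_sums_are_class_counts(self):
        truth = ["a"] * 3 + ["b"] * 7
        pred = [1, 1, 2, 2, 2, 2, 1, 1, 2, 2]
        report = match_cluster_scores(truth, pred)
        assert report.confusion.sum(axis=1).tolist() == [3, 7]


class TestDiscriminator:
    def test_linearly_separable_embedding_scores_one(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (50, 2)), rng.normal(4, 0.2, (50, 2))])
        y = ["a"] * 50 + ["b"] * 50
        _, report = train_discriminator(X, y, seed=0)
        assert report.accuracy == 1.0

    def test_shuffled_labels_score_near_chance(self, rng):
        X = rng.normal(size=(200, 4))
        y = np.array(["a", "b"] * 100)
        rng.shuffle(y)
        _, report = train_discriminator(X, list(y), seed=0)
        # 99% binomial bounds around 0.5 at the held-out n=40
        assert abs(report.accuracy - 0.5) < 2.576 * np.sqrt(0.25 / 40)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            train_discriminator(rng.normal(size=(10, 2)), ["a"] * 10)

    def test_logistic_baseline_available(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (20, 2)), rng.normal(4, 0.2, (20, 2))])
        y = ["a"] * 20 + ["b"] * 20
        _, report = train_discriminator(X, y, classifier_name="logistic", seed=0)
        assert report.accuracy == 1.0
        with pytest.raises(ValidationError):
            train_discriminator(X, y, classifier_name="svm")


class TestCoincidence:
    def _table(self, z0):
        return pd.DataFrame({"z0": z0, "dz": [10] * len(z0)})

    def test_events_at_incidences_all_coincide(self):
        incidences = [100, 200, 300]
        labels = coincidence_labels([100, 200, 300], incidences, window=0)
        assert labels.all()

    def test_ten_incidences_from_thousand_spacing(self):
        timing = list(range(0, 10000, 1000))
        assert len(timing) == 10

    def test_labels_match_interval_scan_oracle(self, rng):
        incidences = sorted(rng.choice(5000, 8, replace=False).tolist())
        z0 = rng.integers(0, 5000, 300)
        window = 40
        labels = coincidence_labels(z0, incidences, window)
        oracle = np.array(
            [any(t <= z <= t + window for t in incidences) for z in z0]
        )
        assert np.array_equal(labels, oracle)

    def test_default_window_is_half_median_gap_capped(self):
        assert default_coincidence_window([0, 100, 200]) == 50
        assert default_coincidence_window(list(range(0, 10000, 1000))) == 100

    def test_degenerate_labels_raise(self, rng):
        table = self._table([5, 6, 7])
        X = rng.normal(size=(3, 2))
        with pytest.raises(DegenerateLabelError):
            predict_coincidence(table, [0], X, window=100)

    def test_separable_coincidence_classification(self, rng):
        """Events locked to stimuli with a distinct embedding signature are
        classified nearly perfectly."""
        incidences = list(range(0, 10000, 1000))
        z0_coinc = [t + int(rng.integers(0, 50)) for t in incidences for _ in range(10)]
        z0_rand = [int(v) for v in rng.integers(200, 900, 100)]  # off-stimulus
        table = self._table(z0_coinc + z0_rand)
        X = np.vstack(
            [rng.normal(0, 0.3, (100, 2)), rng.normal(3, 0.3, (100, 2))]
        )
        labels, report = predict_coincidence(
            table, incidences, X, window=100, seed=0
        )
        assert labels[:100].all() and not labels[100:].any()
        assert report.accuracy >= 0.9


class TestIncidenceRegression:
    def test_offsets_match_nearest_preceding_oracle(self, rng):
        incidences = [0, 500, 1200, 4000]
        z0 = rng.integers(0, 5000, 50)
        offsets = match_incidence_offset(z0, incidences)
        inc = np.array(incidences)
        for z, off in zip(z0, offsets):
            preceding = inc[inc <= z].max()
            assert off == z - preceding

    def test_constant_offset_gives_zero_rmse(self, rng):
        incidences = list(range(0, 2000, 100))
        z0 = [t + 5 for t in incidences]
        table = pd.DataFrame({"z0": z0})
        X = rng.normal(size=(len(z0), 3))
        scores = predict_incidence_location(table, incidences, X, seed=0)
        assert scores["rmse"] == pytest.approx(0.0, abs=1e-9)

    def test_linear_offset_recovered_to_noise_level(self, rng):
        """Offset linear in one embedding coordinate + noise: held-out RMSE
        lands near the noise scale."""
        n, sigma = 200, 2.0
        code = rng.uniform(0, 1, n)
        offset = np.clip(
            (60 * code + rng.normal(0, sigma, n)).round().astype(int), 0, None
        )
        incidences = list(range(0, n * 1000, 1000))
        z0 = [t + o for t, o in zip(incidences, offset)]
        table = pd.DataFrame({"z0": z0})
        X = np.column_stack([code, rng.normal(size=n)])
        scores = predict_incidence_location(table, incidences, X, seed=0)
        assert scores["rmse"] < 1.5 * sigma + 1.0

    def test_too_few_events_rejected(self, rng):
        table = pd.DataFrame({"z0": [1, 2, 3]})
        with pytest.raises(ValidationError):
            predict_incidence_location(table, [0], rng.normal(size=(3, 2)))
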