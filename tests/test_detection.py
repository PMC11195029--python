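"""Detection pipeline: smoothing, dual thresholding, morphology, labelling,
event extraction and the chunked end-to-end driver."""

import numpy as np
import pytest
from _oracles import bfs_label, brute_force_peak_extents, partitions_equivalent

from astroevents import synthetic
from astroevents.detection import (
    DetectionConfig,
    EventCollection,
    combine_masks,
    detect,
    exclude_border,
    extract_events,
    label_events,
    morphological_cleanup,
    smooth,
    spatial_threshold,
    summarize_detection,
    temporal_threshold,
)
from astroevents.errors import ValidationError


class TestSmooth:
    def test_sigma_zero_is_identity(self, rng):
        video = rng.normal(size=(3, 8, 8))
        assert np.array_equal(smooth(video, 0.0), video)

    def test_delta_image_mass_conserved(self):
        video = np.zeros((1, 21, 21))
        video[0, 10, 10] = 1.0
        out = smooth(video, 1.0, radius=3)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert out[0, 10, 10] == out.max()

    def test_matches_dense_convolution_oracle(self, rng):
        """Interior pixels equal direct convolution with the truncated kernel."""
        sigma, radius = 1.0, 3
        video = rng.normal(size=(1, 16, 16))
        out = smooth(video, sigma, radius)
        offsets = np.arange(-radius, radius + 1)
        k1 = np.exp(-(offsets**2) / (2 * sigma**2))
        kernel = np.outer(k1, k1)
        kernel /= kernel.sum()
        for y, x in [(5, 5), (8, 3), (10, 12)]:
            patch = video[0, y - radius : y + radius + 1, x - radius : x + radius + 1]
            assert out[0, y, x] == pytest.approx(float((patch * kernel).sum()), abs=1e-9)


class TestSpatialThreshold:
    def test_block_on_zeros_with_min_ratio_one(self):
        """A bright 3x3 block on a zero background is exactly recovered."""
        video = np.zeros((1, 12, 12))
        video[0, 4:7, 4:7] = 10.0
        mask = spatial_threshold(video, min_ratio=1.0, z_depth=1)
        expected = video[0] > 0
        assert np.array_equal(mask[0], expected)

    def test_constant_frame_has_no_active_pixels(self):
        video = np.full((2, 8, 8), 3.0)
        assert not spatial_threshold(video, min_ratio=2.0).any()

    def test_bimodal_frame_matches_exhaustive_cutoff_search(self, rng):
        """Active set agrees with exhaustively maximising between-class
        variance over every possible cutoff (<=2% pixel disagreement)."""
        frame = rng.normal(0, 1, (24, 24))
        frame[8:16, 8:16] = rng.normal(8, 1, (8, 8))
        video = frame[None]
        mask = spatial_threshold(video, min_ratio=1.0, z_depth=1)[0]
        values = np.sort(frame.ravel())
        best_cut, best_score = None, -np.inf
        for cut in values[1:]:
            hi, lo = frame[frame >= cut], frame[frame < cut]
            w = len(hi) / frame.size
            score = w * (1 - w) * (hi.mean() - lo.mean()) ** 2
            if score > best_score:
                best_score, best_cut = score, cut
        oracle = frame >= best_cut
        disagreement = np.mean(mask != oracle)
        assert disagreement <= 0.02
        blob = np.zeros_like(mask)
        blob[8:16, 8:16] = True
        assert np.mean(mask != blob) <= 0.02

    def test_noise_only_window_fails_ratio_test(self, rng):
        video = rng.normal(5.0, 0.2, (3, 16, 16))
        assert not spatial_threshold(video, min_ratio=2.0, z_depth=3).any()


class TestTemporalThreshold:
    def test_constant_traces_all_false(self):
        assert not temporal_threshold(np.full((10, 4, 4), 2.0)).any()

    def test_clean_bump_active_during_extent(self):
        """A noise-free bump marks exactly its rel-height extent."""
        video = np.zeros((30, 4, 4))
        profile = 5.0 * (1 - np.abs(np.linspace(-1, 1, 7)))
        video[10:17, 2, 2] = profile
        mask = temporal_threshold(
            video, prominence=2.0, width=3, rel_height=0.9, wlen=None
        )
        assert mask[:, 2, 2].any()
        active = set(np.flatnonzero(mask[:, 2, 2]))
        (expected,) = brute_force_peak_extents(video[:, 2, 2], 2.0, 0.9, 3)
        assert active == set(range(expected[0], expected[1] + 1))
        assert not mask[:, 0, 0].any()

    def test_random_traces_match_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        video = rng.normal(0, 1, (40, 3, 3)).cumsum(axis=0) * 0.3
        mask = temporal_threshold(
            video, prominence=1.0, width=1, rel_height=0.8, wlen=None
        )
        for y in range(3):
            for x in range(3):
                active = set(np.flatnonzero(mask[:, y, x]))
                expected = set()
                for a, b in brute_force_peak_extents(
                    video[:, y, x], 1.0, 0.8, 1
                ):
                    expected.update(range(a, b + 1))
                assert active == expected


class TestMaskCombination:
    def test_idempotence_and_disjoint_intersection(self, rng):
        a = rng.random((4, 5, 5)) > 0.5
        assert np.array_equal(combine_masks(a, a, "union"), a)
        assert np.array_equal(combine_masks(a, a, "intersection"), a)
        assert not combine_masks(a, ~a, "intersection").any()

    def test_matches_elementwise_truth_tables(self, rng):
        a = rng.random((4, 5, 5)) > 0.5
        b = rng.random((4, 5, 5)) > 0.5
        assert np.array_equal(combine_masks(a, b, "union"), a | b)
        assert np.array_equal(combine_masks(a, b, "intersection"), a & b)


class TestMorphology:
    def test_single_pixel_hole_filled(self):
        mask = np.zeros((1, 9, 9), dtype=bool)
        mask[0, 2:7, 2:7] = True
        mask[0, 4, 4] = False
        out = morphological_cleanup(mask, area_threshold=1, min_size=1)
        assert out[0, 4, 4]

    def test_isolated_voxel_removed_by_min_size(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        assert not morphological_cleanup(mask, area_threshold=0, min_size=2).any()

    def test_survivors_match_flood_fill_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((6, 8, 8)) < 0.15
            out = morphological_cleanup(
                mask, area_threshold=0, min_size=3, connectivity=26
            )
            oracle_labels = bfs_label(mask, 26)
            keep = np.zeros_like(mask)
            for lab in range(1, oracle_labels.max() + 1):
                voxels = oracle_labels == lab
                if voxels.sum() >= 3:
                    keep |= voxels
            assert np.array_equal(out, keep)

    def test_output_subset_of_hole_filled_mask(self, rng):
        mask = rng.random((4, 10, 10)) < 0.3
        out = morphological_cleanup(mask, area_threshold=2, min_size=5)
        filled = np.stack(
            [morphological_cleanup(mask[t][None], 2, 1)[0] for t in range(4)]
        )
        assert not (out & ~filled).any()


class TestExcludeBorder:
    def test_zero_border_is_identity(self, rng):
        mask = rng.random((3, 6, 6)) > 0.5
        assert np.array_equal(exclude_border(mask, 0), mask)

    def test_border_one_keeps_interior(self):
        mask = np.ones((2, 6, 6), dtype=bool)
        out = exclude_border(mask, 1)
        assert out.sum() == 2 * 4 * 4
        assert out[:, 1:5, 1:5].all()

    def test_cleared_set_matches_coordinate_predicate(self, rng):
        mask = rng.random((3, 8, 10)) > 0.4
        out = exclude_border(mask, 2)
        H, W = 8, 10
        for y in range(H):
            for x in range(W):
                border = y < 2 or y >= H - 2 or x < 2 or x >= W - 2
                if border:
                    assert not out[:, y, x].any()
                else:
                    assert np.array_equal(out[:, y, x], mask[:, y, x])

    def test_excessive_border_rejected(self):
        with pytest.raises(ValidationError):
            exclude_border(np.ones((1, 6, 6), dtype=bool), 3)


class TestLabelEvents:
    def test_empty_mask_has_zero_labels(self):
        assert label_events(np.zeros((3, 4, 4), dtype=bool)).max() == 0

    def test_spatially_disjoint_blobs_get_two_labels(self):
        mask = np.zeros((4, 10, 10), dtype=bool)
        mask[0:3, 1:3, 1:3] = True
        mask[1:4, 6:8, 6:8] = True
        assert label_events(mask).max() == 2
        # make them touch in one frame: single label
        mask[2, 3:6, 3:6] = True
        mask[2, 2:4, 2:4] = True
        assert label_events(mask).max() == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_random_volumes_partition_equivalent_to_bfs(self, connectivity):
        """200 random small volumes labelled identically to flood fill."""
        rng = np.random.default_rng(connectivity)
        for _ in range(200):
            mask = rng.random((4, 6, 6)) < 0.25
            ours = label_events(mask, connectivity)
            oracle = bfs_label(mask, connectivity)
            assert partitions_equivalent(ours, oracle)


class TestExtractEvents:
    def test_span_duration_and_trace_length(self, small_collection):
        coll, _, _ = small_collection
        ev = coll.events.set_index("event_id")
        assert ev.loc[1, "z0"] == 2 and ev.loc[1, "z1"] == 4 and ev.loc[1, "dz"] == 3
        for eid in ev.index:
            assert len(coll.trace(eid)) == ev.loc[eid, "dz"]
            assert coll.footprint(eid).sum() == ev.loc[eid, "v_area"]

    def test_single_voxel_event_trace_value(self, tmp_path):
        video = np.zeros((5, 4, 4))
        video[2, 1, 1] = 7.0
        labels = np.zeros((5, 4, 4), dtype=np.int32)
        labels[2, 1, 1] = 1
        coll = extract_events(labels, video, tmp_path / "one.roi")
        assert np.array_equal(coll.trace(1), [7.0])
        assert coll.events.iloc[0]["v_area"] == 1

    def test_traces_match_voxel_list_averaging_oracle(self, small_collection):
        coll, video, labels = small_collection
        for eid in coll.events["event_id"]:
            voxels = labels == eid
            z0 = int(coll.events.set_index("event_id").loc[eid, "z0"])
            expected = []
            t = z0
            while t < labels.shape[0] and voxels[t].any():
                expected.append(video[t][voxels[t]].mean())
                t += 1
            assert np.allclose(coll.trace(eid), expected, atol=1e-6)

    def test_empty_labels_give_empty_collection(self, tmp_path, caplog):
        labels = np.zeros((3, 4, 4), dtype=np.int32)
        with caplog.at_level("WARNING"):
            coll = extract_events(labels, np.zeros((3, 4, 4)), tmp_path / "e.roi")
        assert len(coll) == 0
        assert "no events" in caplog.text

    def test_collection_round_trips_losslessly(self, small_collection):
        coll, _, _ = small_collection
        reloaded = EventCollection(coll.directory)
        assert reloaded.events.equals(coll.events)
        for eid in coll.events["event_id"]:
            assert np.array_equal(reloaded.trace(eid), coll.trace(eid))
            assert np.array_equal(reloaded.footprint(eid), coll.footprint(eid))
        assert reloaded.provenance["n_events"] == len(coll)


class TestDetect:
    def test_all_zero_video_yields_no_events(self, tmp_path):
        coll = detect(np.zeros((30, 16, 16)), DetectionConfig(), tmp_path / "z.roi")
        assert len(coll) == 0

    def test_well_separated_transients_recovered(self, tmp_path):
        """Every planted event in a small scene overlaps a detection at
        IoU > 0.5 and the per-event count matches."""
        scene = synthetic.SceneParams(
            num_rows=6, z_range=(10, 60),
            generators=[synthetic.SignalParams(
                trace_length=(25, 25), amplitude=6.0, b=0.4, plateau_duration=4,
                onset_jitter=False,
            )],
            video_shape=(100, 64, 64), blob_radius=2.0, background_level=5.0,
            pixel_noise=0.5, min_separation=14.0, seed=4,
        )
        table = synthetic.generate_event_table(scene)
        video, gt_labels = synthetic.render_video(table, scene)
        # clean data: require both evidence sources per voxel
        coll = detect(
            video, DetectionConfig(combine_mode="intersection"), tmp_path / "s.roi"
        )
        report = synthetic.evaluate_detection(
            gt_labels, coll, (5, 1000), iou_threshold=0.5
        )
        assert report["matched"] == report["generated"] == 6

    def test_min_size_monotonicity(self, tmp_path, rng):
        video = rng.normal(5, 0.5, (40, 24, 24))
        video[10:20, 8:14, 8:14] += 5.0
        counts = []
        for min_size in (1, 20, 200):
            coll = detect(
                video, DetectionConfig(min_size=min_size),
                tmp_path / f"m{min_size}.roi",
            )
            counts.append(len(coll))
        assert counts[0] >= counts[1] >= counts[2]

    def test_exclude_border_never_increases_active_voxels(self, tmp_path, rng):
        video = rng.normal(5, 0.5, (30, 20, 20))
        video[5:15, 2:8, 2:8] += 5.0
        plain = detect(video, DetectionConfig(), tmp_path / "p.roi")
        bordered = detect(
            video, DetectionConfig(exclude_border=3), tmp_path / "b.roi"
        )
        assert (
            bordered.events["n_voxels"].sum() <= plain.events["n_voxels"].sum()
        )

    def test_split_events_flag_rejected(self):
        with pytest.raises(ValidationError, match="unsupported"):
            DetectionConfig(split_events=True)

    def test_summary_reports_counts_and_quantiles(self, small_collection):
        coll, _, _ = small_collection
        summary = summarize_detection(coll)
        assert summary["n_events"] == 3
        assert "0.5" in summary["dz_quantiles"]
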