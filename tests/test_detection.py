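"""Background construction, differencing, blob filters, repeat suppression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dldflow.detection import (
    BlobParams,
    Detection,
    DetectionLedger,
    assign_channels,
    build_background,
    detect_blobs,
    filter_new_particles,
    frame_difference,
    subtract_background,
    summarize_run,
)
from dldflow.geometry import ChannelGeometry
from oracles import brute_force_new_particles

LOOSE = BlobParams(
    min_area=4,
    max_area=500,
    min_circularity=0.0,
    intensity_threshold_range=(50, 200, 50),
    min_repeatability=1,
)


def _disk(shape, row, col, radius, value, base=0.0):
    img = np.full(shape, base)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img[np.hypot(rr - row, cc - col) <= radius] = value
    return img


class TestBuildBackground:
    def test_blob_free_frame_returned_identical(self):
        frame = (np.arange(100).reshape(10, 10) % 30 + 10).astype(np.uint8)
        bg = build_background(frame, LOOSE)
        assert np.array_equal(bg.pixels, frame)
        assert bg.patched_regions == []

    def test_hand_computed_row_patch(self):
        # 10x10 frame of value 10 with a 3x3 bright blob at rows/cols 4-6:
        # each affected row's blob pixels become the mean of its 7 others
        frame = np.full((10, 10), 10, dtype=np.uint8)
        frame[4:7, 4:7] = 200
        bg = build_background(frame, LOOSE)
        assert np.array_equal(bg.pixels, np.full((10, 10), 10))
        assert len(bg.patched_regions) >= 1

    def test_nonuniform_rows_use_their_own_mean(self):
        # row r has constant value 10*(r+1); only the stamped blob exceeds
        # the threshold sweep
        frame = np.repeat(
            np.arange(10, 110, 10, dtype=np.uint8)[:, None], 10, axis=1
        )
        frame[4:7, 4:7] = 250
        params = BlobParams(
            min_area=4, max_area=500, min_circularity=0.0,
            intensity_threshold_range=(150, 200, 50), min_repeatability=1,
        )
        bg = build_background(frame, params)
        for r in range(4, 7):
            expected = frame[r, [0, 1, 2, 3, 7, 8, 9]].mean()
            assert np.allclose(bg.pixels[r, 4:7], round(expected))

    def test_full_row_blob_falls_back_to_global_mean(self):
        frame = np.full((8, 6), 20, dtype=np.uint8)
        frame[3, :] = 220  # entire row is one wide blob
        params = BlobParams(
            min_area=2, max_area=50, min_circularity=0.0,
            intensity_threshold_range=(100, 200, 50), min_repeatability=1,
        )
        bg = build_background(frame, params)
        assert bg.full_row_fallbacks == [3]
        assert np.allclose(bg.pixels[3], 20)

    def test_patch_recovers_particle_free_fixture(self):
        base = np.repeat(
            np.linspace(60, 180, 40)[:, None], 60, axis=1
        ).astype(np.uint8)
        withp = base.astype(float).copy()
        withp = _disk(withp.shape, 20, 30, 5, 240, base=0) + withp * (
            _disk(withp.shape, 20, 30, 5, 1, base=0) == 0
        )
        bg = build_background(np.clip(withp, 0, 255).astype(np.uint8), LOOSE)
        assert np.max(np.abs(bg.pixels.astype(int) - base.astype(int))) <= 2

    def test_idempotence(self):
        frame = np.full((20, 20), 30, dtype=np.uint8)
        frame[8:13, 8:13] = 250
        bg = build_background(frame, LOOSE)
        bg2 = build_background(bg.pixels, LOOSE)
        assert np.array_equal(bg.pixels, bg2.pixels)
        assert bg2.patched_regions == []


class TestSubtraction:
    def test_frame_equal_to_background_is_zero(self):
        img = np.full((5, 5), 80, dtype=np.uint8)
        bg = build_background(img, LOOSE)
        assert not subtract_background(img, bg).any()

    def test_arithmetic_and_clamping(self):
        bg = build_background(np.full((1, 2), 50, dtype=np.uint8), LOOSE)
        bg.pixels[0, 1] = 80
        frame = np.array([[80, 50]], dtype=np.uint8)
        out = subtract_background(frame, bg)
        assert out.tolist() == [[30, 0]]

    def test_difference_arithmetic(self):
        a = np.array([[10, 0]], dtype=np.uint8)
        b = np.array([[0, 10]], dtype=np.uint8)
        assert frame_difference(a, b).tolist() == [[10, 0]]
        assert not frame_difference(a, a).any()

    def test_shape_mismatch_raises(self):
        bg = build_background(np.zeros((4, 4), dtype=np.uint8), LOOSE)
        with pytest.raises(ValueError):
            subtract_background(np.zeros((5, 4), dtype=np.uint8), bg)
        with pytest.raises(ValueError):
            frame_difference(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_residual_confined_to_particle_footprint(self):
        base = np.full((40, 60), 100, dtype=np.uint8)
        bg = build_background(base, LOOSE)
        frame = np.clip(_disk((40, 60), 20, 30, 5, 240, base=100), 0, 255).astype(np.uint8)
        res = subtract_background(frame, bg)
        rr, cc = np.nonzero(res)
        assert np.hypot(rr - 20, cc - 30).max() <= 6.5


class TestDetectBlobs:
    def test_zero_matrix_gives_empty_list(self):
        assert detect_blobs(np.zeros((30, 30)), LOOSE) == []

    def test_disk_centroid_recovered(self):
        img = _disk((50, 60), 20, 30, 5, 200.0)
        params = BlobParams(
            min_area=20, max_area=500, min_circularity=0.5,
            intensity_threshold_range=(50, 150, 50), min_repeatability=1,
        )
        (r, c), = detect_blobs(img, params)
        assert (r, c) == pytest.approx((20.0, 30.0), abs=0.1)

    def test_elongated_shape_rejected_disk_accepted(self):
        img = np.zeros((60, 80))
        img[10, 20:49] = 200          # 1x29 line segment, area 29
        img += _disk((60, 80), 40, 40, 3, 200.0)  # disk of comparable area
        params = BlobParams(
            min_area=15, max_area=100, min_circularity=0.7,
            intensity_threshold_range=(100, 100, 10), min_repeatability=1,
        )
        cents = detect_blobs(img, params)
        assert len(cents) == 1
        assert cents[0] == pytest.approx((40.0, 40.0), abs=0.2)

    def test_repeatability_filter_drops_single_threshold_blobs(self):
        img = _disk((40, 40), 20, 20, 4, 60.0)  # visible only below t=60
        params = BlobParams(
            min_area=10, max_area=200, min_circularity=0.0,
            intensity_threshold_range=(50, 250, 10), min_repeatability=3,
        )
        assert detect_blobs(img, params) == []

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BlobParams(min_area=10, max_area=5)
        with pytest.raises(ValueError):
            BlobParams(min_circularity=1.5)


class TestRepeatSuppression:
    @pytest.mark.parametrize(
        "previous, current, expected_new",
        [
            # same row, column advanced -> downstream repeat, suppressed
            ([(100, 50)], [(100, 60)], []),
            # row moved by 5 px (> 1 px tolerance) -> new particle
            ([(100, 50)], [(105, 60)], [(105, 60)]),
            # identical position -> new (a particle cannot be stationary)
            ([(100, 50)], [(100, 50)], [(100, 50)]),
            # duplicate centroids collapse, then suppressed as repeat
            ([(100, 50)], [(100.5, 60), (100.5, 60)], []),
            # empty previous set: everything is new
            ([], [(10, 10), (30, 10)], [(10, 10), (30, 10)]),
        ],
    )
    def test_rule_examples(self, previous, current, expected_new):
        ledger = DetectionLedger(previous_centroids=[(float(r), float(c)) for r, c in previous])
        new = filter_new_particles(current, ledger, frame_index=5)
        assert [(d.row, d.col) for d in new] == [
            (float(r), float(c)) for r, c in expected_new
        ]
        # previous set is replaced by the full (collapsed) current set
        assert ledger.previous_centroids == sorted(
            set((round(float(r), 1), round(float(c), 1)) for r, c in current),
            key=lambda p: [(round(float(r), 1), round(float(c), 1)) for r, c in current].index(p),
        )

    def test_exhaustive_delta_grid_matches_oracle(self):
        # all (row offset, col offset) combinations around one previous point
        prev = [(100.0, 50.0)]
        for dr in (0.0, 0.5, 2.0):
            for dc in (0.0, 10.0):
                cur = [(100.0 + dr, 50.0 + dc)]
                ledger = DetectionLedger(previous_centroids=list(prev))
                got = [(d.row, d.col) for d in filter_new_particles(cur, ledger, 3)]
                assert got == brute_force_new_particles(prev, cur)

    def test_monotonic_unique_count(self):
        ledger = DetectionLedger()
        sizes = []
        rng = np.random.default_rng(4)
        for f in range(1, 20):
            cur = [
                (float(rng.integers(0, 40)), float(rng.integers(0, 200)))
                for _ in range(rng.integers(0, 5))
            ]
            filter_new_particles(cur, ledger, f)
            sizes.append(ledger.total)
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    @settings(max_examples=300, derandomize=True)
    @given(
        prev=st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 12)), max_size=5
        ),
        cur=st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 12)), max_size=5
        ),
    )
    def test_randomized_sets_match_oracle(self, prev, cur):
        prevf = [(float(r), float(c)) for r, c in prev]
        curf = [(float(r) / 2, float(c)) for r, c in cur]  # sub-pixel rows
        ledger = DetectionLedger(previous_centroids=list(prevf))
        got = [(d.row, d.col) for d in filter_new_particles(curf, ledger, 2)]
        want = brute_force_new_particles(
            prevf, [(round(r, 1), round(c, 1)) for r, c in curf]
        )
        assert got == want


class TestChannelAssignment:
    geom = ChannelGeometry((0, 10, 20))

    @pytest.mark.parametrize(
        "row, channel",
        [(5, 1), (10, 1), (10.5, 2), (20, 2), (25, None), (0, None)],
    )
    def test_interval_membership(self, row, channel):
        (d,) = assign_channels([Detection(row, 1.0, 1)], self.geom)
        assert d.channel_id == channel


class TestSummarize:
    def _ledger_for_counts(self, counts, walls):
        ledger = DetectionLedger()
        geom = ChannelGeometry(tuple(walls))
        f = 1
        for ch_idx, n in enumerate(counts):
            u, l, _ = geom.channels[ch_idx]
            for _ in range(n):
                ledger.unique_detections.append(
                    Detection((u + l) / 2.0, 10.0, f)
                )
                f += 1
        assign_channels(ledger.unique_detections, geom)
        return ledger, geom

    def test_percentages_and_total(self):
        ledger, geom = self._ledger_for_counts([2, 3, 5], [0, 10, 20, 30])
        s = summarize_run(ledger, geom)
        assert s.total == 10
        assert s.counts.tolist() == [2, 3, 5]
        assert s.percentages.tolist() == [20.0, 30.0, 50.0]

    def test_outlet_tail_counts_sum_like_a_real_run(self):
        # a run concentrated in the last four outlets: 4, 5, 7, 9 -> 25
        counts = [0] * 8 + [4, 5, 7, 9]
        walls = list(range(0, 121, 10))
        ledger, geom = self._ledger_for_counts(counts, walls)
        s = summarize_run(ledger, geom)
        assert s.total == 25
        assert s.counts.tolist() == counts

    def test_empty_ledger_all_zero(self):
        geom = ChannelGeometry((0, 10, 20))
        s = summarize_run(DetectionLedger(), geom)
        assert s.total == 0
        assert s.counts.tolist() == [0, 0]
        assert s.percentages.tolist() == [0.0, 0.0]

    def test_conservation_identity(self):
        ledger, geom = self._ledger_for_counts([1, 2], [0, 10, 20])
        ledger.unique_detections.append(Detection(99.0, 5.0, 9))  # out of span
        assign_channels(ledger.unique_detections, geom)
        s = summarize_run(ledger, geom)
        assert s.counts.sum() + s.unassigned == s.total
        assert s.percentages.sum() == pytest.approx(100.0)

    def test_table_schema(self):
        ledger, geom = self._ledger_for_counts([1, 1], [0, 10, 20])
        s = summarize_run(ledger, geom, {"flow_rate_ml_min": 2.0})
        assert list(s.table.columns) == ["frame_index", "row", "col", "channel"]
        assert len(s.table) == 2
        assert s.metadata["flow_rate_ml_min"] == 2.0


class TestPipelineRecovery:
    def test_noise_free_counts_exact(self, analyzed_small):
        summary, state, truth = analyzed_small
        assert summary.total == truth.true_total
        assert summary.counts.tolist() == truth.true_per_channel
        assert summary.unassigned == 0

    def test_noisy_counts_within_tolerance(self, noisy_video):
        from conftest import pipeline_settings
        from dldflow.pipeline import analyze_video

        cfg, seq, truth, tpl = noisy_video
        summary, _ = analyze_video(seq, tpl, pipeline_settings())
        err = abs(summary.total - truth.true_total) / truth.true_total * 100
        assert err <= 2.2
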