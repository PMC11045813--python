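import itertools

import numpy as np
import pytest

from trawlcount import (
    BoundingBox,
    FrameDetections,
    SortTracker,
    TrackerConfig,
    associate,
)
from trawlcount.sort import box_to_z, z_to_box

from conftest import random_box


def brute_force_assignment(iou_matrix, iou_min):
    """Enumerate all one-to-one assignments; return the max total IoU."""
    n_t, n_d = iou_matrix.shape
    best = 0.0
    k = min(n_t, n_d)
    for rows in itertools.permutations(range(n_t), k):
        for cols in itertools.permutations(range(n_d), k):
            total = sum(
                iou_matrix[r, c]
                for r, c in zip(rows, cols)
                if iou_matrix[r, c] >= iou_min
            )
            best = max(best, total)
    return best


class TestStateConversion:
    def test_box_roundtrip_is_exact(self):
        b = BoundingBox(100, 100, 40, 80)
        z = box_to_z(b)
        assert z == pytest.approx([120, 140, 3200, 0.5])
        back = z_to_box(z)
        assert (back.x_left, back.y_top, back.width, back.height) == pytest.approx(
            (100, 100, 40, 80)
        )

    def test_square_box_has_unit_aspect(self):
        assert box_to_z(BoundingBox(0, 0, 10, 10))[3] == 1.0


class TestTrackLifecycle:
    def test_birth_state(self):
        tracker = SortTracker()
        t = tracker.init_track(BoundingBox(100, 100, 40, 80), frame_index=0)
        assert t.state.x[4:].tolist() == [0, 0, 0]
        assert t.hits == 1 and t.time_since_update == 0
        assert len(t.history) == 1

    def test_track_ids_unique(self):
        tracker = SortTracker()
        a = tracker.init_track(BoundingBox(0, 0, 10, 10))
        b = tracker.init_track(BoundingBox(50, 50, 10, 10))
        assert a.track_id != b.track_id

    def test_fresh_track_predicts_in_place(self):
        tracker = SortTracker()
        t = tracker.init_track(BoundingBox(100, 100, 40, 80))
        pred = tracker.predict(t)
        assert (pred.center_x(), pred.center_y()) == pytest.approx((120, 140))
        tracker.predict(t)
        assert t.time_since_update == 2

    def test_noiseless_constant_velocity_extrapolates_linearly(self):
        """With noise scales ~0 the filter converges to the line fit."""
        cfg = TrackerConfig(
            process_noise_scale=1e-9, measurement_noise_scale=1e-9
        )
        tracker = SortTracker(cfg)
        t = tracker.init_track(BoundingBox(100, 100, 40, 80), frame_index=0)
        for k in range(1, 11):
            tracker.predict(t)
            tracker._update(t, BoundingBox(100, 100 + 5 * k, 40, 80), k)
        pred = tracker.predict(t)
        assert pred.center_y() == pytest.approx(140 + 5 * 11, abs=0.5)


class TestAssociate:
    def test_single_pair_above_threshold_matches(self):
        track_box = BoundingBox(0, 0, 10, 10)
        det = BoundingBox(1, 0, 10, 10)  # iou ~0.8
        matches, ud, ut = associate([(7, track_box)], [det], iou_min=0.3)
        assert matches == [(7, 0)] and ud == [] and ut == []

    def test_low_overlap_leaves_both_unmatched(self):
        matches, ud, ut = associate(
            [(7, BoundingBox(0, 0, 10, 10))], [BoundingBox(8, 8, 10, 10)], 0.3
        )
        assert matches == [] and ud == [0] and ut == [7]

    def test_empty_inputs(self):
        assert associate([], [], 0.3) == ([], [], [])
        m, ud, ut = associate([], [BoundingBox(0, 0, 1, 1)], 0.3)
        assert (m, ud, ut) == ([], [0], [])

    def test_optimal_against_permutation_oracle(self, rng):
        """Hungarian total IoU equals exhaustive search on random matrices."""
        for _ in range(100):
            n_t = int(rng.integers(1, 6))
            n_d = int(rng.integers(1, 6))
            tracks = [(i, random_box(rng)) for i in range(n_t)]
            dets = [random_box(rng) for _ in range(n_d)]
            from trawlcount import iou as iou_fn

            M = np.array([[iou_fn(tb, d) for d in dets] for _, tb in tracks])
            matches, ud, ut = associate(tracks, dets, iou_min=0.1)
            total = sum(M[tid, di] for tid, di in matches)
            assert total == pytest.approx(brute_force_assignment(M, 0.1), abs=1e-9)
            # conservation: outputs partition the inputs
            assert len(matches) + len(ud) == n_d
            assert len(matches) + len(ut) == n_t


def descend(n, x=600.0, y0=0.0, dy=5.0, w=40.0, h=80.0, start=0):
    return [
        FrameDetections(start + k, [BoundingBox(x, y0 + dy * k, w, h, 0.9)])
        for k in range(n)
    ]


class TestStep:
    def test_single_object_yields_one_confirmed_track(self):
        tracker = SortTracker()
        confirmed_ids = set()
        for frame in descend(20):
            for t in tracker.step(frame):
                confirmed_ids.add(t.track_id)
        assert confirmed_ids == {1}
        (track,) = tracker.tracks
        assert track.hits == 20 and len(track.history) == 20

    def test_no_detections_no_tracks(self):
        tracker = SortTracker()
        for k in range(10):
            assert tracker.step(FrameDetections(k)) == []

    def test_confirmation_requires_min_hits(self):
        tracker = SortTracker(TrackerConfig(min_hits=3))
        frames = descend(5)
        assert tracker.step(frames[0]) == []
        assert tracker.step(frames[1]) == []
        assert len(tracker.step(frames[2])) == 1

    def test_track_dies_after_max_age_missed_frames(self):
        tracker = SortTracker(TrackerConfig(max_age=3, min_hits=1))
        for frame in descend(5):
            tracker.step(frame)
        for k in range(5, 10):
            tracker.step(FrameDetections(k))
        assert tracker.tracks == []

    def test_two_parallel_objects_keep_identities(self):
        tracker = SortTracker()
        for k in range(20):
            frame = FrameDetections(
                k,
                [
                    BoundingBox(100, 5.0 * k, 40, 80, 0.9),
                    BoundingBox(900, 5.0 * k, 40, 80, 0.9),
                ],
            )
            tracker.step(frame)
        assert len(tracker.tracks) == 2
        for track in tracker.tracks:
            xs = [b.x_left for _, b in track.history]
            assert max(xs) - min(xs) < 1.0  # each stays in its lane

    def test_out_of_order_frames_rejected(self):
        tracker = SortTracker()
        tracker.step(FrameDetections(5))
        with pytest.raises(ValueError, match="increasing order"):
            tracker.step(FrameDetections(3))

    def test_prediction_error_shrinks_on_linear_motion(self):
        """After burn-in, predicted centers converge to the true line."""
        tracker = SortTracker(TrackerConfig(min_hits=1))
        errors = []
        t = tracker.init_track(BoundingBox(580, 0, 40, 80), frame_index=0)
        for k in range(1, 40):
            pred = tracker.predict(t)
            true = BoundingBox(580, 5.0 * k, 40, 80)
            errors.append(abs(pred.center_y() - true.center_y()))
            tracker._update(t, true, k)
        assert errors[-1] < 0.5
        assert errors[-1] <= errors[5]
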