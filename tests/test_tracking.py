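import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orchardtrack.detection_io import Detection
from orchardtrack.tracking import (
    INFEASIBLE_COST,
    KalmanFilter,
    Track,
    TrackState,
    Tracker,
    TrackerConfig,
    build_cost_matrix,
    cosine_distance,
    hungarian_solve,
    iou,
    normalize,
    run_tracker,
)


def det(frame=0, cx=100.0, cy=100.0, w=40.0, h=40.0, conf=0.9):
    return Detection(frame, cx, cy, w, h, conf, 0)


def unit(v):
    return normalize(np.asarray(v, dtype=float))


# ---------------------------------------------------------------------------
# cosine distance


class TestCosineDistance:
    def test_identical_unit_vectors(self):
        v = unit([1, 2, 3])
        assert cosine_distance(v, v) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_45_degrees(self):
        # hand evaluation: 1 - cos(45 deg)
        d = cosine_distance([1, 0], unit([1, 1]))
        assert d == pytest.approx(1 - 0.70710678, abs=1e-8)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0, 0], [1, 0])

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_range(self, a, b):
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            return
        d1 = cosine_distance(a, b)
        assert d1 == pytest.approx(cosine_distance(b, a))
        assert -1e-9 <= d1 <= 2 + 1e-9

    def test_scale_invariance(self):
        # zero iff positive scalar multiples
        assert cosine_distance([1, 2], [3, 6]) == pytest.approx(0.0, abs=1e-12)
        assert cosine_distance([1, 2], [-1, -2]) == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# cost matrix


def make_track(gallery, track_id=1):
    kf = KalmanFilter()
    mean, cov = kf.initiate((100, 100, 1.0, 40))
    t = Track(track_id=track_id, mean=mean, covariance=cov)
    for g in gallery:
        t.add_feature(np.asarray(g, dtype=float), 100)
    return t


class TestCostMatrix:
    def test_exact_gallery_match_is_zero(self):
        f = unit(np.arange(1, 9))
        t = make_track([f])
        cost = build_cost_matrix([t], [f])
        assert cost[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_gate_replaces_with_sentinel(self):
        g = unit([1, 0, 0])
        # cosine distance 0.36 > 0.15 gate
        e = unit([math.cos(math.acos(0.64)), math.sin(math.acos(0.64)), 0])
        t = make_track([g])
        cost = build_cost_matrix([t], [e])
        assert cost[0, 0] == INFEASIBLE_COST

    def test_minimum_over_gallery(self):
        rng = np.random.default_rng(0)
        base = unit(rng.normal(size=16))

        def rotated(target_dist):
            # construct a vector at exact cosine distance from base
            orth = rng.normal(size=16)
            orth -= orth @ base * base
            orth = unit(orth)
            c = 1 - target_dist
            return c * base + math.sqrt(1 - c**2) * orth

        g1, g2 = rotated(0.10), rotated(0.02)
        t = make_track([g1, g2])
        cost = build_cost_matrix([t], [base])
        # brute-force min over the gallery
        expected = min(cosine_distance(g, base) for g in (g1, g2))
        assert cost[0, 0] == pytest.approx(expected, abs=1e-9)
        assert cost[0, 0] == pytest.approx(0.02, abs=1e-9)

    def test_empty_gallery_is_internal_error(self):
        kf = KalmanFilter()
        mean, cov = kf.initiate((0, 0, 1.0, 10))
        t = Track(track_id=1, mean=mean, covariance=cov)
        with pytest.raises(RuntimeError):
            build_cost_matrix([t], [unit([1, 0])])


# ---------------------------------------------------------------------------
# Hungarian assignment


class TestHungarian:
    def test_single_cell(self):
        assert hungarian_solve(np.array([[0.05]])) == {(0, 0)}

    def test_two_by_two_chooses_cross(self):
        # total 4 beats the diagonal's 5
        assert hungarian_solve(np.array([[1.0, 2.0], [2.0, 4.0]])) == {(0, 1), (1, 0)}

    def test_empty(self):
        assert hungarian_solve(np.zeros((0, 0))) == set()
        assert hungarian_solve(np.zeros((0, 3))) == set()

    def test_sentinel_pairs_dropped(self):
        cost = np.array([[0.1, INFEASIBLE_COST], [INFEASIBLE_COST, INFEASIBLE_COST]])
        assert hungarian_solve(cost) == {(0, 0)}

    def test_non_square_padding_keeps_best_columns(self):
        cost = np.array([[0.5, 0.1, 0.9]])
        assert hungarian_solve(cost) == {(0, 1)}

    @pytest.mark.parametrize("shape", [(2, 2), (3, 3), (4, 4), (3, 5), (5, 3), (6, 6)])
    def test_matches_exhaustive_permutation_minimum(self, shape, rng):
        # brute-force oracle: enumerate all one-to-one pairings
        for _ in range(20):
            cost = rng.uniform(0, 1, size=shape)
            got = hungarian_solve(cost, infeasible=10.0)
            got_total = sum(cost[i, j] for i, j in got)
            r, c = shape
            k = min(r, c)
            best = min(
                sum(cost[i, j] for i, j in zip(rows, cols))
                for rows in itertools.permutations(range(r), k)
                for cols in itertools.permutations(range(c), k)
            )
            assert got_total == pytest.approx(best, abs=1e-9)


# ---------------------------------------------------------------------------
# IoU


class TestIoU:
    def test_identical(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == pytest.approx(1.0)

    def test_disjoint(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_hand_computed_overlap(self):
        # intersection 2, union 6
        assert iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)

    @given(
        st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(1, 30), st.floats(1, 30)),
        st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(1, 30), st.floats(1, 30)),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        box_a = (a[0], a[1], a[0] + a[2], a[1] + a[3])
        box_b = (b[0], b[1], b[0] + b[2], b[1] + b[3])
        v = iou(box_a, box_b)
        assert v == pytest.approx(iou(box_b, box_a))
        assert 0.0 <= v <= 1.0 + 1e-12

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 1), (0, 0, 1, 1))


# ---------------------------------------------------------------------------
# Kalman filter


class TestKalman:
    def setup_method(self):
        self.kf = KalmanFilter()

    def test_initiate_sets_positions_zero_velocities(self):
        mean, cov = self.kf.initiate((100, 100, 1.0, 40))
        assert np.allclose(mean, [100, 100, 1.0, 40, 0, 0, 0, 0])
        assert np.allclose(cov, cov.T)

    def test_initiate_velocity_uncertainty_exceeds_position(self):
        _, cov = self.kf.initiate((100, 100, 1.0, 40))
        d = np.diag(cov)
        assert all(d[i + 4] > d[i] for i in range(4))

    def test_initiate_deterministic(self):
        a = self.kf.initiate((5, 6, 0.9, 33))
        b = self.kf.initiate((5, 6, 0.9, 33))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_initiate_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            self.kf.initiate((0, 0, 1.0, -1))
        with pytest.raises(ValueError):
            self.kf.initiate((0, 0, 0.0, 10))

    def test_predict_zero_velocity_keeps_position(self):
        mean, cov = self.kf.initiate((100, 100, 1.0, 40))
        mean2, _ = self.kf.predict(mean, cov)
        assert np.allclose(mean2[:4], mean[:4])

    def test_predict_advances_by_velocity(self):
        mean = np.array([0, 0, 1, 10, 2, 0, 0, 0], dtype=float)
        _, cov = self.kf.initiate((0, 0, 1.0, 10))
        mean2, _ = self.kf.predict(mean, cov)
        assert mean2[0] == pytest.approx(2.0)
        assert mean2[1] == pytest.approx(0.0)

    def test_predict_grows_uncertainty(self):
        mean, cov = self.kf.initiate((100, 100, 1.0, 40))
        for _ in range(3):
            tr_before = np.trace(cov)
            mean, cov = self.kf.predict(mean, cov)
            assert np.trace(cov) >= tr_before

    def test_update_zero_innovation_keeps_measured_components(self):
        mean, cov = self.kf.initiate((100, 100, 1.0, 40))
        mean, cov = self.kf.predict(mean, cov)
        z = tuple(mean[:4])
        mean2, _ = self.kf.update(mean, cov, z)
        assert np.allclose(mean2[:4], mean[:4])

    def test_update_moves_toward_measurement_and_converges(self):
        mean, cov = self.kf.initiate((100, 100, 1.0, 40))
        z = np.array([120, 90, 1.1, 44])
        errs = []
        for _ in range(50):
            mean, cov = self.kf.predict(mean, cov)
            before = mean[:4].copy()
            mean, cov = self.kf.update(mean, cov, z)
            # posterior lies between prior and measurement component-wise
            for i in range(4):
                lo, hi = sorted((before[i], z[i]))
                assert lo - 1e-9 <= mean[i] <= hi + 1e-9
            errs.append(np.abs(mean[:4] - z).sum())
        assert errs[-1] < errs[0] * 0.1

    def test_update_reduces_position_variance(self):
        mean, cov = self.kf.initiate((100, 100, 1.0, 40))
        mean, cov = self.kf.predict(mean, cov)
        prior = np.diag(cov)[:4].copy()
        _, cov2 = self.kf.update(mean, cov, (101, 99, 1.0, 41))
        assert np.all(np.diag(cov2)[:4] <= prior + 1e-12)


# ---------------------------------------------------------------------------
# Tracker lifecycle


def steady_scene(n_frames, cx0=100.0, step=5.0, feature=None):
    """One fruit drifting right, one detection per frame."""
    feature = unit(np.arange(1, 17)) if feature is None else feature
    frames = [[det(frame=f, cx=cx0 + step * f)] for f in range(n_frames)]
    feats = [feature.reshape(1, -1) for _ in range(n_frames)]
    return frames, feats


class TestTrackerLifecycle:
    def test_confirmation_on_third_hit(self):
        frames, feats = steady_scene(3)
        res = run_tracker(frames, feats)
        assert res.count == 1
        assert res.confirmation_events == [(1, 2)]  # confirmed at frame index 2

    def test_single_frame_fruit_dies_tentative(self):
        frames, feats = steady_scene(1)
        frames += [[] for _ in range(5)]
        feats += [np.zeros((0, 16)) for _ in range(5)]
        res = run_tracker(frames, feats)
        assert res.count == 0
        assert res.reports[1].deleted_track_ids == [1]

    def test_two_frame_fruit_not_counted(self):
        frames, feats = steady_scene(2)
        frames += [[]]
        feats += [np.zeros((0, 16))]
        assert run_tracker(frames, feats).count == 0

    @pytest.mark.parametrize("gap,expect_new_track", [(30, False), (31, True)])
    def test_max_age_governs_reappearance(self, gap, expect_new_track):
        f = unit(np.arange(1, 17))
        frames, feats = steady_scene(5, step=0.0)
        frames += [[] for _ in range(gap)]
        feats += [np.zeros((0, 16)) for _ in range(gap)]
        more_frames, more_feats = steady_scene(5, step=0.0)
        for d_list in more_frames:
            d_list[0] = det(frame=0, cx=100.0)
        frames += more_frames
        feats += more_feats
        res = run_tracker(frames, feats)
        new_ids = {tid for r in res.reports[5 + gap :] for tid in r.new_track_ids}
        assert bool(new_ids) is expect_new_track
        assert res.count == (2 if expect_new_track else 1)

    def test_duplicated_detections_do_not_inflate_count(self):
        # every detection duplicated at IoU 1.0 with itself
        rng = np.random.default_rng(2)
        n_fruits, n_frames = 5, 12
        latents = [unit(rng.normal(size=32)) for _ in range(n_fruits)]
        frames, feats = [], []
        for f in range(n_frames):
            ds, es = [], []
            for i in range(n_fruits):
                d = det(frame=f, cx=100 + 300 * i + 5 * f)
                ds += [d, d]
                es += [latents[i], latents[i]]
            frames.append(ds)
            feats.append(np.vstack(es))
        assert run_tracker(frames, feats).count == n_fruits

    def test_gated_feature_still_matches_by_iou(self):
        # appearance jumps beyond the 0.15 gate for one frame; the IoU
        # fallback must keep the identity alive
        f1 = unit(np.r_[1.0, np.zeros(15)])
        f2 = unit(np.r_[0.0, 1.0, np.zeros(14)])  # orthogonal: distance 1
        frames = [[det(frame=f, cx=100 + 2 * f)] for f in range(6)]
        feats = [f1.reshape(1, -1)] * 3 + [f2.reshape(1, -1)] + [f1.reshape(1, -1)] * 2
        res = run_tracker(frames, feats)
        assert res.count == 1
        assert all(len(r.new_track_ids) == 0 for r in res.reports[1:])

    def test_count_non_decreasing_and_matches_confirmations(self, noiseless_run):
        res, truth = noiseless_run
        counts = [r.cumulative_count for r in res.reports]
        assert counts == sorted(counts)
        assert res.count == len(res.confirmation_events)
        assert res.count == truth.true_count

    def test_no_double_association_per_frame(self, noiseless_run):
        res, _ = noiseless_run
        for r in res.reports:
            tids = [t for t, _ in r.matches]
            djs = [j for _, j in r.matches]
            assert len(tids) == len(set(tids))
            assert len(djs) == len(set(djs))

    def test_empty_input(self):
        assert run_tracker([], []).count == 0
        assert run_tracker([[], [], []], [np.zeros((0, 4))] * 3).count == 0

    def test_deterministic(self):
        from conftest import make_scene, run_scene

        cfg = make_scene(n_fruits=10, n_frames=100, seed=9)
        res_a, _ = run_scene(cfg)
        res_b, _ = run_scene(cfg)
        assert res_a.count == res_b.count
        assert res_a.confirmation_events == res_b.confirmation_events
        assert res_a.mot_rows == res_b.mot_rows


class TestTrackerContracts:
    def test_feature_length_mismatch(self):
        tracker = Tracker()
        with pytest.raises(ValueError):
            tracker.step([det()], np.zeros((2, 8)))

    def test_track_ids_sequential_from_one(self):
        frames = [[det(cx=100), det(cx=600)]]
        feats = [np.vstack([unit([1, 0, 0]), unit([0, 1, 0])])]
        res = run_tracker(frames, feats)
        assert sorted(res.reports[0].new_track_ids) == [1, 2]

    def test_deleted_track_never_rejoins(self):
        cfg = TrackerConfig(max_age=2)
        f = unit(np.arange(1, 9))
        frames, feats = steady_scene(4, step=0.0, feature=f)
        frames += [[] for _ in range(3)]
        feats += [np.zeros((0, 16)) for _ in range(3)]
        frames += [[det(cx=100.0)]]
        feats += [f.reshape(1, -1)]
        res = run_tracker(frames, feats, cfg)
        # the reappearance must be a new track id
        assert res.reports[-1].new_track_ids == [2]
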