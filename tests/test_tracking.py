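"""Tracking: geometry, NMS, Kalman prediction, association, lifecycle."""

import dataclasses
import itertools

import numpy as np
import pytest

from paniclepheno import (Detection, TrackerParams, associate, iou, nms,
                          tracking_accuracy, track_stream)
from paniclepheno.errors import (DeletedTrackError, EmptyFrameError,
                                 InvalidBoxError, MissingDayError)
from paniclepheno.synthetic_scene import (DetectionStream, SamplingSchedule,
                                          build_schedule)
from paniclepheno.tracking import (BoxKalman, Track, TrackState,
                                   min_cost_assignment, predict)


def det(box, conf=0.9, vf=0.1, src=None):
    return Detection(box=box, confidence=conf, vf_prob=vf, source_panicle_id=src)


class TestIoU:
    def test_identity_and_disjoint(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
        assert iou((0, 0, 10, 10), (20, 20, 5, 5)) == 0.0

    def test_partial_overlap_by_inclusion_exclusion(self):
        # intersection 1x2=2, union 4+4-2=6
        assert iou((0, 0, 2, 2), (1, 0, 2, 2)) == pytest.approx(1 / 3)

    def test_symmetry(self):
        a, b = (0, 0, 4, 3), (2, 1, 5, 5)
        assert iou(a, b) == iou(b, a)

    def test_non_positive_dimensions_rejected(self):
        with pytest.raises(InvalidBoxError):
            iou((0, 0, 0, 5), (0, 0, 1, 1))


class TestNMS:
    def test_duplicate_suppression_keeps_highest_confidence(self):
        a = det((0, 0, 10, 10), conf=0.9)
        b = det((0, 0, 10, 10), conf=0.8)
        assert nms([b, a], 0.5) == [a]

    def test_disjoint_boxes_all_survive(self):
        a, b = det((0, 0, 5, 5)), det((50, 50, 5, 5), conf=0.4)
        assert nms([a, b], 0.5) == [a, b]

    def test_chain_suppression_matches_greedy_rule(self):
        # A overlaps B, B overlaps C, A and C disjoint enough; conf A>B>C.
        a = det((0, 0, 10, 10), conf=0.9)
        b = det((6, 0, 10, 10), conf=0.8)
        c = det((12, 0, 10, 10), conf=0.7)
        tau = 0.2
        assert iou(a.box, b.box) > tau and iou(b.box, c.box) > tau
        assert iou(a.box, c.box) < tau
        assert nms([a, b, c], tau) == [a, c]

    def test_confidence_tie_keeps_earlier_input(self):
        a = det((0, 0, 10, 10), conf=0.8)
        b = det((1, 0, 10, 10), conf=0.8)
        assert nms([a, b], 0.3) == [a]


class TestKalman:
    def test_stationary_fixed_point(self):
        kf = BoxKalman((10, 20, 30, 40))
        before = kf.box
        kf.predict()
        assert kf.box == pytest.approx(before)

    def test_velocity_advances_centre_linearly(self):
        kf = BoxKalman((0, 0, 10, 10))
        kf.x[4] = 5.0  # vx px/frame
        kf.predict()
        assert kf.x[0] == pytest.approx(10.0)  # cx was 5
        kf.predict()
        assert kf.x[0] == pytest.approx(15.0)

    def test_update_pulls_state_towards_measurement(self):
        kf = BoxKalman((0, 0, 10, 10))
        kf.update((100, 0, 10, 10))
        assert 5 < kf.x[0] < 105

    def test_predict_on_deleted_track_rejected(self):
        t = Track(track_id=0, kf=BoxKalman((0, 0, 5, 5)), state=TrackState.DELETED)
        with pytest.raises(DeletedTrackError):
            predict(t)


class TestAssociate:
    def _track(self, box, tid=0):
        return Track(track_id=tid, kf=BoxKalman(box), state=TrackState.CONFIRMED)

    def test_single_feasible_pair_matches(self):
        t = self._track((0, 0, 10, 10))
        d = det((0, 0, 10, 8))  # IoU 0.8
        m, ut, ud = associate([t], [d], TrackerParams(max_iou_distance=0.7))
        assert m == [(0, 0)] and not ut and not ud

    def test_gate_forbids_weak_overlap(self):
        t = self._track((0, 0, 10, 10))
        d = det((8, 8, 10, 10))  # IoU ~0.01, cost ~0.99 > 0.7
        m, ut, ud = associate([t], [d], TrackerParams(max_iou_distance=0.7))
        assert m == [] and ut == [0] and ud == [0]

    def test_two_by_two_picks_global_minimum(self):
        # cost matrix [[0.1, 0.5], [0.4, 0.2]] -> diagonal, total 0.3
        m = min_cost_assignment(np.array([[0.1, 0.5], [0.4, 0.2]]))
        assert m == [(0, 0), (1, 1)]

    def test_empty_sides(self):
        t = self._track((0, 0, 10, 10))
        assert associate([], [det((0, 0, 1, 1))], TrackerParams()) == ([], [], [0])
        assert associate([t], [], TrackerParams()) == ([], [0], [])

    def test_hungarian_equals_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n, m = (int(v) for v in rng.integers(1, 7, size=2))
            cost = rng.random((n, m))
            got = min_cost_assignment(cost)
            total = sum(cost[r, c] for r, c in got)
            k = min(n, m)
            best = min(
                sum(cost[r, c] for r, c in zip(rows, cols))
                for rows in itertools.permutations(range(n), k)
                for cols in itertools.permutations(range(m), k))
            assert total == pytest.approx(best)


def _stream_from_frames(day, frames):
    """frames: list of detection lists, one per minute 0, 10, 20, ..."""
    minutes = tuple(10 * i for i in range(len(frames)))
    sched = SamplingSchedule(mode="dense", timestamps=minutes, days=(day,))
    return DetectionStream(schedule=sched,
                           frames={(day, m): f for m, f in zip(minutes, frames)})


class TestTrackStream:
    def test_static_panicles_yield_one_track_each(self):
        boxes = [(0, 0, 50, 50), (200, 0, 50, 50), (0, 200, 50, 50)]
        frames = [[det(b, src=i) for i, b in enumerate(boxes)] for _ in range(8)]
        ts = track_stream(_stream_from_frames(60, frames), 60)
        confirmed = ts.confirmed()
        assert len(confirmed) == 3
        for tr in confirmed:
            assert len(tr.history) == 8
            assert all(e.matched for e in tr.history)

    def test_short_dropout_keeps_identity(self):
        b = (0, 0, 50, 50)
        frames = [[det(b)]] * 3 + [[]] * 2 + [[det(b)]] * 3
        ts = track_stream(_stream_from_frames(60, frames),
                          60, TrackerParams(max_age=5))
        assert len(ts.confirmed()) == 1
        assert ts.confirmed()[0].history[-1].matched

    def test_long_dropout_spawns_new_identity(self):
        b = (0, 0, 50, 50)
        frames = [[det(b)]] * 2 + [[]] * 4 + [[det(b)]] * 2
        ts = track_stream(_stream_from_frames(60, frames),
                          60, TrackerParams(max_age=3))
        ids = sorted(t.track_id for t in ts.tracks)
        assert len(ids) == 2 and ids[0] < ids[1]
        states = {t.track_id: t.state for t in ts.tracks}
        assert states[ids[0]] is TrackState.DELETED

    def test_low_confidence_detections_are_ignored(self):
        frames = [[det((0, 0, 50, 50), conf=0.1)]] * 4
        ts = track_stream(_stream_from_frames(60, frames),
                          60, TrackerParams(min_confidence=0.25))
        assert ts.confirmed() == []

    def test_missing_day_rejected(self):
        ts = _stream_from_frames(60, [[det((0, 0, 5, 5))]])
        with pytest.raises(MissingDayError):
            track_stream(ts, 61)

    def test_no_detection_double_assignment(self, n300_clean_scene, n300_clean_tracks):
        _cfg, _truth, stream = n300_clean_scene
        for ts in n300_clean_tracks[:4]:
            for minute in ts.minutes:
                claimed = [id(e.detection) for t in ts.tracks
                           for e in t.history
                           if e.minute == minute and e.matched]
                assert len(claimed) == len(set(claimed))


class TestTrackingAccuracy:
    def test_noise_free_scene_is_perfect(self, n300_clean_scene, n300_clean_tracks):
        _cfg, truth, _stream = n300_clean_scene
        for ts in n300_clean_tracks:
            if any(t.visible(ts.day) for t in truth):
                assert tracking_accuracy(ts, truth) == 1.0

    def test_ratio_counts_only_continuously_tracked(self, n300_clean_scene):
        _cfg, truth, stream = n300_clean_scene
        day = 66
        ts = track_stream(stream, day)
        # sabotage: retag the entries of one track mid-day -> ID switch
        victim = ts.confirmed()[0]
        switch_at = ts.minutes[len(ts.minutes) // 2]
        clone = dataclasses.replace  # noqa: F841 (readability)
        new_id = max(t.track_id for t in ts.tracks) + 1
        tail = [e for e in victim.history if e.minute >= switch_at]
        head = [e for e in victim.history if e.minute < switch_at]
        victim.history = head
        ts.tracks.append(Track(track_id=new_id, kf=victim.kf,
                               state=TrackState.CONFIRMED, history=tail))
        n_visible = sum(1 for t in truth if t.visible(day))
        acc = tracking_accuracy(ts, truth)
        assert acc == pytest.approx((n_visible - 1) / n_visible)

    def test_empty_first_frame_rejected(self, n300_clean_tracks):
        with pytest.raises(EmptyFrameError):
            tracking_accuracy(n300_clean_tracks[0], [], day=58)

    def test_accuracy_degrades_with_jitter(self):
        import paniclepheno as pp
        accs = {}
        for jitter in (0.0, 25.0):
            vals = []
            for seed in range(10):
                cfg = dataclasses.replace(pp.noise_free(pp.CALIBRATIONS["N240"]),
                                          seed=seed, box_jitter_sd=jitter)
                truth = pp.simulate_population(cfg)
                sched = build_schedule("dense", [66])
                stream = pp.render_detections(truth, sched, cfg)
                vals.append(tracking_accuracy(track_stream(stream, 66), truth))
            accs[jitter] = np.mean(vals)
        assert accs[25.0] <= accs[0.0] == 1.0
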