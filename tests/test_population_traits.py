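"""Plot-level phenology: counts, plateau, heading dates, flowering window."""

import dataclasses

import pytest

from paniclepheno import (CALIBRATIONS, DailyCounts, build_schedule,
                          cumulative_flowering, daily_counts,
                          flowering_counts, flowering_duration, heading_dates,
                          noise_free, render_detections, simulate_population,
                          stable_panicle_number, vft_group)
from paniclepheno.errors import NoFloweringError, NoPlateauError
from paniclepheno.synthetic_scene import (Detection, DetectionStream,
                                          SamplingSchedule)


def _stream(day_frames: dict[int, list[int]], vigorous: dict[tuple[int, int], int] | None = None):
    """Stream with the given per-day per-frame detection counts.

    ``day_frames[dat]`` lists total detections per frame; ``vigorous`` maps
    (dat, frame_index) to how many of them are vigorous.
    """
    vigorous = vigorous or {}
    days = tuple(sorted(day_frames))
    n_frames = max(len(v) for v in day_frames.values())
    minutes = tuple(60 * i for i in range(n_frames))
    frames = {}
    for dat, counts in day_frames.items():
        for fi, count in enumerate(counts):
            n_vig = vigorous.get((dat, fi), 0)
            dets = []
            for j in range(count):
                vf = 0.9 if j < n_vig else 0.1
                dets.append(Detection(box=(200.0 * j, 0, 50, 50),
                                      confidence=0.9, vf_prob=vf))
            frames[(dat, minutes[fi])] = dets
    sched = SamplingSchedule(mode="hourly", timestamps=minutes, days=days)
    return DetectionStream(schedule=sched, frames=frames)


class TestDailyCounts:
    def test_constant_counts(self):
        s = _stream({60: [10] * 9, 61: [10] * 9})
        c = daily_counts(s)
        assert c.pn == {60: 10.0, 61: 10.0}

    def test_mean_and_median_of_a_ramp(self):
        s = _stream({60: [8, 9, 10, 11, 12, 13, 14, 15, 16]})
        c = daily_counts(s)
        assert c.pn[60] == 12.0 and c.median[60] == 12.0

    def test_empty_day_counts_zero(self):
        s = _stream({60: [0] * 9})
        assert daily_counts(s).pn[60] == 0.0


class TestStablePanicleNumber:
    def test_plateau_mean(self):
        c = DailyCounts(per_day={d: [v] for d, v in
                                 zip(range(58, 64), [2, 10, 20, 23, 23, 23])})
        # plateau = days with pn >= 0.95 * 23 = 21.85
        assert stable_panicle_number(c) == pytest.approx(23.0)

    def test_constant_curve_is_its_own_plateau(self):
        c = DailyCounts(per_day={d: [23.11] for d in range(58, 64)})
        assert stable_panicle_number(c) == pytest.approx(23.11)

    def test_sharp_final_rise_gives_single_day_plateau(self):
        c = DailyCounts(per_day={d: [v] for d, v in
                                 zip(range(58, 63), [1, 2, 3, 4, 100])})
        assert stable_panicle_number(c) == pytest.approx(100.0)

    def test_all_zero_counts_rejected(self):
        c = DailyCounts(per_day={58: [0], 59: [0], 60: [0]})
        with pytest.raises(NoPlateauError):
            stable_panicle_number(c)


class TestHeadingDates:
    def test_mean_and_median_rule_trace(self):
        # (pn, median) per day; stable 20 -> levels 2 / 10 / 16
        per_day = {1: [1, 1, 1], 2: [2, 2, 5], 3: [10, 10, 13],
                   4: [17, 17, 17], 5: [20, 20, 20]}
        c = DailyCounts(per_day=per_day)
        assert c.pn[2] == pytest.approx(3.0) and c.median[2] == 2.0
        r = heading_dates(c, stable=20)
        assert (r.initial_heading, r.heading, r.full_heading) == (2, 3, 4)
        assert r.heading_duration == 2

    def test_never_crossed_thresholds_are_none(self):
        c = DailyCounts(per_day={58: [1], 59: [1]})
        r = heading_dates(c, stable=100)
        assert r.initial_heading is None and r.heading is None and r.full_heading is None

    def test_ordering_invariant_on_simulated_scenes(self, hourly_schedule):
        for seed in range(10):
            cfg = dataclasses.replace(CALIBRATIONS["N270"], seed=seed)
            truth = simulate_population(cfg)
            stream = render_detections(truth, hourly_schedule, cfg)
            c = daily_counts(stream)
            r = heading_dates(c, stable_panicle_number(c))
            dates = [d for d in (r.initial_heading, r.heading, r.full_heading)
                     if d is not None]
            assert dates == sorted(dates)

    def test_noise_free_heading_is_half_emergence_day(self, hourly_schedule):
        for seed in (0, 1, 2):
            cfg = dataclasses.replace(noise_free(CALIBRATIONS["N300"]), seed=seed)
            truth = simulate_population(cfg)
            stream = render_detections(truth, hourly_schedule, cfg)
            c = daily_counts(stream)
            r = heading_dates(c, stable_panicle_number(c))
            expected = min(d for d in hourly_schedule.days
                           if sum(1 for t in truth if t.emergence_dat <= d)
                           >= 0.5 * len(truth))
            assert r.heading == expected


class TestFloweringCounts:
    def test_fn_is_daily_max_of_vigorous_counts(self):
        s = _stream({60: [6] * 5}, vigorous={(60, 0): 0, (60, 1): 2, (60, 2): 5,
                                             (60, 3): 3, (60, 4): 0})
        f = flowering_counts(s)
        assert f.fn[60] == 5

    def test_suppressed_day_has_zero_fn(self):
        s = _stream({63: [6] * 5})
        assert flowering_counts(s).fn[63] == 0

    def test_tied_frames_keep_the_max(self):
        s = _stream({60: [6] * 3}, vigorous={(60, i): 4 for i in range(3)})
        assert flowering_counts(s).fn[60] == 4


class TestFloweringDuration:
    @pytest.mark.parametrize("start,end,days", [(59, 70, 12), (60, 69, 10),
                                                (60, 68, 9)])
    def test_inclusive_day_count(self, start, end, days):
        fn = {d: (1 if start <= d <= end else 0) for d in range(58, 72)}
        assert flowering_duration(fn) == (start, end, days)

    def test_single_flowering_day(self):
        assert flowering_duration({60: 0, 61: 3, 62: 0}) == (61, 61, 1)

    def test_no_flowering_rejected(self):
        with pytest.raises(NoFloweringError):
            flowering_duration({60: 0, 61: 0})


class TestVftGroup:
    def test_unique_peak_minute(self):
        vig = {(62, i): v for i, v in enumerate([0, 1, 3, 7, 2])}
        s = _stream({62: [8] * 5}, vigorous=vig)
        # frames at 0,60,...; peak at frame 3 -> minute 180
        assert vft_group(s, 62) == 180

    def test_tie_broken_by_earliest_frame(self):
        vig = {(62, 1): 5, (62, 3): 5}
        s = _stream({62: [8] * 5}, vigorous=vig)
        assert vft_group(s, 62) == 60

    def test_single_nonzero_frame(self):
        s = _stream({62: [8] * 5}, vigorous={(62, 4): 1})
        assert vft_group(s, 62) == 240

    def test_no_vigorous_day_returns_none(self):
        s = _stream({62: [8] * 5})
        assert vft_group(s, 62) is None


class TestCumulativeFlowering:
    def test_prefix_sum(self):
        vig = {(60, i): v for i, v in enumerate([1, 2, 0, 3])}
        s = _stream({60: [5] * 4}, vigorous=vig)
        cum = cumulative_flowering(s)
        assert list(cum.values()) == [1, 3, 3, 6]

    def test_all_zero_stream(self):
        s = _stream({60: [5] * 4})
        assert set(cumulative_flowering(s).values()) == {0}

    def test_dominance_orders_curves(self):
        lo = _stream({60: [5] * 4}, vigorous={(60, i): 1 for i in range(4)})
        hi = _stream({60: [5] * 4}, vigorous={(60, i): 3 for i in range(4)})
        clo, chi = cumulative_flowering(lo), cumulative_flowering(hi)
        assert all(chi[k] >= clo[k] for k in clo)

    def test_fn_never_exceeds_frame_detection_count(self, n300_clean_scene):
        _cfg, _truth, stream = n300_clean_scene
        f = flowering_counts(stream)
        c = daily_counts(stream)
        for d in stream.schedule.days:
            assert f.fn[d] <= max(c.per_day[d])
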