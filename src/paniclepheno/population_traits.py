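"""Plot-level heading and flowering phenology from a detection stream.

The daily panicle number ``pn`` is the mean per-frame detection count over a
day's sampled frames; its plateau mean is the stable panicle number.
Heading dates are threshold crossings of the count curve at 10% (initial
heading), 50% (heading) and 80% (full heading) of the stable number, where a
day crosses only when both the day's mean and median counts reach the
threshold — the box-plot rule used in field practice, which keeps a single
outlier frame from declaring heading.  The daily flowering panicle number
``fn`` is the day's maximum per-frame count of vigorous-flowering boxes, the
group vigorous-flowering time ``VFT_g`` the frame minute at which that count
peaks, and the flowering duration the inclusive day span from first to last
flowering day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median as _median

from .errors import NoFloweringError, NoPlateauError
from .synthetic_scene import DetectionStream
from .tracking import nms

DEFAULT_MIN_CONFIDENCE = 0.25
DEFAULT_NMS_MAX_OVERLAP = 0.7
DEFAULT_VF_THRESHOLD = 0.5


@dataclass
class DailyCounts:
    """Per-frame panicle counts per day; means/medians derive on demand."""

    per_day: dict[int, list[int]]

    @property
    def pn(self) -> dict[int, float]:
        return {d: (sum(c) / len(c) if c else 0.0) for d, c in self.per_day.items()}

    @property
    def median(self) -> dict[int, float]:
        return {d: (float(_median(c)) if c else 0.0) for d, c in self.per_day.items()}


@dataclass
class HeadingReport:
    """Stable panicle number and the three heading-date crossings."""

    stable_number: float
    initial_heading: int | None
    heading: int | None
    full_heading: int | None

    @property
    def heading_duration(self) -> int | None:
        """Days from initial to full heading (difference, not inclusive)."""
        if self.initial_heading is None or self.full_heading is None:
            return None
        return self.full_heading - self.initial_heading


@dataclass
class FloweringSummary:
    """Daily flowering counts, peak times and the flowering window."""

    fn: dict[int, int]
    vft_g: dict[int, int | None]
    duration_start: int | None = None
    duration_end: int | None = None
    cumulative: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def duration_days(self) -> int | None:
        if self.duration_start is None or self.duration_end is None:
            return None
        return self.duration_end - self.duration_start + 1


def _frame_counts(stream: DetectionStream, min_confidence: float,
                  nms_max_overlap: float):
    """Post-filter detection lists per frame, in chronological order."""
    for dat in stream.schedule.days:
        for minute in stream.schedule.timestamps:
            dets = [d for d in stream.frame(dat, minute)
                    if d.confidence >= min_confidence]
            yield dat, minute, nms(dets, nms_max_overlap)


def daily_counts(stream: DetectionStream, *,
                 min_confidence: float = DEFAULT_MIN_CONFIDENCE,
                 nms_max_overlap: float = DEFAULT_NMS_MAX_OVERLAP) -> DailyCounts:
    """Per-frame post-NMS panicle counts, grouped by day."""
    per_day: dict[int, list[int]] = {d: [] for d in stream.schedule.days}
    for dat, _minute, dets in _frame_counts(stream, min_confidence, nms_max_overlap):
        per_day[dat].append(len(dets))
    return DailyCounts(per_day=per_day)


def stable_panicle_number(counts: DailyCounts, *, plateau_frac: float = 0.95) -> float:
    """Mean daily count over the plateau of the count curve.

    The plateau runs from the first day whose mean count reaches
    ``plateau_frac`` of the maximum daily mean through the last observed day.
    """
    pn = counts.pn
    if not pn or max(pn.values()) <= 0:
        raise NoPlateauError("all-zero counts: no plateau to average")
    days = sorted(pn)
    peak = max(pn.values())
    onset = next(d for d in days if pn[d] >= plateau_frac * peak)
    plateau = [pn[d] for d in days if d >= onset]
    return sum(plateau) / len(plateau)


def heading_dates(counts: DailyCounts, stable: float,
                  fractions: tuple[float, float, float] = (0.10, 0.50, 0.80),
                  ) -> HeadingReport:
    """Threshold crossings of the count curve at the heading fractions.

    A fraction ``f`` is crossed on the first day whose mean *and* median
    count both reach ``f * stable``; a threshold never reached gives None.
    """
    if stable <= 0:
        raise ValueError("stable panicle number must be positive")
    pn, med = counts.pn, counts.median
    days = sorted(pn)
    crossings = []
    for f in fractions:
        level = f * stable
        day = next((d for d in days if pn[d] >= level and med[d] >= level), None)
        crossings.append(day)
    return HeadingReport(stable_number=stable, initial_heading=crossings[0],
                         heading=crossings[1], full_heading=crossings[2])


def _vigorous_counts(stream: DetectionStream, vf_threshold: float,
                     min_confidence: float, nms_max_overlap: float):
    for dat, minute, dets in _frame_counts(stream, min_confidence, nms_max_overlap):
        yield dat, minute, sum(1 for d in dets if d.vf_prob > vf_threshold)


def flowering_counts(stream: DetectionStream,
                     vf_threshold: float = DEFAULT_VF_THRESHOLD, *,
                     min_confidence: float = DEFAULT_MIN_CONFIDENCE,
                     nms_max_overlap: float = DEFAULT_NMS_MAX_OVERLAP,
                     ) -> FloweringSummary:
    """Daily flowering panicle numbers, peak times and cumulative curve.

    ``fn(day)`` is the maximum per-frame vigorous count; ``vft_g(day)`` the
    earliest frame minute attaining that maximum (None on non-flowering
    days); ``cumulative`` the running sum of per-frame vigorous counts.
    """
    fn: dict[int, int] = {d: 0 for d in stream.schedule.days}
    vft: dict[int, int | None] = {d: None for d in stream.schedule.days}
    cumulative: dict[tuple[int, int], int] = {}
    total = 0
    peak: dict[int, int] = {}
    for dat, minute, v in _vigorous_counts(stream, vf_threshold,
                                           min_confidence, nms_max_overlap):
        total += v
        cumulative[(dat, minute)] = total
        if v > peak.get(dat, 0):
            peak[dat] = v
            vft[dat] = minute
        fn[dat] = max(fn[dat], v)

    flowering_days = [d for d, v in fn.items() if v >= 1]
    start = min(flowering_days) if flowering_days else None
    end = max(flowering_days) if flowering_days else None
    return FloweringSummary(fn=fn, vft_g=vft, duration_start=start,
                            duration_end=end, cumulative=cumulative)


def flowering_duration(summary: FloweringSummary | dict[int, int],
                       min_fn: int = 1) -> tuple[int, int, int]:
    """Inclusive flowering window: (first day, last day, day count).

    ``days = end - start + 1``: a plot flowering DAT 59 through DAT 70
    flowers for 12 days.
    """
    fn = summary.fn if isinstance(summary, FloweringSummary) else summary
    days = [d for d, v in fn.items() if v >= min_fn]
    if not days:
        raise NoFloweringError(f"no day reaches fn >= {min_fn}")
    start, end = min(days), max(days)
    return start, end, end - start + 1


def vft_group(stream: DetectionStream, day: int,
              vf_threshold: float = DEFAULT_VF_THRESHOLD, *,
              min_confidence: float = DEFAULT_MIN_CONFIDENCE,
              nms_max_overlap: float = DEFAULT_NMS_MAX_OVERLAP) -> int | None:
    """Minute of the day's peak vigorous count (earliest frame on ties)."""
    best_minute: int | None = None
    best = 0
    for dat, minute, v in _vigorous_counts(stream, vf_threshold,
                                           min_confidence, nms_max_overlap):
        if dat != day:
            continue
        if v > best:
            best = v
            best_minute = minute
    return best_minute


def cumulative_flowering(stream: DetectionStream,
                         vf_threshold: float = DEFAULT_VF_THRESHOLD, *,
                         min_confidence: float = DEFAULT_MIN_CONFIDENCE,
                         nms_max_overlap: float = DEFAULT_NMS_MAX_OVERLAP,
                         ) -> dict[tuple[int, int], int]:
    """Running total of per-frame vigorous counts over the whole season."""
    return flowering_counts(stream, vf_threshold, min_confidence=min_confidence,
                            nms_max_overlap=nms_max_overlap).cumulative
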