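"""Synthetic panicle populations and noisy detection streams.

A field camera looks straight down on a small paddy plot and photographs it
on a fixed daily schedule through the heading-flowering stage.  A detector
proposes one bounding box per panicle with a confidence, and a classifier
scores each box for "vigorous flowering" (abundant open spikelets).  This
module simulates that whole front end: a latent panicle population with
per-panicle emergence days, multi-day flowering windows and midday-peaked
daily vigorous-flowering intervals, plus a rendering step that turns the
latent state into per-frame detections with misses, false positives, box
jitter and classification errors.

Every downstream stage (tracking, population traits, per-panicle traits,
evaluation) consumes only the rendered :class:`DetectionStream` and, for
scoring, the latent :class:`PanicleGroundTruth` records, so the package is
fully testable without images.

Units: days are DAT (days after transplanting); times are integer minutes
from 08:00; boxes are ``(x_min, y_min, width, height)`` in pixels, origin
top-left, y down.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import reference
from .errors import EmptyScheduleError, SceneLayoutError, UnknownModeError

Box = tuple[float, float, float, float]

#: Resolution (minutes) at which flowering-state transitions are generated.
#: Flowering onset/offset is only observable at the sampling cadence of the
#: dense protocol (10 min over midday), so the generator quantises interval
#: endpoints to this grid; see docs/methods.md.
FLOWERING_TIME_QUANTUM = 10

#: Annotation floor: panicles smaller than 20x20 px are not annotated.
MIN_BOX_SIDE = 20.0


# ---------------------------------------------------------------------------
# Sampling schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingSchedule:
    """Daily image-sampling protocol for one plot-season.

    ``hourly`` is the 9-frame protocol (one frame per hour, 08:00-16:00)
    used for counting and heading-date work; ``dense`` is the 41-frame
    protocol (15-min cadence on 08:00-10:00 and 14:00-16:00, 10-min cadence
    on 10:00-14:00) used for tracking and flowering-time work.
    """

    mode: str
    timestamps: tuple[int, ...]
    days: tuple[int, ...]

    def frame_keys(self):
        """All (day, minute) keys in chronological order."""
        return [(d, m) for d in self.days for m in self.timestamps]


def build_schedule(mode: str, days) -> SamplingSchedule:
    """Build the hourly (9 frames/day) or dense (41 frames/day) schedule.

    Frame times are the nominal grid instants; the within-hour randomness of
    the original acquisition is dropped for reproducibility.
    """
    days = tuple(int(d) for d in days)
    if not days:
        raise EmptyScheduleError("schedule needs at least one day")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")
    if mode == "hourly":
        ts = tuple(range(0, 481, 60))
    elif mode == "dense":
        grid = set(range(0, 121, 15)) | set(range(120, 361, 10)) | set(range(360, 481, 15))
        ts = tuple(sorted(grid))
    else:
        raise UnknownModeError(f"unknown sampling mode {mode!r}")
    return SamplingSchedule(mode=mode, timestamps=ts, days=days)


# ---------------------------------------------------------------------------
# Scene configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Latent-population and noise parameters for one simulated plot-season.

    The flowering block (``flowering_days_*``, ``vft_center_*``, ``dbe_*``)
    describes per-panicle behaviour: each panicle flowers on a run of
    consecutive days starting ``flowering_lag`` days after it emerges, and on
    each flowering day shows one contiguous vigorous interval whose centre
    and width are drawn per day.  Detection noise (``detect_recall``,
    ``detect_precision_fp_rate``) is calibrated near the published detector
    validation accuracy; see :data:`paniclepheno.reference.DETECTION_ACCURACY`.
    """

    n_panicles: int = 28
    emergence_mean_dat: float = 62.0
    emergence_sd: float = 1.5
    flowering_lag_mean: float = 0.5
    flowering_lag_sd: float = 0.5
    flowering_days_mean: float = 4.0
    flowering_days_sd: float = 0.6
    vft_center_mean: float = 255.0
    vft_center_sd: float = 25.0
    dbe_mean: float = 94.0
    dbe_sd: float = 28.0
    suppressed_days: frozenset[int] = frozenset()
    detect_recall: float = 1.0
    detect_precision_fp_rate: float = 0.0
    class_error_rate: float = 0.0
    box_jitter_sd: float = 0.0
    frame_size: tuple[int, int] = (1500, 1000)
    px_per_cm: float = 71.0
    row_spacing_cm: float = 2.8
    col_spacing_cm: float = 2.8
    dat_start: int = 58
    dat_end: int = 71
    seed: int = 0

    def __post_init__(self):
        for name in ("detect_recall", "class_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("emergence_sd", "flowering_lag_sd", "flowering_days_sd",
                     "vft_center_sd", "dbe_sd", "box_jitter_sd",
                     "detect_precision_fp_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_panicles < 0:
            raise ValueError("n_panicles must be non-negative")
        if self.frame_size[0] <= 0 or self.frame_size[1] <= 0:
            raise ValueError("frame_size must be positive")
        if self.dat_end < self.dat_start:
            raise ValueError("dat_end must be >= dat_start")
        object.__setattr__(self, "suppressed_days", frozenset(self.suppressed_days))


def _calibration(treatment: str, plateau: int, heading: dict, flowering: dict | None,
                 suppressed: frozenset[int]) -> SceneConfig:
    # Emergence centre = observed heading (50% crossing) day; spread chosen so
    # the 10% crossing lands near the observed initial heading date.
    kw = dict(
        n_panicles=plateau,
        emergence_mean_dat=float(heading["heading_observed"]),
        emergence_sd=1.5,
        suppressed_days=suppressed,
        detect_recall=0.86,
        detect_precision_fp_rate=2.5,
        class_error_rate=0.045,
        box_jitter_sd=3.0,
    )
    if flowering is not None:
        dbe_mean, dbe_sd = flowering["daily_dbe"]
        vft_mean, vft_sd = flowering["vft_p"]
        kw.update(
            flowering_days_mean=flowering["fds"][0],
            flowering_days_sd=flowering["fds"][1],
            # The observed VFT_p is the *start* of the daily vigorous interval;
            # the generator draws the interval centre, so shift by half a span.
            vft_center_mean=vft_mean + dbe_mean / 2.0,
            vft_center_sd=vft_sd,
            dbe_mean=dbe_mean,
            dbe_sd=dbe_sd,
            flowering_lag_mean=max(0.0, flowering["fdat"][0] - kw["emergence_mean_dat"] + 1.0),
            flowering_lag_sd=0.7,
        )
    return SceneConfig(**kw)


def _build_calibrations() -> dict[str, SceneConfig]:
    plateaus = {"N150": 23, "N300": 31, "N270": 28, "N240": 27}
    out = {}
    for t in reference.TREATMENTS:
        flowering = reference.SINGLE_PANICLE_TABLE.get(t)
        if flowering is None:  # N150: single-panicle stats were not published
            flowering = {
                k: (float(np.mean([v[k][0] for v in reference.SINGLE_PANICLE_TABLE.values()])),
                    float(np.mean([v[k][1] for v in reference.SINGLE_PANICLE_TABLE.values()])))
                for k in ("fdat", "fds", "vft_p", "total_dbe", "daily_dbe")
            }
            flowering["fdat"] = (61.5, 1.4)
        out[t] = _calibration(t, plateaus[t], reference.HEADING_TABLE[t],
                              flowering, reference.SUPPRESSED_DAYS[t])
    return out


#: Packaged per-treatment calibrations (plateau counts 23/31/28/27 and the
#: published single-panicle flowering statistics where available).
CALIBRATIONS: dict[str, SceneConfig] = _build_calibrations()


# ---------------------------------------------------------------------------
# Latent ground truth
# ---------------------------------------------------------------------------

@dataclass
class PanicleGroundTruth:
    """Latent state of one panicle: emergence, flowering windows, trajectory.

    ``daily_intervals`` maps each flowering DAT to the contiguous vigorous
    interval ``(vf_start_min, vf_end_min)`` on that day.  ``fdat_true`` and
    ``flowering_days_true`` describe the flowering window *before* any
    weather suppression; suppressed days are simply absent from
    ``daily_intervals``.
    """

    panicle_id: int
    emergence_dat: int
    fdat_true: int
    flowering_days_true: int
    daily_intervals: dict[int, tuple[int, int]]
    base_box: Box
    growth_per_day: float = 0.05
    growth_cap: float = 1.4
    frame_size: tuple[int, int] = (1500, 1000)

    def box_at(self, dat: int, minute: int = 0) -> Box:
        """True box on a given frame: fixed centre, slow linear growth."""
        x, y, w, h = self.base_box
        scale = min(1.0 + self.growth_per_day * max(0, dat - self.emergence_dat),
                    self.growth_cap)
        cx, cy = x + w / 2.0, y + h / 2.0
        w2, h2 = w * scale, h * scale
        fw, fh = self.frame_size
        nx = min(max(cx - w2 / 2.0, 0.0), fw - w2)
        ny = min(max(cy - h2 / 2.0, 0.0), fh - h2)
        return (nx, ny, w2, h2)

    def visible(self, dat: int) -> bool:
        return dat >= self.emergence_dat

    def flowering(self, dat: int, minute: int) -> bool:
        iv = self.daily_intervals.get(dat)
        return iv is not None and iv[0] <= minute <= iv[1]


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Detection:
    """One detector output box with confidence and flowering-class score."""

    box: Box
    confidence: float
    vf_prob: float
    source_panicle_id: int | None = None

    def __post_init__(self):
        if self.box[2] <= 0 or self.box[3] <= 0:
            raise ValueError("detection box must have positive width and height")
        if not (0.0 <= self.confidence <= 1.0 and 0.0 <= self.vf_prob <= 1.0):
            raise ValueError("confidence and vf_prob must lie in [0, 1]")

    @property
    def vigorous(self) -> bool:
        return self.vf_prob > 0.5


@dataclass
class DetectionStream:
    """Ordered per-frame detection sets for one plot-season."""

    schedule: SamplingSchedule
    frames: dict[tuple[int, int], list[Detection]] = field(default_factory=dict)

    def frame(self, dat: int, minute: int) -> list[Detection]:
        return self.frames.get((dat, minute), [])

    def day_frames(self, dat: int) -> list[tuple[int, list[Detection]]]:
        return [(m, self.frame(dat, m)) for m in self.schedule.timestamps]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _quantise_interval(center: float, width: float) -> tuple[int, int]:
    q = FLOWERING_TIME_QUANTUM
    start = q * round((center - width / 2.0) / q)
    end = q * round((center + width / 2.0) / q)
    start = int(min(max(start, 0), 600))
    end = int(min(max(end, start), 600))
    return start, end


def simulate_population(config: SceneConfig) -> list[PanicleGroundTruth]:
    """Draw the latent panicle population for one plot-season.

    Emergence days are truncated-normal on the study window; each panicle
    starts flowering ``lag`` days after emergence and flowers for
    ``max(1, round(N(flowering_days_mean, sd)))`` consecutive days.  Each
    flowering day carries one contiguous vigorous interval with normal centre
    and width floored at one observation quantum.  Base boxes sit on a
    planting grid (``row_spacing_cm`` x ``col_spacing_cm`` at ``px_per_cm``)
    with a small per-panicle offset.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    fw, fh = config.frame_size
    dx = config.col_spacing_cm * config.px_per_cm
    dy = config.row_spacing_cm * config.px_per_cm
    n_cols = int(fw // dx)
    n_rows = int(fh // dy)
    if config.n_panicles > 0 and n_cols * n_rows < config.n_panicles:
        raise SceneLayoutError(
            f"grid of {n_rows}x{n_cols} cells cannot hold {config.n_panicles} panicles"
        )

    out: list[PanicleGroundTruth] = []
    for pid in range(config.n_panicles):
        emergence = int(round(float(np.clip(
            rng.normal(config.emergence_mean_dat, config.emergence_sd),
            config.dat_start, config.dat_end))))
        lag = max(0, int(round(rng.normal(config.flowering_lag_mean,
                                          config.flowering_lag_sd))))
        fdat = emergence + lag
        n_days = max(1, int(round(rng.normal(config.flowering_days_mean,
                                             config.flowering_days_sd))))

        intervals: dict[int, tuple[int, int]] = {}
        for d in range(fdat, fdat + n_days):
            center = rng.normal(config.vft_center_mean, config.vft_center_sd)
            width = max(float(FLOWERING_TIME_QUANTUM),
                        rng.normal(config.dbe_mean, config.dbe_sd))
            if d in config.suppressed_days:
                continue  # weather-suppressed: no flowering observable
            intervals[d] = _quantise_interval(center, width)

        row, col = divmod(pid, n_cols)
        cx = (col + 0.5) * dx + rng.normal(0.0, dx / 10.0)
        cy = (row + 0.5) * dy + rng.normal(0.0, dy / 10.0)
        w = max(MIN_BOX_SIDE + 10.0, rng.normal(90.0, 8.0))
        h = max(MIN_BOX_SIDE + 10.0, rng.normal(70.0, 6.0))
        x = float(np.clip(cx - w / 2.0, 0.0, fw - w))
        y = float(np.clip(cy - h / 2.0, 0.0, fh - h))

        out.append(PanicleGroundTruth(
            panicle_id=pid,
            emergence_dat=emergence,
            fdat_true=fdat,
            flowering_days_true=n_days,
            daily_intervals=intervals,
            base_box=(x, y, w, h),
            frame_size=config.frame_size,
        ))
    return out


def render_detections(truth: list[PanicleGroundTruth],
                      schedule: SamplingSchedule,
                      config: SceneConfig) -> DetectionStream:
    """Render the latent population into a noisy per-frame detection stream.

    Each emerged panicle is detected with probability ``detect_recall``; its
    box gets zero-mean normal jitter.  False positives arrive Poisson per
    frame with uniform in-frame positions and sizes drawn from the true box
    size distribution.  ``vf_prob`` lands above 0.5 exactly when the frame
    minute lies inside the panicle's vigorous interval, flipped with
    probability ``class_error_rate``.
    """
    if not schedule.days or not schedule.timestamps:
        raise EmptyScheduleError("cannot render an empty schedule")
    # Independent sub-stream so population and rendering draws do not couple.
    rng = np.random.default_rng([config.seed, 0x5EED])
    fw, fh = config.frame_size
    sizes = [(t.base_box[2], t.base_box[3]) for t in truth] or [(90.0, 70.0)]

    frames: dict[tuple[int, int], list[Detection]] = {}
    for dat in schedule.days:
        for minute in schedule.timestamps:
            dets: list[Detection] = []
            for t in truth:
                if not t.visible(dat):
                    continue
                if rng.random() > config.detect_recall:
                    continue
                x, y, w, h = t.box_at(dat, minute)
                if config.box_jitter_sd > 0:
                    jx, jy = rng.normal(0.0, config.box_jitter_sd, size=2)
                    jw, jh = rng.normal(0.0, config.box_jitter_sd / 2.0, size=2)
                    x, y = x + jx, y + jy
                    w = max(5.0, w + jw)
                    h = max(5.0, h + jh)
                conf = float(rng.uniform(0.55, 0.99))
                inside = t.flowering(dat, minute)
                vf = float(rng.uniform(0.75, 0.99)) if inside else float(rng.uniform(0.01, 0.25))
                if config.class_error_rate > 0 and rng.random() < config.class_error_rate:
                    vf = 1.0 - vf
                dets.append(Detection(box=(x, y, w, h), confidence=conf,
                                      vf_prob=vf, source_panicle_id=t.panicle_id))
            n_fp = int(rng.poisson(config.detect_precision_fp_rate))
            for _ in range(n_fp):
                w, h = sizes[int(rng.integers(len(sizes)))]
                x = float(rng.uniform(0.0, max(1e-6, fw - w)))
                y = float(rng.uniform(0.0, max(1e-6, fh - h)))
                conf = float(rng.uniform(0.25, 0.75))
                dets.append(Detection(box=(x, y, w, h), confidence=conf,
                                      vf_prob=float(rng.uniform(0.01, 0.25)),
                                      source_panicle_id=None))
            frames[(dat, minute)] = dets
    return DetectionStream(schedule=schedule, frames=frames)


def emerged_count_curve(truth: list[PanicleGroundTruth], days) -> dict[int, int]:
    """Cumulative emerged-panicle count per day (non-decreasing)."""
    return {d: sum(1 for t in truth if t.emergence_dat <= d) for d in days}


def noise_free(config: SceneConfig) -> SceneConfig:
    """Copy of a config with all detection/classification noise switched off."""
    return replace(config, detect_recall=1.0, detect_precision_fp_rate=0.0,
                   class_error_rate=0.0, box_jitter_sd=0.0)
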