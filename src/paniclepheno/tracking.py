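"""Within-day tracking-by-detection for panicle identity resolution.

Detections from consecutive frames of one day are linked into identity
tracks with the classic recipe: confidence filtering and greedy NMS, a
constant-velocity Kalman filter per track to predict where each panicle's
box will be in the next frame, and a Hungarian (minimum-cost) assignment on
the ``1 - IoU`` cost between predicted and detected boxes.  Appearance
embeddings are deliberately not used: the scene is a fixed nadir camera over
a planted grid, so spatial overlap alone resolves identity, and the
association gate ``max_iou_distance`` plus the ``max_age`` miss budget
handle short detector dropouts.

Tracking is per day only.  Panicles move too much overnight for overlap
association to survive the gap, so cross-day identity is resolved separately
(see :func:`paniclepheno.panicle_traits.provenance_id_map`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import (DeletedTrackError, EmptyFrameError, InvalidBoxError,
                     MissingDayError)
from .synthetic_scene import Box, Detection, DetectionStream, PanicleGroundTruth


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two ``(x, y, w, h)`` boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise InvalidBoxError("boxes must have positive width and height")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def iou_matrix(boxes_a: list[Box], boxes_b: list[Box]) -> np.ndarray:
    """Pairwise IoU, vectorised; shape (len(a), len(b))."""
    if not boxes_a or not boxes_b:
        return np.zeros((len(boxes_a), len(boxes_b)))
    a = np.asarray(boxes_a, dtype=float)
    b = np.asarray(boxes_b, dtype=float)
    ax1, ay1 = a[:, 0:1], a[:, 1:2]
    ax2, ay2 = ax1 + a[:, 2:3], ay1 + a[:, 3:4]
    bx1, by1 = b[None, :, 0], b[None, :, 1]
    bx2, by2 = bx1 + b[None, :, 2], by1 + b[None, :, 3]
    iw = np.clip(np.minimum(ax2, bx2) - np.maximum(ax1, bx1), 0.0, None)
    ih = np.clip(np.minimum(ay2, by2) - np.maximum(ay1, by1), 0.0, None)
    inter = iw * ih
    union = (a[:, 2:3] * a[:, 3:4]) + (b[None, :, 2] * b[None, :, 3]) - inter
    return inter / union


def nms(detections: list[Detection], max_overlap: float) -> list[Detection]:
    """Greedy non-maximum suppression.

    Detections are visited in descending confidence (ties keep input order)
    and kept unless they overlap an already-kept box by more than
    ``max_overlap`` IoU.
    """
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    kept: list[int] = []
    for i in order:
        if all(iou(detections[i].box, detections[j].box) <= max_overlap for j in kept):
            kept.append(i)
    kept.sort()
    return [detections[i] for i in kept]


# ---------------------------------------------------------------------------
# Kalman filter (constant velocity on the box centre)
# ---------------------------------------------------------------------------

class BoxKalman:
    """Constant-velocity Kalman filter on ``(cx, cy, w, h, vcx, vcy)``.

    Width and height are tracked as random-walk states without velocities;
    the centre has a velocity pair.  Noise scales with box size, in the SORT
    convention, since no sensor-noise measurements exist for this scene.
    """

    _F = np.eye(6)
    _F[0, 4] = 1.0
    _F[1, 5] = 1.0
    _H = np.eye(4, 6)

    #: Per-unit-size standard deviations (position, velocity).
    _STD_POS = 1.0 / 20.0
    _STD_VEL = 1.0 / 160.0

    def __init__(self, box: Box):
        cx, cy, w, h = box[0] + box[2] / 2.0, box[1] + box[3] / 2.0, box[2], box[3]
        self.x = np.array([cx, cy, w, h, 0.0, 0.0])
        q = (w + h) / 2.0
        std = [2 * self._STD_POS * q] * 4 + [10 * self._STD_VEL * q] * 2
        self.P = np.diag(np.square(std))

    def _size(self) -> float:
        return (self.x[2] + self.x[3]) / 2.0

    def predict(self) -> None:
        q = self._size()
        std = [self._STD_POS * q] * 4 + [self._STD_VEL * q] * 2
        Q = np.diag(np.square(std))
        self.x = self._F @ self.x
        self.P = self._F @ self.P @ self._F.T + Q

    def update(self, box: Box) -> None:
        z = np.array([box[0] + box[2] / 2.0, box[1] + box[3] / 2.0, box[2], box[3]])
        q = self._size()
        R = np.diag(np.square([self._STD_POS * q] * 4))
        S = self._H @ self.P @ self._H.T + R
        K = self.P @ self._H.T @ np.linalg.inv(S)
        self.x = self.x + K @ (z - self._H @ self.x)
        self.P = (np.eye(6) - K @ self._H) @ self.P

    @property
    def box(self) -> Box:
        cx, cy, w, h = self.x[:4]
        w = max(w, 1.0)
        h = max(h, 1.0)
        return (float(cx - w / 2.0), float(cy - h / 2.0), float(w), float(h))


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

class TrackState(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass(frozen=True)
class TrackerParams:
    """Output-filter knobs of the tracking stage.

    Defaults: the confidence floor matches the detector's own threshold
    (0.25); the NMS and association gates are the common SORT settings; a
    track survives up to ``max_age`` consecutive misses; ``n_init`` matched
    frames confirm a track.
    """

    min_confidence: float = 0.25
    nms_max_overlap: float = 0.7
    max_age: int = 5
    max_iou_distance: float = 0.7
    n_init: int = 1

    def __post_init__(self):
        for name in ("min_confidence", "nms_max_overlap", "max_iou_distance"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_age < 0 or self.n_init < 1:
            raise ValueError("max_age must be >= 0 and n_init >= 1")


@dataclass
class TrackEntry:
    """One frame of a track's history."""

    dat: int
    minute: int
    box: Box
    matched: bool
    detection: Detection | None = None


@dataclass
class Track:
    """One identity through a day: Kalman state plus per-frame history."""

    track_id: int
    kf: BoxKalman
    state: TrackState = TrackState.TENTATIVE
    history: list[TrackEntry] = field(default_factory=list)
    misses: int = 0
    hits: int = 0

    def entry_at(self, minute: int) -> TrackEntry | None:
        for e in self.history:
            if e.minute == minute:
                return e
        return None


def predict(track: Track) -> Track:
    """Kalman time-update in place; the history is untouched."""
    if track.state is TrackState.DELETED:
        raise DeletedTrackError(f"track {track.track_id} is deleted")
    track.kf.predict()
    return track


@dataclass
class TrackSet:
    """All tracks of one day plus the frame minutes they were run over."""

    tracks: list[Track]
    params: TrackerParams
    day: int
    minutes: tuple[int, ...] = ()

    def confirmed(self) -> list[Track]:
        return [t for t in self.tracks
                if t.state is not TrackState.TENTATIVE or t.hits >= self.params.n_init]


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

_INFEASIBLE = 1e6


def min_cost_assignment(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-total-cost one-to-one assignment, deterministic tie-break.

    Among cost-equal optima the lexicographically smallest (row, col) set is
    preferred, enforced by an epsilon perturbation far below any real cost
    difference.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return []
    n, m = cost.shape
    eps = 1e-9 / (n * m + 1)
    tie = eps * (np.arange(n)[:, None] * m + np.arange(m)[None, :])
    rows, cols = linear_sum_assignment(cost + tie)
    return sorted(zip(rows.tolist(), cols.tolist()))


def associate(tracks: list[Track], detections: list[Detection],
              params: TrackerParams):
    """Gated Hungarian matching of live tracks to detections.

    Cost is ``1 - IoU`` between each track's predicted box and the detection
    box; pairs with cost above ``max_iou_distance`` are unassignable.
    Returns ``(matches, unmatched_track_idx, unmatched_detection_idx)`` where
    matches pair indices into the two input lists.
    """
    if not tracks or not detections:
        return [], list(range(len(tracks))), list(range(len(detections)))
    cost = 1.0 - iou_matrix([t.kf.box for t in tracks], [d.box for d in detections])
    gated = np.where(cost > params.max_iou_distance, _INFEASIBLE, cost)
    matches = [(r, c) for r, c in min_cost_assignment(gated)
               if gated[r, c] < _INFEASIBLE]
    mt = {r for r, _ in matches}
    md = {c for _, c in matches}
    return (matches,
            [i for i in range(len(tracks)) if i not in mt],
            [j for j in range(len(detections)) if j not in md])


# ---------------------------------------------------------------------------
# The per-day tracker
# ---------------------------------------------------------------------------

def track_stream(stream: DetectionStream, day: int,
                 params: TrackerParams | None = None) -> TrackSet:
    """Run tracking-by-detection over all frames of one day.

    Per frame: confidence filter, NMS, Kalman predict for live tracks,
    gated Hungarian association, measurement update of matched tracks, miss
    bookkeeping (tentative tracks die on their first miss, confirmed ones
    after ``max_age`` consecutive misses), and new tentative tracks from the
    leftover detections.  Deterministic given the input stream.
    """
    params = params or TrackerParams()
    if day not in stream.schedule.days:
        raise MissingDayError(f"day {day} not in stream schedule")

    next_id = 0
    tracks: list[Track] = []
    minutes = tuple(stream.schedule.timestamps)

    for minute in minutes:
        dets = [d for d in stream.frame(day, minute)
                if d.confidence >= params.min_confidence]
        dets = nms(dets, params.nms_max_overlap)

        live = [t for t in tracks if t.state is not TrackState.DELETED]
        for t in live:
            predict(t)

        matches, um_tracks, um_dets = associate(live, dets, params)

        for ti, di in matches:
            t, d = live[ti], dets[di]
            t.kf.update(d.box)
            t.misses = 0
            t.hits += 1
            if t.state is TrackState.TENTATIVE and t.hits >= params.n_init:
                t.state = TrackState.CONFIRMED
            t.history.append(TrackEntry(day, minute, d.box, True, d))

        for ti in um_tracks:
            t = live[ti]
            t.misses += 1
            if t.state is TrackState.TENTATIVE or t.misses > params.max_age:
                t.state = TrackState.DELETED
            else:
                t.history.append(TrackEntry(day, minute, t.kf.box, False, None))

        for di in um_dets:
            d = dets[di]
            t = Track(track_id=next_id, kf=BoxKalman(d.box), hits=1)
            next_id += 1
            if t.hits >= params.n_init:
                t.state = TrackState.CONFIRMED
            t.history.append(TrackEntry(day, minute, d.box, True, d))
            tracks.append(t)

    return TrackSet(tracks=tracks, params=params, day=day, minutes=minutes)


def tracking_accuracy(trackset: TrackSet, truth: list[PanicleGroundTruth],
                      day: int | None = None) -> float:
    """Fraction of first-frame panicles tracked by one ID through the day.

    A panicle visible in the day's first frame counts as correctly tracked
    when a single track reports a box overlapping its true box (IoU >= 0.5)
    in every sampled frame — matched detections and coasted (predicted)
    frames both count, since the track still carries the identity through a
    short detector dropout.  An identity switch mid-day, or a track that
    starts late or dies early, excludes the panicle from the numerator.
    """
    day = trackset.day if day is None else day
    minutes = trackset.minutes
    if not minutes:
        raise EmptyFrameError("trackset covers no frames")
    visible = [t for t in truth if t.visible(day)]
    if not visible:
        raise EmptyFrameError(f"no panicles visible in the first frame of day {day}")

    correct = 0
    for panicle in visible:
        covered_by = None
        ok = True
        for minute in minutes:
            true_box = panicle.box_at(day, minute)
            holder = None
            for tr in trackset.tracks:
                e = tr.entry_at(minute)
                if e is not None and iou(e.box, true_box) >= 0.5:
                    holder = tr.track_id
                    break
            if holder is None or (covered_by is not None and holder != covered_by):
                ok = False
                break
            covered_by = holder
        if ok:
            correct += 1
    return correct / len(visible)
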