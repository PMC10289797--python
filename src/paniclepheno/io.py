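"""CSV/YAML serialisation for streams, ground truth, tracks and configs.

Files are plain UTF-8 CSV with headers.  Times are integer minutes from
08:00, days are integer DAT, boxes are ``x, y, w, h`` in pixels (origin
top-left, 0-based, half-open).  The detection-stream dialect is MOT-like:
one row per detection with ``dat, minute, x, y, w, h, conf, vf_prob,
source_id`` where ``source_id`` is -1 for false positives.  Writing then
reading a canonical file is the identity.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import pandas as pd
import yaml

from .errors import StreamParseError
from .synthetic_scene import (Detection, DetectionStream, PanicleGroundTruth,
                              SamplingSchedule, SceneConfig, build_schedule)
from .tracking import TrackSet

STREAM_COLUMNS = ["dat", "minute", "x", "y", "w", "h", "conf", "vf_prob", "source_id"]
TRUTH_COLUMNS = ["panicle_id", "dat", "vf_start_min", "vf_end_min", "x", "y", "w", "h"]
TRACK_COLUMNS = ["dat", "minute", "track_id", "x", "y", "w", "h", "matched_flag"]


# ---------------------------------------------------------------------------
# Detection streams
# ---------------------------------------------------------------------------

def write_stream(stream: DetectionStream, path: str | Path) -> None:
    """Write a detection stream in the canonical CSV dialect."""
    lines = [",".join(STREAM_COLUMNS)]
    for dat in stream.schedule.days:
        for minute in stream.schedule.timestamps:
            for d in stream.frame(dat, minute):
                sid = -1 if d.source_panicle_id is None else d.source_panicle_id
                x, y, w, h = d.box
                lines.append(
                    f"{dat},{minute},{x:.2f},{y:.2f},{w:.2f},{h:.2f},"
                    f"{d.confidence:.6f},{d.vf_prob:.6f},{sid}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_stream(path: str | Path, schedule: SamplingSchedule | None = None,
                ) -> DetectionStream:
    """Read a detection-stream CSV; malformed rows fail with line numbers.

    Without an explicit schedule, the mode is inferred from the distinct
    minutes present (9 -> hourly, otherwise dense) over the days present.
    """
    text = Path(path).read_text(encoding="utf-8")
    header, *rows = text.splitlines() or [""]
    if [c.strip() for c in header.split(",")] != STREAM_COLUMNS:
        raise StreamParseError(
            f"expected header {','.join(STREAM_COLUMNS)!r}, got {header!r}", line=1)

    frames: dict[tuple[int, int], list[Detection]] = {}
    days: set[int] = set()
    minutes: set[int] = set()
    for lineno, row in enumerate(rows, start=2):
        if not row.strip():
            continue
        parts = row.split(",")
        if len(parts) != len(STREAM_COLUMNS):
            raise StreamParseError(f"expected {len(STREAM_COLUMNS)} fields", line=lineno)
        try:
            dat, minute = int(parts[0]), int(parts[1])
            x, y, w, h, conf, vf = map(float, parts[2:8])
            sid = int(parts[8])
        except ValueError as exc:
            raise StreamParseError(f"non-numeric field ({exc})", line=lineno) from None
        if not (0.0 <= conf <= 1.0 and 0.0 <= vf <= 1.0):
            raise StreamParseError("conf and vf_prob must lie in [0, 1]", line=lineno)
        if w <= 0 or h <= 0:
            raise StreamParseError("box width/height must be positive", line=lineno)
        days.add(dat)
        minutes.add(minute)
        frames.setdefault((dat, minute), []).append(Detection(
            box=(x, y, w, h), confidence=conf, vf_prob=vf,
            source_panicle_id=None if sid < 0 else sid))

    if schedule is None:
        if not days:
            raise StreamParseError("empty stream: no rows and no schedule given")
        mode = "hourly" if minutes <= set(range(0, 481, 60)) else "dense"
        schedule = build_schedule(mode, sorted(days))
    for key in frames:
        if key[0] not in schedule.days or key[1] not in schedule.timestamps:
            raise StreamParseError(f"frame {key} is outside the schedule")
    # materialise empty frames so the stream is schedule-complete
    full = {k: frames.get(k, []) for k in schedule.frame_keys()}
    return DetectionStream(schedule=schedule, frames=full)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def write_truth(truth: list[PanicleGroundTruth], schedule: SamplingSchedule,
                path: str | Path) -> None:
    """One row per (panicle, day): flowering interval and the day's true box."""
    rows = []
    for t in truth:
        for dat in schedule.days:
            if not t.visible(dat):
                continue
            iv = t.daily_intervals.get(dat)
            x, y, w, h = t.box_at(dat)
            rows.append({
                "panicle_id": t.panicle_id, "dat": dat,
                "vf_start_min": -1 if iv is None else iv[0],
                "vf_end_min": -1 if iv is None else iv[1],
                "x": round(x, 2), "y": round(y, 2),
                "w": round(w, 2), "h": round(h, 2),
            })
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def write_tracks(trackset: TrackSet, path: str | Path) -> None:
    rows = []
    for tr in trackset.tracks:
        for e in tr.history:
            rows.append({"dat": e.dat, "minute": e.minute, "track_id": tr.track_id,
                         "x": round(e.box[0], 2), "y": round(e.box[1], 2),
                         "w": round(e.box[2], 2), "h": round(e.box[3], 2),
                         "matched_flag": int(e.matched)})
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def write_scene_config(config: SceneConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["suppressed_days"] = sorted(config.suppressed_days)
    data["frame_size"] = list(config.frame_size)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def read_scene_config(path: str | Path) -> SceneConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "suppressed_days" in data:
        data["suppressed_days"] = frozenset(data["suppressed_days"])
    if "frame_size" in data:
        data["frame_size"] = tuple(data["frame_size"])
    known = {f.name for f in dataclasses.fields(SceneConfig)}
    unknown = set(data) - known
    if unknown:
        raise StreamParseError(f"unknown scene-config keys: {sorted(unknown)}")
    return SceneConfig(**data)


def stream_to_frame(stream: DetectionStream) -> pd.DataFrame:
    """Detection stream as a tidy DataFrame (one row per detection)."""
    buf = _io.StringIO()
    lines = [",".join(STREAM_COLUMNS)]
    for (dat, minute), dets in stream.frames.items():
        for d in dets:
            sid = -1 if d.source_panicle_id is None else d.source_panicle_id
            x, y, w, h = d.box
            lines.append(f"{dat},{minute},{x},{y},{w},{h},{d.confidence},{d.vf_prob},{sid}")
    buf.write("\n".join(lines))
    buf.seek(0)
    return pd.read_csv(buf)
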