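"""Detection, counting, classification and phenology evaluation metrics.

Detection quality follows the detection-benchmark convention: predictions
are matched greedily to ground-truth boxes in descending confidence at an
IoU threshold (0.5 throughout), giving TP/FP/FN for precision, recall and
F1, and a ranked precision-recall curve whose all-point interpolated area
is the single-class AP50.  Counting quality is the coefficient of
determination and root-mean-square error between labelled and estimated
per-image counts.  Classification adds accuracy over the vigorous /
non-vigorous confusion matrix.  Phenology errors are absolute day
differences for heading dates and absolute minute differences for group
vigorous-flowering times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, KeyMismatchError
from .synthetic_scene import Box, Detection
from .tracking import iou


@dataclass
class MatchResult:
    """Detection/ground-truth match counts plus the matched pairs."""

    tp: int
    fp: int
    fn: int
    tn: int = 0
    pairs: list[tuple[int, int, float]] = None  # (pred idx, truth idx, IoU)

    def __post_init__(self):
        if self.pairs is None:
            self.pairs = []


@dataclass
class CountingEval:
    """Counting agreement between labelled and estimated per-image counts."""

    n: int
    labeled: list[float]
    estimated: list[float]
    r2: float
    rmse: float


def match_detections(predictions: list[Detection], truths: list[Box],
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching in descending prediction confidence.

    Each prediction takes the unmatched truth of highest IoU, provided that
    IoU reaches the threshold; leftovers count as FP (predictions) and FN
    (truths).
    """
    order = sorted(range(len(predictions)),
                   key=lambda i: (-predictions[i].confidence, i))
    taken: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i in order:
        best_j, best_iou = -1, iou_threshold
        for j, tb in enumerate(truths):
            if j in taken:
                continue
            v = iou(predictions[i].box, tb)
            if v >= best_iou and (best_j < 0 or v > best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            taken.add(best_j)
            pairs.append((i, best_j, best_iou))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(predictions) - tp, fn=len(truths) - tp,
                       pairs=sorted(pairs))


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean from a match result.

    With ``tp == 0`` the F1 is 0 by convention; fully empty denominators
    are rejected.
    """
    if m.tp + m.fp == 0 or m.tp + m.fn == 0:
        raise DegenerateInputError("precision/recall undefined: empty denominator")
    precision = m.tp / (m.tp + m.fp)
    recall = m.tp / (m.tp + m.fn)
    f1 = (2 * precision * recall / (precision + recall)) if m.tp else 0.0
    return precision, recall, f1


def ap50(predictions: list[tuple[object, Detection]],
         truths: dict[object, list[Box]],
         iou_threshold: float = 0.5) -> float:
    """Single-class average precision at IoU >= 0.5.

    ``predictions`` are ``(frame_key, detection)`` pairs pooled over frames
    and ranked by confidence; each prediction greedily claims the unmatched
    truth of highest IoU in its frame.  The area under the precision-recall
    curve uses the all-point interpolated precision envelope.
    """
    n_truth = sum(len(v) for v in truths.values())
    if n_truth == 0:
        raise DegenerateInputError("AP undefined without ground-truth boxes")
    order = sorted(range(len(predictions)),
                   key=lambda i: (-predictions[i][1].confidence, i))
    taken: dict[object, set[int]] = {k: set() for k in truths}
    tps = []
    for i in order:
        frame, det = predictions[i]
        boxes = truths.get(frame, [])
        best_j, best_iou = -1, iou_threshold
        for j, tb in enumerate(boxes):
            if j in taken.setdefault(frame, set()):
                continue
            v = iou(det.box, tb)
            if v >= best_iou and (best_j < 0 or v > best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[frame].add(best_j)
            tps.append(1)
        else:
            tps.append(0)
    if not tps:
        return 0.0
    tp_cum = np.cumsum(tps)
    rank = np.arange(1, len(tps) + 1)
    recall = tp_cum / n_truth
    precision = tp_cum / rank
    # all-point interpolation: integrate the precision envelope over recall
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def counting_eval(labeled, estimated) -> CountingEval:
    """R^2 and RMSE between labelled and estimated per-image counts.

    ``r2 = 1 - SS_res / SS_tot`` (may be negative);
    ``rmse = sqrt(mean((c_i - c_hat_i)^2))``.
    """
    labeled = [float(v) for v in labeled]
    estimated = [float(v) for v in estimated]
    if len(labeled) != len(estimated):
        raise KeyMismatchError("labeled and estimated lengths differ")
    n = len(labeled)
    if n == 0:
        raise DegenerateInputError("no counts to evaluate")
    c = np.asarray(labeled)
    ch = np.asarray(estimated)
    ss_res = float(np.sum((c - ch) ** 2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("labeled counts are constant: R^2 undefined")
    return CountingEval(n=n, labeled=labeled, estimated=estimated,
                        r2=1.0 - ss_res / ss_tot,
                        rmse=math.sqrt(ss_res / n))


def classification_metrics(tp: int, fp: int, fn: int, tn: int,
                           ) -> tuple[float, float, float]:
    """Precision and recall on the vigorous class, plus overall accuracy."""
    total = tp + fp + fn + tn
    if total == 0:
        raise DegenerateInputError("empty confusion matrix")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / total
    return precision, recall, accuracy


def _paired_abs_errors(a: dict, b: dict, what: str) -> dict:
    if set(a) != set(b):
        raise KeyMismatchError(f"{what}: keys differ: {sorted(a)} vs {sorted(b)}")
    if not a:
        raise DegenerateInputError(f"{what}: nothing to compare")
    return {k: abs(a[k] - b[k]) for k in sorted(a)}


def heading_date_error(estimated: dict[str, int],
                       observed: dict[str, int]) -> tuple[dict[str, int], float]:
    """Per-treatment |estimated - observed| heading day and their mean."""
    errors = _paired_abs_errors(estimated, observed, "heading dates")
    return errors, float(np.mean(list(errors.values())))


def vft_error(estimated: dict[int, int],
              manual: dict[int, int]) -> tuple[dict[int, int], float]:
    """Per-day |estimated - manual| group VFT in minutes and their mean."""
    errors = _paired_abs_errors(estimated, manual, "group VFT")
    return errors, float(np.mean(list(errors.values())))
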