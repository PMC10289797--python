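"""Published field observations from the 2019/2020 nitrogen trial.

The package's synthetic scenes are calibrated against a two-year paddy
experiment with four nitrogen treatments (N150 in 2019; N300, N270, N240 in
2020).  This module holds the field-observed summary tables used both as
calibration inputs for :mod:`paniclepheno.synthetic_scene` and as reference
values for the evaluation stage: stable panicle numbers and heading dates per
treatment, daily group vigorous-flowering times (manual vs. model, DAT 62-67),
and single-panicle flowering statistics (ten tracked panicles per treatment).

Times are minutes from 08:00; days are DAT (days after transplanting).
"""

from __future__ import annotations

TREATMENTS = ("N150", "N300", "N270", "N240")

#: Per-treatment heading summary: stable panicle number on the plateau,
#: estimated initial (10%) / full (80%) heading dates, and the observed vs.
#: estimated heading (50%) date with the per-treatment absolute error in days.
HEADING_TABLE: dict[str, dict[str, float | int]] = {
    "N150": {
        "stable_number": 23.11,
        "initial_heading_est": 60,
        "full_heading_est": 65,
        "heading_observed": 62,
        "heading_estimated": 62,
        "error_days": 0,
    },
    "N300": {
        "stable_number": 31.33,
        "initial_heading_est": 59,
        "full_heading_est": 64,
        "heading_observed": 62,
        "heading_estimated": 61,
        "error_days": 1,
    },
    "N270": {
        "stable_number": 28.16,
        "initial_heading_est": 61,
        "full_heading_est": 65,
        "heading_observed": 63,
        "heading_estimated": 63,
        "error_days": 0,
    },
    "N240": {
        "stable_number": 26.89,
        "initial_heading_est": 60,
        "full_heading_est": 64,
        "heading_observed": 63,
        "heading_estimated": 63,
        "error_days": 0,
    },
}

#: Group vigorous-flowering time (VFT_g), DAT 62-67, minutes from 08:00.
#: ``manual`` is the human reading of the image series, ``estimated`` the
#: model's per-day peak of the flowering-panicle count.
VFT_GROUP_TABLE: dict[str, dict[str, dict[int, int]]] = {
    "N300": {
        "manual": {62: 180, 63: 220, 64: 230, 65: 230, 66: 240, 67: 210},
        "estimated": {62: 190, 63: 220, 64: 230, 65: 230, 66: 220, 67: 220},
    },
    "N270": {
        "manual": {62: 190, 63: 220, 64: 240, 65: 210, 66: 240, 67: 220},
        "estimated": {62: 200, 63: 240, 64: 240, 65: 220, 66: 230, 67: 220},
    },
    "N240": {
        "manual": {62: 180, 63: 220, 64: 230, 65: 220, 66: 220, 67: 220},
        "estimated": {62: 190, 63: 220, 64: 220, 65: 230, 66: 240, 67: 220},
    },
}

#: Published per-day VFT_g error columns (minutes).  The N240 DAT 62 row is
#: internally inconsistent in the source table (manual 11:00 vs. estimated
#: 11:10 but a printed error of 0); the printed column is kept verbatim so the
#: published column means (6.67 / 8.33 / 6.67 min) are reproducible.  See
#: docs/methods.md.
VFT_GROUP_ERRORS_MIN: dict[str, list[int]] = {
    "N300": [10, 0, 0, 0, 20, 10],
    "N270": [10, 20, 0, 10, 10, 0],
    "N240": [0, 0, 10, 10, 20, 0],
}

#: Population flowering window (first and last day any panicle flowers).
FLOWERING_WINDOW: dict[str, tuple[int, int]] = {
    "N300": (59, 70),
    "N270": (60, 69),
    "N240": (60, 68),
}

#: Single-panicle flowering statistics over ten tracked panicles per
#: treatment: mean +/- sd of FDAT (DAT), FDs (days), VFT_p (min from 08:00),
#: total DBE (min) and daily DBE (min).
SINGLE_PANICLE_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "N300": {
        "fdat": (61.20, 1.40),
        "fds": (4.40, 0.70),
        "vft_p": (211.23, 27.32),
        "total_dbe": (399.50, 138.85),
        "daily_dbe": (93.68, 38.40),
    },
    "N270": {
        "fdat": (62.60, 1.51),
        "fds": (3.90, 0.57),
        "vft_p": (209.28, 7.19),
        "total_dbe": (373.50, 127.30),
        "daily_dbe": (94.28, 23.80),
    },
    "N240": {
        "fdat": (62.00, 1.33),
        "fds": (3.60, 0.52),
        "vft_p": (202.08, 13.97),
        "total_dbe": (348.00, 107.27),
        "daily_dbe": (95.92, 22.52),
    },
}

#: Detection-model validation accuracy (two seasons pooled): the noise level
#: the simulator's default detection knobs are calibrated near.
DETECTION_ACCURACY = {"precision": 0.904, "recall": 0.861, "f1": 0.882, "ap50": 0.895}

#: Days with weather-suppressed flowering (cloud/rain), observed in 2019.
SUPPRESSED_DAYS: dict[str, frozenset[int]] = {
    "N150": frozenset({63, 64}),
    "N300": frozenset(),
    "N270": frozenset(),
    "N240": frozenset(),
}

#: Observation window (DAT) of the heading-flowering monitoring campaign.
STUDY_DAYS: tuple[int, int] = (58, 71)
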