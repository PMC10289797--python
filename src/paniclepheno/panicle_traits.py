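"""Single-panicle flowering traits from identity-resolved tracks.

Once a panicle is followed through a day by one track, the flowering-class
score of each matched detection yields an ordered series of vigorous/
non-vigorous flags at the sampled minutes.  From these per-day flag series
the package derives, per panicle:

* **FDAT** — flowering initiation day after transplanting: the earliest day
  with a qualifying vigorous run.
* **FDs** — flowering days: the number of such days.
* **VFT_p** — per-day vigorous flowering time: the minute at which vigorous
  flowering starts *continuously* appearing, formalised as the first run of
  at least ``k`` consecutive vigorous frames (default ``k=2``, i.e. roughly
  15-25 min of persistence on the dense schedule).
* **daily DBE** — span in minutes from the qualifying-run start to the last
  vigorous frame of the day; **total DBE** is its sum over flowering days.

Tracking is per day, so per-day tracks are first joined across days — by
simulator provenance in synthetic scenes, or by an explicit identity map
standing in for manual visual inspection on real data.

Treatment summaries report mean +/- sd per trait with compact-letter
significance groups from all-pairs Tukey HSD comparisons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import TrackJoinError
from .tracking import TrackSet

DEFAULT_VF_THRESHOLD = 0.5
DEFAULT_RUN_LENGTH = 2


@dataclass
class VigorousFlagSeries:
    """Vigorous/non-vigorous flags for one joined panicle, per day.

    ``flags[dat]`` is the ordered list of ``(minute, vigorous)`` pairs at
    the sampled minutes where the panicle's track was matched; unmatched
    frames are absent.
    """

    panicle_id: int
    flags: dict[int, list[tuple[int, bool]]] = field(default_factory=dict)


@dataclass
class PanicleFloweringTraits:
    """FDAT, FDs, per-day VFT_p / daily DBE and total DBE for one panicle."""

    panicle_id: int
    fdat: int | None
    fds: int
    vft_p: dict[int, int]
    daily_dbe: dict[int, int]

    @property
    def total_dbe(self) -> int:
        return sum(self.daily_dbe.values())

    @property
    def mean_vft_p(self) -> float | None:
        return float(np.mean(list(self.vft_p.values()))) if self.vft_p else None

    @property
    def mean_daily_dbe(self) -> float | None:
        return float(np.mean(list(self.daily_dbe.values()))) if self.daily_dbe else None


# ---------------------------------------------------------------------------
# Cross-day joining and flag extraction
# ---------------------------------------------------------------------------

def provenance_id_map(tracksets: list[TrackSet]) -> dict[tuple[int, int], int]:
    """Join per-day tracks via simulator provenance.

    Each track maps to the majority ``source_panicle_id`` among its matched
    detections; tracks made purely of false positives are dropped.  This is
    the synthetic stand-in for the manual visual inspection that merges a
    panicle's per-day identities on real imagery.
    """
    id_map: dict[tuple[int, int], int] = {}
    for ts in tracksets:
        for tr in ts.confirmed():
            src = Counter(e.detection.source_panicle_id for e in tr.history
                          if e.matched and e.detection is not None
                          and e.detection.source_panicle_id is not None)
            if src:
                id_map[(ts.day, tr.track_id)] = src.most_common(1)[0][0]
    return id_map


def flag_series(tracksets: list[TrackSet],
                vf_threshold: float = DEFAULT_VF_THRESHOLD,
                id_map: dict[tuple[int, int], int] | None = None,
                ) -> list[VigorousFlagSeries]:
    """Per-panicle vigorous flag series from joined per-day tracks.

    ``id_map`` maps ``(day, track_id)`` to a cross-day panicle identity; by
    default it is derived from simulator provenance.  Two *explicitly*
    mapped tracks of the same day may not share an identity.
    """
    explicit = id_map is not None
    if id_map is None:
        id_map = provenance_id_map(tracksets)
    if explicit:
        seen: set[tuple[int, int]] = set()
        for (day, _tid), pid in id_map.items():
            if (day, pid) in seen:
                raise TrackJoinError(
                    f"two tracks on day {day} map to panicle {pid}")
            seen.add((day, pid))

    series: dict[int, VigorousFlagSeries] = {}
    for ts in tracksets:
        for tr in ts.confirmed():
            pid = id_map.get((ts.day, tr.track_id))
            if pid is None:
                continue
            s = series.setdefault(pid, VigorousFlagSeries(panicle_id=pid))
            day_flags = s.flags.setdefault(ts.day, [])
            have = {m for m, _ in day_flags}
            for e in tr.history:
                if e.matched and e.detection is not None and e.minute not in have:
                    day_flags.append((e.minute, e.detection.vf_prob > vf_threshold))
                    have.add(e.minute)
    for s in series.values():
        for flags in s.flags.values():
            flags.sort(key=lambda mv: mv[0])
    return [series[k] for k in sorted(series)]


# ---------------------------------------------------------------------------
# Per-day flowering statistics
# ---------------------------------------------------------------------------

def vigorous_run_start(day_flags: list[tuple[int, bool]],
                       k: int = DEFAULT_RUN_LENGTH) -> int | None:
    """Minute of the first run of >= k consecutive vigorous flags.

    Consecutive means adjacent entries of the sampled series.  Returns None
    when no run reaches length ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    run = 0
    for i, (_minute, vig) in enumerate(day_flags):
        run = run + 1 if vig else 0
        if run == k:
            return day_flags[i - k + 1][0]
    return None


def daily_dbe(day_flags: list[tuple[int, bool]],
              k: int = DEFAULT_RUN_LENGTH) -> int:
    """Minutes from the qualifying-run start to the day's last vigorous flag.

    Zero when no run of length ``k`` exists (including a day whose only
    vigorous evidence is a single isolated frame).
    """
    start = vigorous_run_start(day_flags, k)
    if start is None:
        return 0
    last = max(m for m, vig in day_flags if vig)
    return last - start


def panicle_traits(series: VigorousFlagSeries,
                   k: int = DEFAULT_RUN_LENGTH) -> PanicleFloweringTraits:
    """FDAT/FDs/VFT_p/DBE for one panicle from its daily flag series.

    A day counts as a flowering day exactly when it holds a qualifying run
    of ``k`` consecutive vigorous frames, so FDs, VFT_p and daily DBE are
    defined on the same day set by construction.
    """
    vft: dict[int, int] = {}
    dbe: dict[int, int] = {}
    for day in sorted(series.flags):
        start = vigorous_run_start(series.flags[day], k)
        if start is not None:
            vft[day] = start
            dbe[day] = daily_dbe(series.flags[day], k)
    days = sorted(vft)
    return PanicleFloweringTraits(
        panicle_id=series.panicle_id,
        fdat=days[0] if days else None,
        fds=len(days),
        vft_p=vft,
        daily_dbe=dbe,
    )


# ---------------------------------------------------------------------------
# Treatment summaries
# ---------------------------------------------------------------------------

TRAIT_NAMES = ("fdat", "fds", "mean_vft_p", "total_dbe", "mean_daily_dbe")


@dataclass
class TreatmentSummary:
    """Mean +/- sd per trait for one treatment, with significance letters."""

    treatment: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]
    letters: dict[str, str]


def _trait_values(traits: list[PanicleFloweringTraits], name: str) -> list[float]:
    vals = []
    for t in traits:
        v = {"fdat": t.fdat, "fds": t.fds, "mean_vft_p": t.mean_vft_p,
             "total_dbe": t.total_dbe, "mean_daily_dbe": t.mean_daily_dbe}[name]
        if v is not None:
            vals.append(float(v))
    return vals


def compact_letters(labels: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different; ``different``
    holds the unordered significant pairs.
    """
    classes: list[set[str]] = [set(labels)]
    for a, b in sorted(different):
        new: list[set[str]] = []
        for cls in classes:
            if a in cls and b in cls:
                new.extend([cls - {a}, cls - {b}])
            else:
                new.append(cls)
        # absorb classes contained in another
        classes = [c for c in new
                   if c and not any(c < other for other in new)]
        # drop exact duplicates
        uniq: list[set[str]] = []
        for c in classes:
            if c not in uniq:
                uniq.append(c)
        classes = uniq
    classes.sort(key=lambda c: min(labels.index(x) for x in c))
    out = {lab: "" for lab in labels}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for lab in cls:
            out[lab] += letter
    return {lab: "".join(sorted(s)) for lab, s in out.items()}


def summarize_treatments(traits_by_treatment: dict[str, list[PanicleFloweringTraits]],
                         alpha: float = 0.05) -> list[TreatmentSummary]:
    """Per-treatment trait means with Tukey-HSD significance letters.

    For each trait, an all-pairs Tukey HSD at level ``alpha`` decides which
    treatments differ; letter groups are ordered by descending trait mean.
    """
    if len(traits_by_treatment) < 2:
        raise ValueError("need at least two treatments to compare")
    for label, traits in traits_by_treatment.items():
        if len(traits) < 2:
            raise ValueError(f"treatment {label!r} needs at least two panicles")

    labels = list(traits_by_treatment)
    letters: dict[str, dict[str, str]] = {lab: {} for lab in labels}
    means: dict[str, dict[str, float]] = {lab: {} for lab in labels}
    sds: dict[str, dict[str, float]] = {lab: {} for lab in labels}

    for name in TRAIT_NAMES:
        samples = {lab: _trait_values(traits_by_treatment[lab], name)
                   for lab in labels}
        for lab in labels:
            v = samples[lab]
            means[lab][name] = float(np.mean(v)) if v else float("nan")
            sds[lab][name] = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
        usable = [lab for lab in labels if len(samples[lab]) >= 2]
        different: set[tuple[str, str]] = set()
        if len(usable) >= 2 and any(np.std(samples[lab]) > 0 for lab in usable):
            res = stats.tukey_hsd(*[samples[lab] for lab in usable])
            for i in range(len(usable)):
                for j in range(i + 1, len(usable)):
                    if res.pvalue[i, j] < alpha:
                        different.add(tuple(sorted((usable[i], usable[j]))))
        ordered = sorted(usable, key=lambda lab: -means[lab][name])
        cld = compact_letters(ordered, different)
        for lab in labels:
            letters[lab][name] = cld.get(lab, "")

    return [TreatmentSummary(treatment=lab,
                             n=len(traits_by_treatment[lab]),
                             means=means[lab], sds=sds[lab],
                             letters=letters[lab])
            for lab in labels]
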