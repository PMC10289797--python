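# paniclepheno

Time-series phenotyping of rice panicles during the heading–flowering stage,
from per-frame bounding-box detection streams.

A fixed camera above a paddy plot photographs the canopy on a daily schedule
(9 frames/day on the hour for counting, 41 frames/day at 10–15-min cadence
for flowering work). A detector proposes one box per panicle with a
confidence, and a classifier scores each box for *vigorous flowering* (open
spikelets, extruded anthers). This package takes it from there:

- **`synthetic_scene`** — a seeded generator of latent panicle populations
  (emergence days, multi-day flowering windows, midday-peaked daily vigorous
  intervals, weather-suppressed days) and of the noisy detection/
  classification streams a real front end would produce, with packaged
  calibrations for the four nitrogen treatments of a two-year field trial
  (N150, N300, N270, N240).
- **`tracking`** — within-day tracking-by-detection: greedy NMS, a
  constant-velocity Kalman filter per track, Hungarian assignment on the
  `1 − IoU` cost with an association gate, and the daily tracking-accuracy
  statistic (fraction of first-frame panicles carried by a single ID through
  every frame).
- **`population_traits`** — daily panicle number `pn` (mean per-frame count),
  stable panicle number (plateau mean), heading dates as 10 %/50 %/80 %
  crossings of the stable number under the mean-and-median box-plot rule,
  daily flowering panicle number `fn` (max per-frame vigorous count), group
  vigorous-flowering time VFT_g (minute of the daily peak), inclusive
  flowering duration, and the cumulative flowering curve.
- **`panicle_traits`** — single-panicle traits from identity-resolved tracks:
  flowering initiation day **FDAT**, flowering days **FDs**, per-day vigorous
  flowering time **VFT_p** (start of the first run of ≥ k consecutive
  vigorous frames, k = 2 by default), **daily DBE** (run start to last
  vigorous frame) and **total DBE**, plus treatment summaries with Tukey-HSD
  compact letters.
- **`evaluation`** — precision/recall/F1 and AP50 at IoU ≥ 0.5, counting
  R²/RMSE, classification accuracy, heading-date and VFT error statistics.

## Worked example

```python
import dataclasses
import paniclepheno as pp

# one plot-season at the N300 calibration, with realistic detector noise
cfg = dataclasses.replace(pp.CALIBRATIONS["N300"], seed=1)
truth = pp.simulate_population(cfg)
hourly = pp.build_schedule("hourly", range(58, 72))
stream = pp.render_detections(truth, hourly, cfg)

counts = pp.daily_counts(stream)
stable = pp.stable_panicle_number(counts)
report = pp.heading_dates(counts, stable)
window = pp.flowering_duration(pp.flowering_counts(stream))
print(stable, report.initial_heading, report.heading, report.full_heading,
      window, pp.vft_group(stream, 64))
```

prints (seed 1):

```
stable panicle number    : 29.17
initial/50%/full heading : DAT 59 / 62 / 63
flowering window         : DAT 59-71 (13 days)
VFT_g on DAT 64          : 240 min after 08:00
```

The plot holds 31 panicles; at detection recall 0.86 with ≈2.5 false
positives/frame the plateau mean lands at 29.2, the 50 % crossing on DAT 62,
and the population's peak flowering on DAT 64 at 12:00 (240 min after
08:00). Per-panicle traits come from the dense schedule instead; noise-free,
the tracker carries every panicle through the day:

```python
dense = pp.build_schedule("dense", range(58, 72))
cfg_nf = pp.noise_free(cfg)
truth = pp.simulate_population(cfg_nf)
stream = pp.render_detections(truth, dense, cfg_nf)
tracksets = [pp.track_stream(stream, day) for day in dense.days]
traits = [pp.panicle_traits(s, k=2) for s in pp.flag_series(tracksets)]
```

giving 31 tracked panicles, day-64 tracking accuracy 1.0, mean FDAT 62.13,
mean FDs 4.32 days and mean total DBE 386.8 min — consistent with the
calibration's configured FDs 4.40 ± 0.70 days and daily DBE 93.68 min.

A command-line layer wraps the same functions:

```sh
paniclepheno simulate --calibration N300 --mode dense --out-dir out --seed 1
paniclepheno track --stream out/stream_dense.csv --day 64 --out out/tracks.csv
paniclepheno traits population --stream out/stream_dense.csv --out out/pop.json
paniclepheno run --out-dir out/full --seed 1      # all four treatments
```

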