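# zoomotion

Video-based quantification of group motor activity in a fixed enclosure,
plus the downstream chronobiology/biometeorology analysis, with a synthetic
data generator providing ground truth for every stage.

## What it computes

- **A index** — per frame, the fraction of pixels whose grayscale 1-D
  Mahalanobis distance to a sliding background model (per-pixel mean and
  population SD over the 28 preceding frames, SD floored at 2.0) strictly
  exceeds a pixel threshold (default `k = 3.0`).
- **A1 index** — per time bin (10 minutes, 1 hour, 1 day, …), the fraction
  of frames whose A index strictly exceeds 0.01; low-coverage bins are
  reported missing, never zero.
- **Ephemeris** — sunrise/sunset/day length via the NOAA low-accuracy
  solar-position method (zenith 90.833°, rounded to the minute).
- **Pressure** — daily means `p` from station exports and day-to-day
  changes `Δp_i = p_i − p_{i−1}` (a gap day breaks the chain).
- **Statistics** — named study periods (prenatal/postnatal, standard
  time/DST, two excluded stoppage days), OLS trends with slope t-tests,
  pooled/Welch mean comparisons (pooled gated by an F-test at α = 0.05),
  F-test of variances, Pearson correlations of daily A1 with `p` and `Δp`.
  All tests two-sided, raw p-values.
- **Synthetic data** — sunrise-gated activity-probability schedules with a
  parturition step, post-clock-change drift and pressure coupling;
  series-level A1 draws (binomial + truncated Gaussian noise); rendered
  blob videos (static textured background, 9→10 moving discs, night IR
  palette, sensor noise) with the true changed-pixel fraction recorded.

## CLI

```sh
zoomotion --show-config                           # all defaults, incl. k and sd_floor
zoomotion simulate  --out-dir out/sim --seed 1    # synthetic study bundle + ground truth
zoomotion compute-a1 FRAMES_DIR --out-dir out/a1  # A/A1 CSVs + day×time heatmap
zoomotion analyze out/sim/a1_binned.csv out/sim/pressure.csv --out-dir out/an
zoomotion ephemeris --start 2016-03-01 --end 2016-04-29
```

Frame input is a directory of numbered PNGs plus `timestamps.tsv`
(filename + ISO 8601 instant per row). All tabular outputs are CSV; every
run writes a `manifest.json` (seed, config hash, versions) and a log file.

## Conventions worth knowing

- Background SD uses the population convention (divide by W); sample
  statistics elsewhere use n − 1. Both thresholds ("exceeds") are strict.
- All internal timestamps are fixed local standard time (UTC+1); the
  day×time heatmap re-expresses DST-period bins on the standard clock.
- The first W frames of any sequence are warm-up and yield no A samples.
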