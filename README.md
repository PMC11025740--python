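# somite-staircase

Somite number, anterior–posterior length, and formation period inferred from
time-lapse measurements of the chicken embryo's **segmented region (SEG)** —
the A-P distance from the anterior border of somite 1 to the last completely
formed somitic cleft.

## The problem and the method

During somitogenesis, SEG length grows as a staircase: it stays roughly
constant while a somite matures, then jumps by one somite length
(~120–190 µm) each time a new cleft forms. A single measured variable
therefore encodes, for every somite in the recording window,

- **identity**: a backward difference of consecutive SEG measurements
  exceeding a threshold θ (default 50 µm, strict `>`) signals a new somite;
  consecutive supra-threshold steps (a cleft sharpening over several frames)
  merge into one event;
- **length** `L_n`: the summed supra-threshold increments of the event
  (or, in the noise-robust *plateau* mode, the difference of the medians of
  the flanking plateaus); the first measurement is the length of the first
  somite;
- **formation period** `T_n = t_n − t_{n−1}`: the onset-time difference to
  the preceding somite, undefined for the first somite of each recording.

Group somitogenesis rates are estimated by ordinary least squares of onset
time on somite number with one intercept per embryo and a shared slope
β (min/somite), reported with its t-based 95 % CI. Variance homogeneity
between somite groups is tested with the Brown-Forsythe statistic: the
one-way ANOVA F on absolute deviations from group medians,
`z_ij = |y_ij − median_j|`, with (p−1, N−p) degrees of freedom.

A seeded synthetic-embryo generator produces staircase trajectories with
known ground truth (per-somite period/length draws, linear cleft ramps,
truncated Gaussian measurement noise, frame dropout), so every stage of the
pipeline is testable without external data.

## Worked example

Simulate an 11-embryo cohort at the default study conditions (somites 1–9,
3-min sampling, occipital somites every ~75 min then ~90 min, 10 µm
measurement noise), run the full pipeline, and estimate group rates:

```sh
somite-staircase simulate --n-embryos 11 --seed 7 --out demo/sim
somite-staircase run demo/sim/measurements.csv --out demo/out
somite-staircase rate demo/out/records.csv --groups 1-5,6-9 --out demo/rates.csv
```

which prints

```
detected 99 somites in 11 series; outputs in demo/out
somites 1-5: 75.46 min/somite (95% CI 72.81-78.12, 11 embryos, 55 points)
somites 6-9: 90.38 min/somite (95% CI 86.37-94.39, 11 embryos, 44 points)
```

All 99 somites (11 embryos × 9 somites) were recovered from the noisy
staircases, and the regression slopes recover the generator's true periods
(75 and 90 min/somite) to well under a minute. `demo/out/summary.csv` holds
the per-somite mean ± SD table:

```
somite_number,n,length_mean,length_sd,period_mean,period_sd
1,11,140.82,12.62,,
2,11,135.69,9.26,75.27,13.04
3,11,140.44,21.27,74.18,10.4
```

(the first somite's period is blank: its formation predates the recording).
`demo/out/` also contains per-somite records, group rates, Brown-Forsythe
results and a JSON run manifest. The same operations are available as
library functions (`simulate`, `detect_somites`, `compute_periods`,
`group_rate`, `summarize_per_somite`, `brown_forsythe`, `run_pipeline`).

To analyse real measurements, provide a CSV with columns
`embryo_id, operator, time_min, seg_length_um` — or any schema plus a YAML
column map (`--colmap`) declaring column names, unit factors and per-embryo
start somites. `scripts/fetch_figshare.py` downloads the published
measurement deposit when network access is available.

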