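# Methods

## Measurement model

The observable is the segmented region length SEG(t): the A-P distance from
the anterior border of somite 1 to the last completely formed somitic cleft,
sampled nominally every Δt = 3 min. Under sequential somite formation,

    SEG(t) = Σ_{n : t_n ≤ t} L_n + ε(t),

a staircase with step heights L_n (somite A-P lengths, µm), step times t_n
(somite onsets, min) and additive measurement error ε. The pipeline inverts
this: steps → somite identities, step heights → lengths, step spacing →
formation periods T_n = t_n − t_{n−1}.

Assumptions: somites form one at a time (no two steps in one frame at
default rates, since T_n ≈ 60–96 min ≫ Δt); measurement error is much
smaller than a somite length; the first measurement equals the length of
the first somite in the window, so that somite's period is undefined
(it is reported as NA and excluded from statistics, never imputed).

## Event detection

Detection operates on first differences of consecutive SEG measurements
(this is the only "detrending" applied; no smoothing precedes it, keeping
the estimator assumption-light). A difference **strictly greater** than the
threshold θ (default 50 µm) signals a new somite. The boundary is strict by
design: a step of exactly 50 µm is not an event. θ must satisfy
2ε_max < θ < min L_n for reliable detection; 50 µm sits comfortably between
realistic measurement error (≲ 20 µm) and somite lengths (≳ 110 µm).

- **Merging.** A maximal run of consecutive supra-threshold steps is one
  event (a cleft sharpening across two frames must not be double-counted;
  true inter-somite gaps are ≥ ~60 min ≫ Δt). Toggleable
  (`merge_consecutive=False` treats each supra-threshold step as an event).
- **Onset convention.** The later frame of the first triggering pair — the
  first frame at which the somite is visible. Times are minutes from each
  recording's start; frames are 0-based.
- **Length modes.** `increment` (default) sums the event's supra-threshold
  step differences; it is exactly conservative on noise-free data (detected
  lengths sum to the final SEG measurement). `plateau` takes the difference
  of the median SEG of the constant segments flanking the event; medians
  absorb frame-level outliers and negative jitter, at the cost of exact
  conservation. In plateau mode the first somite's length is the median of
  the pre-first-event segment (the plateau-mode analogue of "the first
  measurement is the first somite's length"); end segments use all
  available frames.
- **Negative differences** never trigger or cancel events.
- **Irregular sampling** is tolerated; differences remain per consecutive
  pair, and a warning is logged when a gap exceeds 2Δt, since a long gap
  can hide an event (two somites forming inside one gap are detected as
  one).

## Rate regression

The rate of a contiguous somite group is the slope of

    onset_time ~ embryo (fixed intercepts) + somite_number (shared slope)

fit by OLS, with a t-based 95 % CI. Per-embryo intercepts absorb each
recording's arbitrary absolute start time: two embryos with identical
periods but shifted starts yield the pooled slope of either alone. An
embryo contributing a single point informs only its own intercept. A group
with fewer than two distinct somite numbers has no identifiable slope and
raises a degenerate-design error. Default groups: somites 1–5 (occipital),
6–9, 15–20; all configurable.

**Calibration caveat.** The t interval assumes independent errors, but when
between-somite period variability σ_T dominates, onset errors within an
embryo are a *random walk* (period deviations accumulate), so the OLS
standard error underestimates the slope's true sampling variability. At the
generator defaults (σ_T = 15 min, σ_m = 10 µm, 11 embryos, somites 1–9) the
acceptance script measures ~78 % / ~88 % empirical coverage for the nominal
95 % interval on the occipital / 6–9 groups, while the slope itself is
essentially unbiased (< 1 min/somite over 50 replicates). Interpret the
reported CIs as conditional on the realized period sequence; a
generalized-least-squares or mixed-model interval would be needed for
nominal unconditional coverage and is out of scope here.

## Per-somite summaries and variance comparison

`summarize_per_somite` reports, per somite number: the number of embryos
sampled and mean ± SD of length and period (sample SD, n−1 denominator;
a single observation leaves the SD blank; report rounding is 2 decimals).

`brown_forsythe` tests variance homogeneity across groups: with
z_ij = |y_ij − median_j|, the statistic is the one-way ANOVA F on z with
(p−1, N−p) degrees of freedom and an upper-tail F p-value. Median centering
makes the test robust to outliers. Every group needs ≥ 2 observations; if
all within-group deviations are identical (SSW = 0) the F is undefined and
an explicit error is raised. Default splits compare lengths of somites 1–16
vs 17–20 and periods of somites 1–7 vs 8–20.

## Synthetic-embryo generator

`simulate` emulates the measured study conditions. Per embryo: per-somite
lengths L_n ~ N(µ_L(n), σ_L) and periods T_n ~ N(µ_T(n), σ_T), redrawn
until positive (periods until they exceed the cleft-ramp duration, so every
somite retains a plateau); onsets accumulate from t = 0, where the window's
first somite is already present; SEG is the running sum of formed lengths,
each increment spread linearly over `cleft_frames` frames; truncated
Gaussian noise (clipped at ±2σ_m, which makes the bounded-noise robustness
guarantee provable) is added per frame; frames are dropped uniformly at
rate `dropout_rate` (the first frame is always kept). Output is
bit-identical for identical (config, seed).

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| n_embryos / somite window | 11, somites 1–9 | the early-cohort design |
| µ_T(n) | 75 min (n ≤ 5), 90 min (n ≥ 6) | occipital vs trunk regimes |
| σ_T | 15 min | middle of observed per-somite period SDs (~12–23 min), which also include detection/quantization noise |
| µ_L, σ_L | 140 µm, 18 µm | centre and spread of observed somite lengths |
| σ_m | 10 µm | plausible manual-measurement error; 4σ_m < θ |
| cleft_frames | 1 | instantaneous cleft; the ramp shape of real sharpening is unknown, linear when > 1 |
| sample_interval | 3 min | time-lapse resolution |
| dropout_rate | 0 | missed captures are rare |

What the generator does **not** emulate: operator-specific error structure
(three human measurers), embryo rotation at late stages (which inflates
late-somite length variance in real data), slow drift or re-measurement of
the anterior boundary, and any gene-expression (segmentation-clock)
dynamics. Passing tests therefore demonstrate correctness of the inversion
under the stated noise model, not robustness to every artefact of real
imaging.

## Numerical choices

- Threshold comparisons are strict (`>`), on raw first differences.
- Onset quantization: a true onset between frames is detected at the next
  frame, adding up to Δt of positive delay per onset; it cancels in period
  differences on average and does not bias slopes.
- Detection with a single time point returns the single starting record;
  zero detected events beyond the first somite is not an error.
- OLS is fit on an explicit dummy design (no global intercept, one column
  per embryo + somite number); with a saturated exact fit (zero residual
  df) the CI is reported with zero width.
- Brown-Forsythe uses exact SSB/SSW accumulation in float64; the p-value
  comes from the F survival function.
- Statistics use the n−1 sample SD; undefined periods are excluded.

## Problem sizes

The test suite and acceptance script run cohorts of 5–11 embryos × 6–9
somites and 50 replicate cohorts for the calibration study — the same order
as the study design they emulate — completing in seconds.

## Known limitations

- The iid-error CI undercoverage described above.
- A somite whose length (or per-frame ramp step) does not exceed θ plus
  twice the noise bound can be missed; with default settings this has
  probability ≈ 10⁻⁵ per somite.
- Embryos recorded in two disjoint windows must be supplied as two series
  with distinct ids and start somites; periods never bridge the gap.
- The reader requires a column map for non-canonical schemas; it does not
  guess units.
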