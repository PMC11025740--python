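"""Infer somite number, length and formation period from segmented-region growth.

During vertebrate somitogenesis the embryo's segmented region (SEG) -- the
anterior-posterior distance from the rostral border of somite 1 to the last
completely formed somitic cleft -- grows as a staircase: the length is
approximately constant while a somite is maturing and jumps by one somite
length (~120-190 um in the chicken) each time a new cleft forms.  Time-lapse
measurements of SEG therefore carry, in a single measured variable, the
number, the A-P length and the formation time of every somite in the
recording window.

This module implements the full analysis pipeline on such measurements, in
the order the method runs:

1.  Domain types and validation (``MeasurementSeries``, ``DetectionConfig``,
    record types).
2.  Synthetic-embryo generation (``SimulationConfig``, :func:`simulate`) --
    seeded staircase trajectories with known ground truth, so every
    downstream stage is testable without external data.
3.  Event detection (:func:`detect_somites`): a new somite is declared when
    the backward difference of consecutive SEG measurements exceeds a
    threshold (default 50 um); each somite's length comes either from the
    summed supra-threshold increments or from plateau medians.
4.  Period inference (:func:`compute_periods`): the formation period of
    somite *n* is the difference between the onset times of somites *n* and
    *n-1*; it is undefined for the first somite of a recording.
5.  Group statistics (:func:`group_rate`, :func:`summarize_per_somite`,
    :func:`brown_forsythe`): regression-slope rate estimates with 95 % CIs,
    per-somite mean +/- SD tables, and a Brown-Forsythe variance-homogeneity
    test.
6.  File I/O and the pipeline driver (:class:`ColumnMap`,
    :func:`read_measurements`, :func:`run_pipeline`).

Units are micrometres for lengths and minutes for times throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import yaml

__all__ = [
    "DEFAULT_THRESHOLD_UM",
    "DEFAULT_INTERVAL_MIN",
    "InvalidInputError",
    "InvalidConfigError",
    "DegenerateDesignError",
    "UndefinedVarianceError",
    "MeasurementSeries",
    "DetectionConfig",
    "SomiteRecord",
    "PeriodRecord",
    "GroupRateEstimate",
    "VarianceTestResult",
    "SimulationConfig",
    "default_period_profile",
    "simulate",
    "detect_somites",
    "compute_periods",
    "analyze_series",
    "records_to_frame",
    "group_rate",
    "summarize_per_somite",
    "brown_forsythe",
    "ColumnMap",
    "read_measurements",
    "write_records",
    "read_records",
    "run_pipeline",
]

# --------------------------------------------------------------------------
# Configuration constants and logging
# --------------------------------------------------------------------------

#: Default SEG-increment threshold (um) above which a new somite is declared.
DEFAULT_THRESHOLD_UM: float = 50.0

#: Nominal time-lapse sampling interval (minutes).
DEFAULT_INTERVAL_MIN: float = 3.0

#: Default somite groups for rate regression: occipital (1-5), early
#: cervical (6-9) and the late trunk window (15-20).
DEFAULT_RATE_GROUPS: tuple[tuple[int, int], ...] = ((1, 5), (6, 9), (15, 20))

#: Default Brown-Forsythe splits: lengths of somites 1-16 vs 17-20, periods
#: of somites 1-7 vs 8-20.
DEFAULT_BF_SPLITS: Mapping[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "length_um": ((1, 16), (17, 20)),
    "period_min": ((1, 7), (8, 20)),
}

logger = logging.getLogger("somite_staircase")


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


class InvalidInputError(ValueError):
    """Measurement data violate the input contract."""


class InvalidConfigError(ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class DegenerateDesignError(ValueError):
    """A regression design has no identifiable slope."""


class UndefinedVarianceError(ValueError):
    """The Brown-Forsythe F statistic is undefined (zero within-group SS)."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementSeries:
    """One embryo's time-ordered SEG trajectory.

    Parameters
    ----------
    embryo_id
        Text label for the embryo (or recording-window segment).
    times
        Acquisition times in minutes from the start of this recording,
        strictly increasing.  Nominal spacing is 3 min, but irregular
        spacing is tolerated.
    lengths
        SEG length in micrometres at each time point, non-negative.
    start_somite
        Craniocaudal number of the first somite already present when the
        recording starts (1 for recordings beginning at the 1-somite stage,
        14 for late-trunk windows, ...).
    operator_id
        Optional label of the person/operator who measured this series.
    """

    embryo_id: str
    times: np.ndarray
    lengths: np.ndarray
    start_somite: int = 1
    operator_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lengths", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise InvalidInputError(
                f"{self.embryo_id}: times and lengths must be 1-D and equally long"
            )
        if t.size < 1:
            raise InvalidInputError(f"{self.embryo_id}: series has no time points")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise InvalidInputError(f"{self.embryo_id}: non-finite values in series")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError(
                f"{self.embryo_id}: times must be strictly increasing"
            )
        if np.any(y < 0):
            raise InvalidInputError(f"{self.embryo_id}: negative SEG length")
        if self.start_somite < 1:
            raise InvalidInputError(f"{self.embryo_id}: start_somite must be >= 1")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class DetectionConfig:
    """Settings for somite-event detection.

    ``threshold_um`` is the SEG-increment cut-off: a backward difference
    strictly greater than it signals a new somite.  ``length_mode`` selects
    how each somite's A-P length is computed: ``"increment"`` sums the
    supra-threshold step differences of the event (literal reading of the
    method), ``"plateau"`` differences the medians of the constant segments
    flanking the event (noise-robust alternative).  With
    ``merge_consecutive`` a maximal run of consecutive supra-threshold
    steps -- a cleft sharpening across several frames -- counts as one
    somite.  ``nominal_interval_min`` is only used to warn about sampling
    gaps longer than twice the nominal interval, which could hide an event.
    """

    threshold_um: float = DEFAULT_THRESHOLD_UM
    length_mode: str = "increment"
    merge_consecutive: bool = True
    nominal_interval_min: float = DEFAULT_INTERVAL_MIN

    def __post_init__(self) -> None:
        if not self.threshold_um > 0:
            raise InvalidConfigError("threshold_um must be > 0")
        if self.length_mode not in ("increment", "plateau"):
            raise InvalidConfigError(
                f"length_mode must be 'increment' or 'plateau', got {self.length_mode!r}"
            )
        if not self.nominal_interval_min > 0:
            raise InvalidConfigError("nominal_interval_min must be > 0")


@dataclass(frozen=True)
class SomiteRecord:
    """One detected somite: craniocaudal number, onset time and A-P length."""

    embryo_id: str
    somite_number: int
    onset_time_min: float
    length_um: float


@dataclass(frozen=True)
class PeriodRecord:
    """Formation period of one somite.

    ``period_min`` is the onset-time difference to the preceding somite; it
    is ``None`` exactly for the first somite of each recorded series, whose
    own formation predates the recording.
    """

    embryo_id: str
    somite_number: int
    period_min: float | None


@dataclass(frozen=True)
class GroupRateEstimate:
    """Regression-slope somitogenesis rate for a contiguous somite group.

    The slope (min/somite) of onset time on somite number, with one
    intercept per embryo and a single shared slope, together with its
    t-based 95 % confidence interval.
    """

    group_label: str
    slope_min_per_somite: float
    ci95_low: float
    ci95_high: float
    n_embryos: int
    n_points: int


@dataclass(frozen=True)
class VarianceTestResult:
    """Brown-Forsythe variance-homogeneity test result."""

    F_value: float
    df_between: int
    df_within: int
    p_value: float


# --------------------------------------------------------------------------
# Synthetic-embryo generation
# --------------------------------------------------------------------------


def default_period_profile(somite_number: int) -> float:
    """Mean formation period (min) by axial position.

    Occipital somites (1-5) form every ~75 min; somites 6 onward every
    ~90 min, matching the trunk rate.
    """
    return 75.0 if somite_number <= 5 else 90.0


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for synthetic SEG staircase generation.

    Defaults emulate the measured study conditions: 11 embryos recorded at
    3-min intervals from the 1- to the 9-somite stage, occipital somites
    forming every ~75 min and later somites every ~90 min, somite lengths
    around 140 um, and ~10 um of additive per-frame measurement noise.

    Parameters
    ----------
    n_embryos, start_somite, n_somites
        Cohort size and the recorded somite window
        [start_somite, start_somite + n_somites - 1].
    period_profile
        Somite number -> mean formation period (min).  A mapping, a callable,
        a scalar, or None for the built-in occipital/trunk profile.
    period_sd
        Between-somite SD of the true period (min).  Default 15 min, in the
        middle of the observed per-somite variability once detection and
        sampling-quantization noise are discounted.
    length_profile, length_sd
        Mean somite A-P length (um; same accepted forms as period_profile)
        and its SD.  Defaults 140 um and 18 um.
    noise_sd
        SD of additive per-frame measurement noise (um), truncated at
        +/- 2*noise_sd.  Default 10 um.
    cleft_frames
        Number of frames over which each length increment is spread
        (linear ramp); 1 means an instantaneous cleft.
    sample_interval
        Sampling interval in minutes (default 3).
    dropout_rate
        Fraction of frames removed uniformly at random (missed captures);
        the first frame is always kept.
    tail_frames
        Frames recorded after the last somite has fully formed.
    seed
        Seed for all randomness; output is bit-identical for identical
        (config, seed).
    """

    n_embryos: int = 11
    start_somite: int = 1
    n_somites: int = 9
    period_profile: Mapping[int, float] | Callable[[int], float] | float | None = None
    period_sd: float = 15.0
    length_profile: Mapping[int, float] | Callable[[int], float] | float = 140.0
    length_sd: float = 18.0
    noise_sd: float = 10.0
    cleft_frames: int = 1
    sample_interval: float = DEFAULT_INTERVAL_MIN
    dropout_rate: float = 0.0
    tail_frames: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_embryos < 1 or self.n_somites < 1:
            raise InvalidConfigError("n_embryos and n_somites must be >= 1")
        if self.start_somite < 1:
            raise InvalidConfigError("start_somite must be >= 1")
        for name in ("period_sd", "length_sd", "noise_sd", "dropout_rate"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.dropout_rate >= 1:
            raise InvalidConfigError("dropout_rate must be < 1")
        if self.cleft_frames < 1:
            raise InvalidConfigError("cleft_frames must be >= 1")
        if not self.sample_interval > 0:
            raise InvalidConfigError("sample_interval must be > 0")
        # A somite's plateau must last at least one frame beyond its ramp.
        min_period = self.cleft_frames * self.sample_interval
        for n in self.somite_numbers()[1:]:
            if self.mean_period(n) < min_period:
                raise InvalidConfigError(
                    f"mean period of somite {n} ({self.mean_period(n)} min) is "
                    f"shorter than cleft_frames*sample_interval ({min_period} min); "
                    "no plateau would remain"
                )

    def somite_numbers(self) -> list[int]:
        return list(range(self.start_somite, self.start_somite + self.n_somites))

    def mean_period(self, somite_number: int) -> float:
        return _profile_value(self.period_profile, somite_number, default_period_profile)

    def mean_length(self, somite_number: int) -> float:
        return _profile_value(self.length_profile, somite_number, lambda n: 140.0)


def _profile_value(
    profile: Mapping[int, float] | Callable[[int], float] | float | None,
    somite_number: int,
    default: Callable[[int], float],
) -> float:
    if profile is None:
        return float(default(somite_number))
    if isinstance(profile, Mapping):
        try:
            return float(profile[somite_number])
        except KeyError:
            raise InvalidConfigError(
                f"profile does not cover somite {somite_number}"
            ) from None
    if callable(profile):
        return float(profile(somite_number))
    return float(profile)


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    """Normal draw redrawn until strictly greater than ``low``."""
    if sd == 0:
        if mean <= low:
            raise InvalidConfigError(f"deterministic draw {mean} <= bound {low}")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    raise InvalidConfigError(
        f"could not draw a value > {low} from N({mean}, {sd}) in 1000 tries"
    )


def simulate(
    config: SimulationConfig,
) -> tuple[list[MeasurementSeries], pd.DataFrame]:
    """Generate synthetic SEG trajectories with known ground truth.

    For each embryo, per-somite true lengths and periods are drawn
    (positive-truncated normals), onsets accumulate from time 0 (the first
    somite of the window is present at recording start), SEG(t) is the
    running sum of the lengths of formed somites with each increment spread
    linearly over ``cleft_frames`` frames, truncated Gaussian measurement
    noise is added, and the trajectory is sampled on the (possibly
    dropout-thinned) regular grid.

    Returns
    -------
    series : list of MeasurementSeries
    truth : DataFrame
        Columns ``embryo_id, somite_number, length_um, onset_time_min,
        period_min`` (period NaN for each embryo's first somite).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sample_interval
    somites = config.somite_numbers()
    min_period = config.cleft_frames * dt

    all_series: list[MeasurementSeries] = []
    truth_rows: list[dict] = []

    width = max(2, len(str(config.n_embryos)))
    for e in range(config.n_embryos):
        embryo_id = f"sim{e + 1:0{width}d}"
        lengths = np.array(
            [
                _draw_positive(rng, config.mean_length(n), config.length_sd, 0.0)
                for n in somites
            ]
        )
        # Period of the window's first somite predates the recording.
        periods = np.full(len(somites), np.nan)
        for k, n in enumerate(somites[1:], start=1):
            periods[k] = _draw_positive(
                rng, config.mean_period(n), config.period_sd, min_period
            )
        onsets = np.concatenate([[0.0], np.cumsum(periods[1:])])

        n_frames = (
            int(np.ceil(onsets[-1] / dt))
            + config.cleft_frames
            + config.tail_frames
        )
        grid = np.arange(n_frames) * dt
        increments = np.zeros(n_frames)
        for k in range(1, len(somites)):
            f0 = int(np.ceil(onsets[k] / dt - 1e-9))
            chunk = lengths[k] / config.cleft_frames
            increments[f0 : f0 + config.cleft_frames] += chunk
        seg = lengths[0] + np.cumsum(increments)

        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, n_frames)
            bound = 2.0 * config.noise_sd
            seg_obs = seg + np.clip(noise, -bound, bound)
        else:
            seg_obs = seg.copy()

        keep = np.ones(n_frames, dtype=bool)
        if config.dropout_rate > 0:
            keep = rng.random(n_frames) >= config.dropout_rate
            keep[0] = True  # anchor the first somite's measurement

        all_series.append(
            MeasurementSeries(
                embryo_id=embryo_id,
                times=grid[keep],
                lengths=np.maximum(seg_obs[keep], 0.0),
                start_somite=config.start_somite,
            )
        )
        for k, n in enumerate(somites):
            truth_rows.append(
                {
                    "embryo_id": embryo_id,
                    "somite_number": n,
                    "length_um": lengths[k],
                    "onset_time_min": onsets[k],
                    "period_min": periods[k],
                }
            )

    truth = pd.DataFrame(truth_rows)
    return all_series, truth


# --------------------------------------------------------------------------
# Somite-event detection
# --------------------------------------------------------------------------


def detect_somites(
    series: MeasurementSeries, config: DetectionConfig | None = None
) -> list[SomiteRecord]:
    """Detect somite-formation events from SEG length increments.

    The first measurement of SEG corresponds to the length of the first
    somite of the window, so the first record always has
    ``somite_number = start_somite``, onset at the first time point, and (in
    increment mode) the first measured length.  Thereafter, every backward
    difference strictly greater than ``config.threshold_um`` signals a new
    somite; with ``merge_consecutive`` a maximal run of consecutive
    supra-threshold steps is one event, whose onset is the first frame at
    which the new somite is visible (the later frame of the first triggering
    pair).

    Lengths per event: increment mode sums the event's supra-threshold step
    differences; plateau mode takes the median SEG of the constant segment
    following the event minus the median of the segment preceding it (end
    segments use all available frames; the first somite's length is the
    median of the pre-first-event segment).

    Negative differences never trigger or cancel events.
    """
    if config is None:
        config = DetectionConfig()
    t, y = series.times, series.lengths
    n = t.size

    if n >= 2:
        gaps = np.diff(t)
        big = gaps > 2.0 * config.nominal_interval_min
        if np.any(big):
            logger.warning(
                "%s: %d sampling gap(s) exceed 2x nominal interval "
                "(max %.1f min); an event could be hidden",
                series.embryo_id,
                int(big.sum()),
                float(gaps.max()),
            )

    diffs = np.diff(y) if n >= 2 else np.empty(0)
    supra = diffs > config.threshold_um  # strict: a step of exactly theta is no event

    # Events as (start, end) inclusive index ranges in difference space;
    # diff index i couples frames i and i+1.
    events: list[tuple[int, int]] = []
    if config.merge_consecutive:
        i = 0
        while i < supra.size:
            if supra[i]:
                j = i
                while j + 1 < supra.size and supra[j + 1]:
                    j += 1
                events.append((i, j))
                i = j + 1
            else:
                i += 1
    else:
        events = [(int(i), int(i)) for i in np.flatnonzero(supra)]

    records: list[SomiteRecord] = []
    if config.length_mode == "increment":
        first_length = float(y[0])
    else:
        first_end = events[0][0] if events else n - 1  # last frame before 1st event
        plateau_medians = [float(np.median(y[0 : first_end + 1]))]
        for k, (s, e) in enumerate(events):
            seg_start = e + 1  # first frame after the ramp completes
            seg_end = events[k + 1][0] if k + 1 < len(events) else n - 1
            plateau_medians.append(float(np.median(y[seg_start : seg_end + 1])))
        first_length = plateau_medians[0]

    records.append(
        SomiteRecord(
            embryo_id=series.embryo_id,
            somite_number=series.start_somite,
            onset_time_min=float(t[0]),
            length_um=first_length,
        )
    )
    for k, (s, e) in enumerate(events):
        if config.length_mode == "increment":
            run = diffs[s : e + 1]
            length = float(run[run > config.threshold_um].sum())
        else:
            length = plateau_medians[k + 1] - plateau_medians[k]
        records.append(
            SomiteRecord(
                embryo_id=series.embryo_id,
                somite_number=series.start_somite + k + 1,
                onset_time_min=float(t[s + 1]),
                length_um=length,
            )
        )
    return records


def compute_periods(records: Sequence[SomiteRecord]) -> list[PeriodRecord]:
    """Formation period of each somite: onset(n) minus onset(n-1).

    The first somite of the series gets an undefined (None) period, since
    its formation predates the recording.  All records must come from a
    single embryo and be ordered by somite number.
    """
    if not records:
        return []
    ids = {r.embryo_id for r in records}
    if len(ids) > 1:
        raise InvalidInputError(
            f"records from multiple embryos mixed: {sorted(ids)}"
        )
    numbers = [r.somite_number for r in records]
    if numbers != sorted(numbers):
        raise InvalidInputError("records must be ordered by somite_number")
    out: list[PeriodRecord] = [
        PeriodRecord(records[0].embryo_id, records[0].somite_number, None)
    ]
    for prev, cur in zip(records[:-1], records[1:]):
        out.append(
            PeriodRecord(
                cur.embryo_id,
                cur.somite_number,
                float(cur.onset_time_min - prev.onset_time_min),
            )
        )
    return out


def records_to_frame(
    records: Sequence[SomiteRecord], periods: Sequence[PeriodRecord] | None = None
) -> pd.DataFrame:
    """Tabulate somite records (and optionally their periods) as a DataFrame."""
    df = pd.DataFrame(
        [dataclasses.asdict(r) for r in records],
        columns=["embryo_id", "somite_number", "onset_time_min", "length_um"],
    )
    if periods is not None:
        pf = pd.DataFrame(
            [
                {
                    "embryo_id": p.embryo_id,
                    "somite_number": p.somite_number,
                    "period_min": np.nan if p.period_min is None else p.period_min,
                }
                for p in periods
            ],
            columns=["embryo_id", "somite_number", "period_min"],
        )
        df = df.merge(pf, on=["embryo_id", "somite_number"], how="left")
    return df


def analyze_series(
    series: Iterable[MeasurementSeries], config: DetectionConfig | None = None
) -> pd.DataFrame:
    """Detect somites and periods for a collection of series, pooled.

    Returns a DataFrame with columns ``embryo_id, somite_number,
    onset_time_min, length_um, period_min``.
    """
    frames = []
    for s in series:
        recs = detect_somites(s, config)
        pers = compute_periods(recs)
        frames.append(records_to_frame(recs, pers))
    if not frames:
        return pd.DataFrame(
            columns=[
                "embryo_id",
                "somite_number",
                "onset_time_min",
                "length_um",
                "period_min",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Group statistics
# --------------------------------------------------------------------------


def group_rate(
    records: pd.DataFrame,
    somite_range: tuple[int, int],
    group_label: str | None = None,
) -> GroupRateEstimate:
    """Somitogenesis rate of a somite group, as a regression slope.

    Fits ordinary least squares of onset time (min) on somite number with
    one intercept per embryo and a single shared slope, pooling all embryos
    that sampled somites in the inclusive range ``somite_range``.  The
    per-embryo intercepts absorb the arbitrary absolute start time of each
    recording; the shared slope is the group's formation period in
    min/somite, returned with its t-based 95 % confidence interval.
    """
    lo, hi = somite_range
    if group_label is None:
        group_label = f"somites {lo}-{hi}"
    sub = records[(records["somite_number"] >= lo) & (records["somite_number"] <= hi)]
    sub = sub.dropna(subset=["onset_time_min"])
    if sub["somite_number"].nunique() < 2:
        raise DegenerateDesignError(
            f"{group_label}: need >= 2 distinct somite numbers to estimate a slope"
        )
    embryos = pd.Categorical(sub["embryo_id"])
    x = sub["somite_number"].to_numpy(dtype=float)
    y = sub["onset_time_min"].to_numpy(dtype=float)
    # Design: per-embryo dummy intercepts (no global intercept) + shared slope.
    dummies = (embryos.codes[:, None] == np.arange(len(embryos.categories))).astype(float)
    X = np.column_stack([dummies, x])
    res = sm.OLS(y, X).fit(use_t=True)
    slope = float(res.params[-1])
    ci = res.conf_int(alpha=0.05)
    ci_low, ci_high = float(ci[-1][0]), float(ci[-1][1])
    if not np.isfinite(ci_low):  # saturated exact fit: zero residual df
        ci_low = ci_high = slope
    return GroupRateEstimate(
        group_label=group_label,
        slope_min_per_somite=slope,
        ci95_low=ci_low,
        ci95_high=ci_high,
        n_embryos=int(len(embryos.categories)),
        n_points=int(len(sub)),
    )


def summarize_per_somite(
    records: pd.DataFrame, decimals: int | None = None
) -> pd.DataFrame:
    """Per-somite summary: n embryos, mean +/- SD of length and period.

    Uses the sample SD (n-1 denominator); undefined periods are excluded
    rather than imputed, and a single observation yields a blank (NaN) SD.
    ``decimals`` rounds the statistics for report output (2 is the table
    convention).
    """

    def _agg(g: pd.DataFrame) -> pd.Series:
        periods = g["period_min"].dropna() if "period_min" in g else pd.Series(dtype=float)
        return pd.Series(
            {
                "n": int(g["length_um"].notna().sum()),
                "length_mean": g["length_um"].mean(),
                "length_sd": g["length_um"].std(ddof=1),
                "period_mean": periods.mean() if len(periods) else np.nan,
                "period_sd": periods.std(ddof=1) if len(periods) else np.nan,
            }
        )

    out = (
        records.groupby("somite_number")
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    if decimals is not None:
        for c in ("length_mean", "length_sd", "period_mean", "period_sd"):
            out[c] = out[c].round(decimals)
    return out


def brown_forsythe(samples: Sequence[Sequence[float]]) -> VarianceTestResult:
    """Brown-Forsythe test for homogeneity of variances across groups.

    Computes the absolute deviations of individual observations from their
    respective group medians, z_ij = |y_ij - median_j|, and performs a
    one-way ANOVA on the z values: F with (p-1, N-p) degrees of freedom and
    the upper-tail F-distribution p-value.  Centering on medians rather
    than means makes the test robust to outliers.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise InvalidInputError(f"group {i} has {g.size} observation(s); need >= 2")
        if not np.all(np.isfinite(g)):
            raise InvalidInputError(f"group {i} contains non-finite values")
    z = [np.abs(g - np.median(g)) for g in groups]
    N = sum(g.size for g in groups)
    p = len(groups)
    grand = sum(zi.sum() for zi in z) / N
    ssb = sum(zi.size * (zi.mean() - grand) ** 2 for zi in z)
    ssw = sum(((zi - zi.mean()) ** 2).sum() for zi in z)
    df_between, df_within = p - 1, N - p
    if ssw == 0:
        raise UndefinedVarianceError(
            "all absolute deviations identical within groups (SSW = 0); "
            "F is undefined"
        )
    F = (ssb / df_between) / (ssw / df_within)
    p_value = float(scipy.stats.f.sf(F, df_between, df_within))
    return VarianceTestResult(
        F_value=float(F), df_between=df_between, df_within=df_within, p_value=p_value
    )


# --------------------------------------------------------------------------
# File I/O and pipeline driver
# --------------------------------------------------------------------------

CANONICAL_COLUMNS = ("embryo_id", "time_min", "seg_length_um")


@dataclass
class ColumnMap:
    """Adapts an input table's schema to the canonical measurement columns.

    ``columns`` maps canonical role -> source column name for the roles
    ``embryo_id``, ``time_min``, ``seg_length_um`` and (optionally)
    ``operator``.  ``time_factor`` / ``length_factor`` convert the source
    units to minutes / micrometres.  ``start_somite`` is either a single
    integer for all embryos or a mapping embryo_id -> first somite of that
    recording window (e.g. late-trunk windows starting at somite 14).
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "embryo_id": "embryo_id",
            "time_min": "time_min",
            "seg_length_um": "seg_length_um",
            "operator": "operator",
        }
    )
    time_factor: float = 1.0
    length_factor: float = 1.0
    start_somite: int | Mapping[str, int] = 1

    def __post_init__(self) -> None:
        missing = [r for r in CANONICAL_COLUMNS if r not in self.columns]
        if missing:
            raise InvalidConfigError(f"colmap missing canonical roles: {missing}")
        starts = (
            self.start_somite.values()
            if isinstance(self.start_somite, Mapping)
            else [self.start_somite]
        )
        if any(s < 1 for s in starts):
            raise InvalidConfigError("start_somite must be >= 1")

    def start_for(self, embryo_id: str) -> int:
        if isinstance(self.start_somite, Mapping):
            return int(self.start_somite.get(embryo_id, 1))
        return int(self.start_somite)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "columns" in raw:
            kwargs["columns"] = dict(raw["columns"])
        for key in ("time_factor", "length_factor", "start_somite"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_measurements(
    path: str | Path, colmap: ColumnMap | None = None
) -> list[MeasurementSeries]:
    """Read a measurement table into one MeasurementSeries per embryo.

    The canonical schema has columns ``embryo_id, operator, time_min,
    seg_length_um`` (header required, ``operator`` optional); other schemas
    are adapted through ``colmap``.  Rows are sorted by time within each
    embryo; rows with missing values are logged, counted and dropped.
    Non-numeric times/lengths and duplicate (embryo, time) rows raise with
    the offending row numbers.
    """
    if colmap is None:
        colmap = ColumnMap()
    df = _read_table(path)

    rename = {src: role for role, src in colmap.columns.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [r for r in CANONICAL_COLUMNS if r not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: cannot map columns {missing}; found {list(df.columns)}"
        )

    for col in ("time_min", "seg_length_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
            raise InvalidInputError(
                f"{path}: non-numeric {col} values at file rows {rows[:10]}"
            )
        df[col] = coerced

    n_missing = int(df[["embryo_id", "time_min", "seg_length_um"]].isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%s: dropped %d row(s) with missing values", path, n_missing)
        df = df.dropna(subset=["embryo_id", "time_min", "seg_length_um"])

    dup = df.duplicated(subset=["embryo_id", "time_min"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise InvalidInputError(
            f"{path}: duplicate (embryo_id, time_min) rows at file rows {rows[:10]}"
        )

    df["time_min"] = df["time_min"] * colmap.time_factor
    df["seg_length_um"] = df["seg_length_um"] * colmap.length_factor

    series = []
    for embryo_id, g in df.groupby("embryo_id", sort=True):
        g = g.sort_values("time_min")
        operator = None
        if "operator" in g.columns:
            ops = g["operator"].dropna().unique()
            operator = str(ops[0]) if len(ops) == 1 else None
        series.append(
            MeasurementSeries(
                embryo_id=str(embryo_id),
                times=g["time_min"].to_numpy(),
                lengths=g["seg_length_um"].to_numpy(),
                start_somite=colmap.start_for(str(embryo_id)),
                operator_id=operator,
            )
        )
    return series


def write_measurements(series: Iterable[MeasurementSeries], path: str | Path) -> None:
    """Write series as a canonical measurement CSV."""
    rows = []
    for s in series:
        for t, y in zip(s.times, s.lengths):
            rows.append(
                {
                    "embryo_id": s.embryo_id,
                    "operator": s.operator_id,
                    "time_min": t,
                    "seg_length_um": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write pooled somite/period records CSV (blank field = undefined period)."""
    records.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a records CSV written by :func:`write_records`."""
    df = _read_table(path)
    required = {"embryo_id", "somite_number", "onset_time_min", "length_um"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: records file missing columns {sorted(missing)}")
    df["embryo_id"] = df["embryo_id"].astype(str)
    return df


def _rate_rows(
    records: pd.DataFrame, groups: Sequence[tuple[int, int]]
) -> pd.DataFrame:
    rows = []
    for lo, hi in groups:
        try:
            est = group_rate(records, (lo, hi))
        except DegenerateDesignError as exc:
            logger.info("skipping rate group %d-%d: %s", lo, hi, exc)
            continue
        rows.append(dataclasses.asdict(est))
    return pd.DataFrame(
        rows,
        columns=[
            "group_label",
            "slope_min_per_somite",
            "ci95_low",
            "ci95_high",
            "n_embryos",
            "n_points",
        ],
    )


def _bf_rows(
    records: pd.DataFrame,
    splits: Mapping[str, tuple[tuple[int, int], tuple[int, int]]],
) -> dict:
    out = {}
    for var, ((lo1, hi1), (lo2, hi2)) in splits.items():
        g1 = records.loc[
            records["somite_number"].between(lo1, hi1), var
        ].dropna().to_numpy()
        g2 = records.loc[
            records["somite_number"].between(lo2, hi2), var
        ].dropna().to_numpy()
        key = f"{var}:{lo1}-{hi1}_vs_{lo2}-{hi2}"
        if len(g1) < 2 or len(g2) < 2:
            logger.info("skipping Brown-Forsythe on %s: a group has <2 observations", key)
            continue
        try:
            res = brown_forsythe([g1, g2])
        except UndefinedVarianceError as exc:
            out[key] = {"error": str(exc)}
            continue
        out[key] = dataclasses.asdict(res)
    return out


def run_pipeline(
    input_path: str | Path,
    out_dir: str | Path,
    detection: DetectionConfig | None = None,
    colmap: ColumnMap | None = None,
    rate_groups: Sequence[tuple[int, int]] = DEFAULT_RATE_GROUPS,
    bf_splits: Mapping[str, tuple[tuple[int, int], tuple[int, int]]] = DEFAULT_BF_SPLITS,
    seed: int | None = None,
) -> dict:
    """Run detection -> periods -> statistics -> report on a measurement file.

    Writes to ``out_dir``: ``records.csv`` (per-somite records with periods),
    ``summary.csv`` (per-somite mean +/- SD table, 2 decimals),
    ``group_rates.csv``, ``brown_forsythe.json`` and ``manifest.json``
    (versions, configuration, input checksum surrogate).  Returns the bundle
    as a dict of in-memory objects.  Output is a pure function of
    (input file, configuration).
    """
    detection = detection or DetectionConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    series = read_measurements(input_path, colmap)
    if not series:
        raise InvalidInputError(f"{input_path}: no measurement series found")
    n_rows = sum(len(s) for s in series)
    logger.info("read %d series, %d measurements", len(series), n_rows)

    records = analyze_series(series, detection)
    summary = summarize_per_somite(records, decimals=2)
    rates = _rate_rows(records, rate_groups)
    bf = _bf_rows(records, bf_splits)

    write_records(records, out_dir / "records.csv")
    summary.to_csv(out_dir / "summary.csv", index=False)
    rates.to_csv(out_dir / "group_rates.csv", index=False)
    with open(out_dir / "brown_forsythe.json", "w") as fh:
        json.dump(bf, fh, indent=2)

    import statsmodels

    manifest = {
        "input": str(input_path),
        "n_series": len(series),
        "n_measurements": n_rows,
        "n_somites_detected": int(len(records)),
        "detection": dataclasses.asdict(detection),
        "rate_groups": [list(g) for g in rate_groups],
        "bf_splits": {k: [list(a), list(b)] for k, (a, b) in bf_splits.items()},
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "series": series,
        "records": records,
        "summary": summary,
        "rates": rates,
        "brown_forsythe": bf,
        "manifest": manifest,
    }
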