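"""Somite-event detection on staircase SEG trajectories."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somite_staircase import (
    DetectionConfig,
    InvalidInputError,
    MeasurementSeries,
    detect_somites,
)
from conftest import make_staircase


class TestFirstSomite:
    def test_flat_series_yields_only_the_starting_somite(self):
        s = MeasurementSeries("e", [0, 3, 6, 9], [120, 121, 119, 121])
        recs = detect_somites(s, DetectionConfig())
        assert len(recs) == 1
        r = recs[0]
        assert (r.somite_number, r.onset_time_min, r.length_um) == (1, 0.0, 120.0)

    def test_single_point_series_is_valid_and_yields_one_record(self):
        s = MeasurementSeries("e", [0.0], [130.0])
        recs = detect_somites(s)
        assert len(recs) == 1
        assert recs[0].length_um == 130.0

    def test_start_somite_number_is_respected(self):
        s = MeasurementSeries("e", [0, 3], [120, 250], start_somite=14)
        recs = detect_somites(s)
        assert [r.somite_number for r in recs] == [14, 15]


class TestEventDetection:
    def test_two_plateau_staircase(self, clean_staircase):
        recs = detect_somites(clean_staircase)
        assert [(r.somite_number, r.onset_time_min, r.length_um) for r in recs] == [
            (1, 0.0, 120.0),
            (2, 90.0, 140.0),
        ]

    @pytest.mark.parametrize(
        "step,n_expected",
        [(50.0, 1), (50.5, 2), (49.9, 1), (51.0, 2)],
        ids=["at-threshold", "just-above", "below", "above"],
    )
    def test_threshold_is_a_strict_inequality(self, step, n_expected):
        s = make_staircase([100.0, 100.0 + step], [3, 3])
        assert len(detect_somites(s)) == n_expected

    def test_negative_differences_never_trigger(self):
        y = [140.0, 200.0, 140.0, 200.0, 140.0]  # rises of 60 um, drops of 60 um
        s = MeasurementSeries("e", [0, 3, 6, 9, 12], y)
        recs = detect_somites(s)
        # the two +60 rises trigger; the -60 drops neither trigger nor cancel
        assert len(recs) == 3
        assert all(r.length_um > 0 for r in recs)

    def test_multi_frame_burst_merges_into_one_event(self):
        # cleft sharpens across two frames: +70 then +80
        s = MeasurementSeries("e", [0, 3, 6, 9, 12], [100, 100, 170, 250, 250])
        merged = detect_somites(s, DetectionConfig(merge_consecutive=True))
        assert len(merged) == 2
        assert merged[1].onset_time_min == 6.0  # first frame the somite is visible
        assert merged[1].length_um == pytest.approx(150.0)

        split = detect_somites(s, DetectionConfig(merge_consecutive=False))
        assert len(split) == 3
        assert [r.length_um for r in split[1:]] == [70.0, 80.0]

    def test_onset_is_the_later_frame_of_the_triggering_pair(self, clean_staircase):
        recs = detect_somites(clean_staircase)
        assert recs[1].onset_time_min == 90.0


class TestPlateauLengthMode:
    def test_plateau_lengths_match_increment_on_clean_data(self, clean_staircase):
        inc = detect_somites(clean_staircase, DetectionConfig(length_mode="increment"))
        pla = detect_somites(clean_staircase, DetectionConfig(length_mode="plateau"))
        assert [r.length_um for r in pla] == pytest.approx([r.length_um for r in inc])

    def test_plateau_mode_is_robust_to_an_outlier_frame(self):
        # one wild frame inside plateau 2 corrupts increment sums, not medians
        y = np.array([120.0] * 10 + [260.0] * 10)
        y[14] = 500.0
        t = np.arange(20) * 3.0
        s = MeasurementSeries("e", t, y)
        pla = detect_somites(s, DetectionConfig(length_mode="plateau"))
        lengths = [r.length_um for r in pla if r.somite_number >= 2]
        assert lengths[0] == pytest.approx(140.0)

    def test_plateau_first_somite_uses_pre_event_median(self):
        s = make_staircase([118.0, 122.0, 120.0, 260.0], [1, 1, 1, 5], noise=None)
        # merge the three jittery frames into one plateau by keeping steps < 50
        pla = detect_somites(s, DetectionConfig(length_mode="plateau"))
        assert pla[0].length_um == pytest.approx(np.median([118, 122, 120]))


class TestInvariants:
    def test_conservation_increment_mode_noise_free(self):
        s = make_staircase([120, 260, 400, 555], [4, 5, 3, 6])
        recs = detect_somites(s, DetectionConfig(length_mode="increment"))
        assert sum(r.length_um for r in recs) == pytest.approx(555.0, abs=1e-12)

    @given(
        steps=st.lists(st.floats(51.0, 200.0), min_size=0, max_size=5),
        frames=st.lists(st.integers(2, 8), min_size=6, max_size=6),
        theta_pair=st.tuples(st.floats(10.0, 80.0), st.floats(0.1, 100.0)),
    )
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, steps, frames, theta_pair):
        """Raising the threshold never increases the number of detected somites."""
        levels = 120.0 + np.concatenate([[0.0], np.cumsum(steps)])
        s = make_staircase(levels, frames[: len(levels)])
        lo, extra = theta_pair
        n_lo = len(detect_somites(s, DetectionConfig(threshold_um=lo)))
        n_hi = len(detect_somites(s, DetectionConfig(threshold_um=lo + extra)))
        assert n_hi <= n_lo

    @given(
        steps=st.lists(st.floats(95.0, 200.0), min_size=1, max_size=5),
        frames=st.lists(st.integers(2, 8), min_size=6, max_size=6),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_noise_preserves_event_count(self, steps, frames, seed):
        """Noise bounded by eps with 2*eps < threshold creates no spurious events,
        and misses none when every true step clears threshold + 2*eps."""
        eps = 22.0  # 2*eps = 44 < 50; steps >= 95 > 50 + 44
        levels = 120.0 + np.concatenate([[0.0], np.cumsum(steps)])
        frames = frames[: len(levels)]
        clean = make_staircase(levels, frames)
        noise = np.random.default_rng(seed).uniform(-eps, eps, sum(frames))
        noisy = make_staircase(levels, frames, noise=noise)
        assert len(detect_somites(noisy)) == len(detect_somites(clean)) == len(levels)

    @given(
        steps=st.lists(st.floats(51.0, 200.0), min_size=1, max_size=6),
        frames=st.lists(st.integers(1, 6), min_size=7, max_size=7),
    )
    @settings(max_examples=50, deadline=None)
    def test_order_and_numbering(self, steps, frames):
        levels = 100.0 + np.concatenate([[0.0], np.cumsum(steps)])
        s = make_staircase(levels, frames[: len(levels)])
        recs = detect_somites(s)
        onsets = [r.onset_time_min for r in recs]
        numbers = [r.somite_number for r in recs]
        assert onsets == sorted(onsets) and len(set(onsets)) == len(onsets)
        assert numbers == list(range(numbers[0], numbers[0] + len(numbers)))


class TestValidation:
    def test_empty_series_rejected(self):
        with pytest.raises(InvalidInputError):
            MeasurementSeries("e", [], [])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(InvalidInputError):
            MeasurementSeries("e", [0, 3, 3], [1, 2, 3])

    def test_negative_length_rejected(self):
        with pytest.raises(InvalidInputError):
            MeasurementSeries("e", [0, 3], [100, -1])

    def test_long_sampling_gap_logs_a_warning(self, caplog):
        s = MeasurementSeries("e", [0, 3, 30], [100, 100, 100])
        with caplog.at_level(logging.WARNING, logger="somite_staircase"):
            detect_somites(s)
        assert any("gap" in rec.message for rec in caplog.records)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(threshold_um=0)
        with pytest.raises(ValueError):
            DetectionConfig(length_mode="banana")
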