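import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from somite_staircase import DetectionConfig, MeasurementSeries, SimulationConfig, simulate


@pytest.fixture
def clean_staircase() -> MeasurementSeries:
    """Noise-free two-plateau staircase: somite 1 (120 um) then somite 2 (140 um) at t=90."""
    t = np.arange(0, 180, 3.0)
    y = np.where(t < 90, 120.0, 260.0)
    return MeasurementSeries("emb1", t, y)


@pytest.fixture
def default_config() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def occipital_cohort():
    """Seeded synthetic cohort at the study conditions (11 embryos, somites 1-9)."""
    cfg = SimulationConfig(seed=42)
    series, truth = simulate(cfg)
    return cfg, series, truth


def make_staircase(
    plateau_lengths, plateau_frames, dt=3.0, noise=None, embryo_id="emb", start_somite=1
) -> MeasurementSeries:
    """Build a piecewise-constant staircase from cumulative plateau specs.

    ``plateau_lengths[k]`` is the SEG value on plateau k, held for
    ``plateau_frames[k]`` frames.
    """
    y = np.concatenate(
        [np.full(nf, lv, dtype=float) for lv, nf in zip(plateau_lengths, plateau_frames)]
    )
    t = np.arange(y.size) * dt
    if noise is not None:
        y = y + np.asarray(noise, dtype=float)
    return MeasurementSeries(embryo_id, t, y, start_somite=start_somite)
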