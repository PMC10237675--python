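"""Shared synthetic fixtures (generated at test time; nothing on disk)."""

import numpy as np
import pytest

from pulsecap import (
    SimulationParams,
    draw_interval_sequence,
    normalize_trajectory,
    select_tracks,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def gap_pulses():
    """15-h interval-with-gap protocol (tau_geom=10, tau_gap=20)."""
    return draw_interval_sequence(10, 20, 900, seed=11)


@pytest.fixture(scope="session")
def noiseless_ensemble(gap_pulses):
    """30 identical deterministic responder cells; exact reconstruction."""
    params = SimulationParams.noiseless()
    raws, truth = simulate_experiment(gap_pulses, 30, params, seed=21)
    xs = [normalize_trajectory(r) for r in raws]
    return raws, truth, xs


@pytest.fixture(scope="session")
def noisy_ensemble(gap_pulses):
    """100 cells at default (noisy, heterogeneous) generator settings,
    after the standard f=20% track selection and normalization."""
    params = SimulationParams()
    raws, truth = simulate_experiment(gap_pulses, 100, params, seed=22)
    selected = select_tracks(raws, f=0.2)
    xs = [normalize_trajectory(r) for r in selected]
    return raws, truth, xs
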