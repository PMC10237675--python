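"""Synthetic single-cell ERK-KTR trajectory generator.

Emulates the measured phenomenology of optogenetically driven ERK
activity pulses read out by a kinase translocation reporter (KTR):

* a stereotyped unimodal response kernel -- translocation rises steepest
  between 2 and 3 min after a light pulse, peaks at 6 min and rebounds
  fastest around 11 min;
* a refractory period -- the probability that a cell mounts a
  distinguishable response grows with the interval since the previous
  pulse (about 70% at 10 min, 90% at 15 min);
* a non-responder subpopulation (~20% of cells) whose reporter or
  receptor is non-functional;
* cell-to-cell amplitude and timing variability, per-minute additive
  observation noise, and a slow multiplicative drift of the imaging field
  intensity (so that the first normalization step is exercised).

The generator produces *raw* nuclear-intensity tracks plus the ground
truth (pulse sequence and per-cell per-pulse response flags), so every
downstream stage of the analysis can be tested without real microscopy
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta

from .protocols import PulseSequence

__all__ = [
    "SimulationParams",
    "CellPhenotype",
    "RawTrajectory",
    "GroundTruth",
    "sample_phenotypes",
    "response_kernel",
    "response_probability",
    "simulate_experiment",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic trajectory generator.

    Kernel landmark times are minutes after the light pulse.  The
    refractory logistic is calibrated so that the response probability is
    ~0.70 at a 10-min and ~0.90 at a 15-min preceding interval.
    Amplitudes are on the translocation scale (fraction of nuclear
    reporter leaving the nucleus); intensities are arbitrary fluorescence
    units.
    """

    kernel_peak_time: float = 6.0
    kernel_rise_steepest: float = 2.5
    kernel_fall_steepest: float = 11.0
    kernel_amplitude_mean: float = 0.35
    amplitude_cv: float = 0.3
    noise_sd: float = 0.015
    noise_ar1: float = 0.0
    refractory_half_interval: Optional[float] = 6.86
    refractory_steepness: float = 3.70
    nonresponder_fraction: float = 0.2
    timing_jitter: Tuple[float, float, float] = (0.1, 0.8, 0.1)
    baseline_level: float = 1000.0
    baseline_cv: float = 0.2
    field_level: float = 500.0
    field_drift_rate: float = 2e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonresponder_fraction < 1.0:
            raise ValueError("nonresponder_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (
            self.kernel_rise_steepest
            < self.kernel_peak_time
            < self.kernel_fall_steepest
        ):
            raise ValueError("kernel landmarks must satisfy rise < peak < fall")
        if abs(sum(self.timing_jitter) - 1.0) > 1e-9 or min(self.timing_jitter) < 0:
            raise ValueError("timing_jitter must be probabilities of {-1, 0, +1}")
        if not -1.0 < self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must be in (-1, 1)")

    @classmethod
    def noiseless(cls, **overrides) -> "SimulationParams":
        """Fully deterministic cell population: no observation noise, no
        non-responders, no amplitude/timing variability, no refractoriness.

        Used for oracle end-to-end runs where the reconstruction must be
        exact."""
        params = cls(
            noise_sd=0.0,
            amplitude_cv=0.0,
            nonresponder_fraction=0.0,
            timing_jitter=(0.0, 1.0, 0.0),
            refractory_half_interval=None,
            baseline_cv=0.0,
        )
        return replace(params, **overrides)


@dataclass(frozen=True)
class CellPhenotype:
    """Static per-cell properties drawn once per simulated cell."""

    track_id: int
    responder: bool
    amplitude: float
    timing_offset: int
    noise_sd: float
    baseline: float

    def __post_init__(self) -> None:
        if self.responder and self.amplitude <= 0:
            raise ValueError("responder amplitude must be positive")
        if self.timing_offset not in (-1, 0, 1):
            raise ValueError("timing_offset must be in {-1, 0, +1}")


@dataclass
class RawTrajectory:
    """Raw per-cell reporter track before any normalization.

    ``times`` are contiguous integer minutes (negative during the
    pre-stimulation history); intensities are strictly positive arbitrary
    fluorescence units.
    """

    track_id: int
    times: np.ndarray
    nuclear_intensity: np.ndarray
    field_mean_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.nuclear_intensity = np.asarray(self.nuclear_intensity, dtype=float)
        self.field_mean_intensity = np.asarray(self.field_mean_intensity, dtype=float)
        if not (
            len(self.times)
            == len(self.nuclear_intensity)
            == len(self.field_mean_intensity)
        ):
            raise ValueError("trajectory arrays must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) != 1):
            raise ValueError("times must be contiguous at 1-min spacing")
        if np.any(self.nuclear_intensity <= 0) or np.any(
            self.field_mean_intensity <= 0
        ):
            raise ValueError("intensities must be strictly positive")


@dataclass
class GroundTruth:
    """Ground truth of a simulated experiment."""

    pulse_sequence: PulseSequence
    #: tidy table: track_id, pulse_time_min, responded (bool)
    responded: pd.DataFrame
    phenotypes: List[CellPhenotype] = field(default_factory=list)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    if cv <= 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def sample_phenotypes(
    n_cells: int, params: SimulationParams, seed
) -> List[CellPhenotype]:
    """Draw static phenotypes for ``n_cells`` cells; deterministic per seed."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _as_rng(seed)
    responders = rng.random(n_cells) >= params.nonresponder_fraction
    amplitudes = _lognormal(rng, params.kernel_amplitude_mean, params.amplitude_cv, n_cells)
    offsets = rng.choice((-1, 0, 1), size=n_cells, p=params.timing_jitter)
    baselines = _lognormal(rng, params.baseline_level, params.baseline_cv, n_cells)
    return [
        CellPhenotype(
            track_id=i,
            responder=bool(responders[i]),
            amplitude=float(amplitudes[i]),
            timing_offset=int(offsets[i]),
            noise_sd=params.noise_sd,
            baseline=float(baselines[i]),
        )
        for i in range(n_cells)
    ]


def kernel_support(params: SimulationParams) -> int:
    """Last minute (inclusive) at which the unit kernel is nonzero."""
    return int(
        round(
            params.kernel_peak_time
            + 2.0 * (params.kernel_fall_steepest - 0.5 - params.kernel_peak_time)
        )
    )


def response_kernel(
    params: SimulationParams, phenotype: Optional[CellPhenotype] = None
) -> np.ndarray:
    """Stereotyped translocation response to one light pulse.

    Values over minutes 0..support after the pulse.  The rise is a Beta
    CDF on [0, peak] whose density mode sits at ``kernel_rise_steepest``,
    so the largest backward difference falls on the minute bracketing the
    steepest slope; the decay is a raised cosine whose inflection sits at
    ``kernel_fall_steepest - 1/2``, placing the largest backward decrement
    at ``kernel_fall_steepest``.  Zero at minute 0 and at the end of the
    support.  If a phenotype is given, the curve is scaled by its
    amplitude and shifted by its timing offset.
    """
    peak = params.kernel_peak_time
    end = float(kernel_support(params))
    t = np.arange(0, int(end) + 1, dtype=float)
    k = np.empty_like(t)
    rising = t <= peak
    # Beta(2, peak/rise_steepest) CDF has pdf mode at rise_steepest/peak
    k[rising] = _beta.cdf(t[rising] / peak, 2.0, peak / params.kernel_rise_steepest)
    k[~rising] = 0.5 * (1.0 + np.cos(np.pi * (t[~rising] - peak) / (end - peak)))
    if phenotype is not None:
        if not phenotype.responder:
            raise ValueError("non-responders have no response kernel")
        shifted = np.zeros_like(k)
        off = phenotype.timing_offset
        if off >= 0:
            shifted[off:] = k[: len(k) - off] if off else k
        else:
            shifted[:off] = k[-off:]
        k = phenotype.amplitude * shifted
    return k


def response_probability(interval_since_previous: float, params: SimulationParams) -> float:
    """Probability that a responder mounts a distinguishable response.

    Logistic in the interval since the previous pulse, with half-interval
    and steepness from ``params``; saturates at 1 for long intervals.
    A first pulse (``interval = inf``) is always responded to.  Passing
    ``refractory_half_interval = None`` disables refractoriness entirely.
    """
    if params.refractory_half_interval is None:
        return 1.0
    if np.isinf(interval_since_previous):
        return 1.0
    if interval_since_previous < 1:
        raise ValueError("interval must be >= 1 minute")
    z = (interval_since_previous - params.refractory_half_interval) / params.refractory_steepness
    return float(1.0 / (1.0 + np.exp(-z)))


def _noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, n)
    if rho != 0.0:
        out = np.empty(n)
        out[0] = eps[0]
        scale = np.sqrt(1.0 - rho * rho)
        for i in range(1, n):
            out[i] = rho * out[i - 1] + scale * eps[i]
        return out
    return eps


def simulate_experiment(
    pulses: PulseSequence,
    n_cells: int,
    params: SimulationParams,
    seed,
    history: int = 130,
) -> Tuple[List[RawTrajectory], GroundTruth]:
    """Simulate an ensemble of raw KTR tracks for one stimulation run.

    Each responder cell responds to each pulse independently with the
    refractory probability of the preceding inter-pulse interval; realized
    responses superpose amplitude-scaled kernels on the cell baseline.
    Tracks span ``history`` minutes before stimulation onset (>= 120 min,
    the burn-in required by the trailing-mean normalization) through the
    end of the protocol.  The imaging-field mean intensity carries a slow
    multiplicative (bleaching-like) drift that also multiplies the nuclear
    signal, so it cancels in the first normalization step.
    """
    if history < 120:
        raise ValueError("history must be >= 120 min for normalization burn-in")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _as_rng(seed)
    phenotypes = sample_phenotypes(n_cells, params, rng)

    times = np.arange(-history, pulses.duration)
    n_t = len(times)
    drift = np.exp(-params.field_drift_rate * np.arange(n_t, dtype=float))
    field = params.field_level * drift

    pulse_times = pulses.times_array
    if pulse_times.size:
        intervals = np.concatenate(([np.inf], np.diff(pulse_times).astype(float)))
        probs = np.array([response_probability(iv, params) for iv in intervals])
    else:
        probs = np.empty(0)

    base_kernel = response_kernel(params)
    klen = len(base_kernel)

    trajectories: List[RawTrajectory] = []
    responded_rows = []
    for ph in phenotypes:
        signal = np.zeros(n_t)
        responded = np.zeros(len(pulse_times), dtype=bool)
        if ph.responder and pulse_times.size:
            responded = rng.random(len(pulse_times)) < probs
            for pt in pulse_times[responded]:
                i0 = pt + history + ph.timing_offset
                i1 = min(i0 + klen, n_t)
                if i1 > i0:
                    signal[i0:i1] += ph.amplitude * base_kernel[: i1 - i0]
        eps = _noise(rng, n_t, ph.noise_sd, params.noise_ar1)
        nuclear = ph.baseline * np.clip(1.0 - signal + eps, 0.05, None) * drift
        trajectories.append(
            RawTrajectory(
                track_id=ph.track_id,
                times=times.copy(),
                nuclear_intensity=nuclear,
                field_mean_intensity=field.copy(),
            )
        )
        for pt, r in zip(pulse_times, responded):
            responded_rows.append((ph.track_id, int(pt), bool(r)))

    truth = GroundTruth(
        pulse_sequence=pulses,
        responded=pd.DataFrame(
            responded_rows, columns=["track_id", "pulse_time_min", "responded"]
        ),
        phenotypes=phenotypes,
    )
    return trajectories, truth
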