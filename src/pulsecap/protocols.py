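"""Pulsatile stimulation protocols and their exact input entropy rates.

Three families of light-pulse protocols on a 1-minute grid are supported:

* **binary** -- a pulse either occurs or not in each of 19 equidistant
  "slots" spaced ``tau_clock`` minutes apart.  The fixed slot pattern is a
  de Bruijn-type sequence containing every 4-digit binary word exactly
  once, so a single short experiment samples all local input contexts.
* **interval** -- inter-pulse intervals are geometrically distributed with
  mean ``tau_geom`` (rate parameter ``p = 1/tau_geom``), the maximally
  entropic discrete renewal process.  Experimentally a technical minimal
  gap of 2 min is kept to make reconstruction unambiguous.
* **interval_gap** -- geometric intervals lengthened by a fixed refractory
  gap ``tau_gap``, trading input entropy for response reliability.

The module also provides the closed-form input entropy rates of each
family and the integer optimization of ``tau_geom`` for a given gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import geom

__all__ = [
    "BINARY_PATTERN",
    "ProtocolSpec",
    "PulseSequence",
    "make_binary_sequence",
    "draw_interval_sequence",
    "entropy_rate_binary",
    "entropy_rate_interval",
    "optimize_tau_geom",
    "input_entropy",
]

#: 19-digit de Bruijn-type pattern: every binary word of length 4 appears
#: exactly once among its 16 sliding windows.
BINARY_PATTERN = "1011010011110000101"

#: Implicit technical gap (minutes) of the plain interval protocol.
DEFAULT_TECHNICAL_GAP = 2

_KINDS = ("binary", "interval", "interval_gap")


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of a stimulation protocol.

    Parameters
    ----------
    kind:
        One of ``"binary"``, ``"interval"``, ``"interval_gap"``.
    tau_clock:
        Clock period in minutes (binary protocols only).
    tau_geom:
        Mean of the geometric interval component, minutes (= 1/p).
    tau_gap:
        Fixed gap added to every drawn interval, minutes.  For the plain
        interval protocol this is the 2-min technical gap.
    """

    kind: str
    tau_clock: Optional[int] = None
    tau_geom: Optional[int] = None
    tau_gap: int = 0
    resolution: int = field(default=1, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.resolution != 1:
            raise ValueError("only the 1-minute grid is supported")
        if self.kind == "binary":
            if self.tau_clock is None or int(self.tau_clock) != self.tau_clock:
                raise ValueError("binary protocol requires integer tau_clock")
            if self.tau_clock < 1:
                raise ValueError("tau_clock must be >= 1 minute")
        else:
            if self.tau_geom is None or int(self.tau_geom) != self.tau_geom:
                raise ValueError("interval protocols require integer tau_geom")
            if self.tau_geom < 1:
                raise ValueError("tau_geom must be >= 1 minute")
            if int(self.tau_gap) != self.tau_gap or self.tau_gap < 0:
                raise ValueError("tau_gap must be a nonnegative integer")

    @property
    def entropy_rate(self) -> float:
        """Input entropy rate in bits per minute."""
        if self.kind == "binary":
            return entropy_rate_binary(self.tau_clock)
        return entropy_rate_interval(self.tau_geom, self.tau_gap)

    @property
    def entropy_per_digit(self) -> float:
        """Input entropy in bits per digit (slot for binary, minute else)."""
        if self.kind == "binary":
            return 1.0
        return entropy_rate_interval(self.tau_geom, self.tau_gap)


@dataclass(frozen=True)
class PulseSequence:
    """A realized stimulation sequence on the 1-minute grid.

    ``pulse_times`` are strictly increasing integer minutes in
    ``[0, duration)``.  The 0/1 digit vector is derived on demand.
    """

    duration: int
    pulse_times: tuple
    protocol: Optional[ProtocolSpec] = None

    def __post_init__(self) -> None:
        times = tuple(int(t) for t in self.pulse_times)
        object.__setattr__(self, "pulse_times", times)
        arr = np.asarray(times)
        if arr.size:
            if np.any(np.diff(arr) <= 0):
                raise ValueError("pulse_times must be strictly increasing")
            if arr[0] < 0 or arr[-1] >= self.duration:
                raise ValueError("pulse_times must lie in [0, duration)")
        if self.protocol is not None and arr.size:
            if self.protocol.kind == "binary":
                if np.any(arr % self.protocol.tau_clock != 0):
                    raise ValueError("binary pulses must sit on clock slots")
            elif self.protocol.kind == "interval_gap" and arr.size > 1:
                if np.any(np.diff(arr) < self.protocol.tau_gap + 1):
                    raise ValueError(
                        "interval_gap pulses closer than tau_gap + 1 apart"
                    )

    @property
    def digits(self) -> np.ndarray:
        """0/1 vector over minutes 0..duration-1."""
        d = np.zeros(self.duration, dtype=np.int8)
        if self.pulse_times:
            d[np.asarray(self.pulse_times)] = 1
        return d

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.pulse_times, dtype=int)

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        proto = None
        if self.protocol is not None:
            proto = {
                "kind": self.protocol.kind,
                "tau_clock": self.protocol.tau_clock,
                "tau_geom": self.protocol.tau_geom,
                "tau_gap": self.protocol.tau_gap,
            }
        return json.dumps(
            {
                "duration_min": self.duration,
                "pulse_times_min": list(self.pulse_times),
                "protocol": proto,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PulseSequence":
        obj = json.loads(text)
        proto = obj.get("protocol")
        spec = None
        if proto is not None:
            spec = ProtocolSpec(
                kind=proto["kind"],
                tau_clock=proto.get("tau_clock"),
                tau_geom=proto.get("tau_geom"),
                tau_gap=proto.get("tau_gap") or 0,
            )
        return cls(
            duration=int(obj["duration_min"]),
            pulse_times=tuple(obj["pulse_times_min"]),
            protocol=spec,
        )

    def to_frame(self) -> pd.DataFrame:
        """Two-column representation (time_min, pulse)."""
        return pd.DataFrame(
            {"time_min": np.arange(self.duration), "pulse": self.digits}
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, protocol: Optional[ProtocolSpec] = None
    ) -> "PulseSequence":
        times = frame.loc[frame["pulse"] == 1, "time_min"].to_numpy()
        return cls(
            duration=int(frame["time_min"].max()) + 1,
            pulse_times=tuple(int(t) for t in np.sort(times)),
            protocol=protocol,
        )


def make_binary_sequence(tau_clock: int, negated: bool = False) -> PulseSequence:
    """Fixed 19-slot binary stimulation sequence (or its logic negation).

    Slots are spaced ``tau_clock`` minutes apart and carry the de Bruijn
    pattern ``1011010011110000101``; duration is ``19 * tau_clock``.
    """
    if int(tau_clock) != tau_clock or tau_clock < 1:
        raise ValueError("tau_clock must be a positive integer")
    tau_clock = int(tau_clock)
    pattern = BINARY_PATTERN
    if negated:
        pattern = "".join("1" if c == "0" else "0" for c in pattern)
    times = tuple(i * tau_clock for i, c in enumerate(pattern) if c == "1")
    return PulseSequence(
        duration=len(pattern) * tau_clock,
        pulse_times=times,
        protocol=ProtocolSpec(kind="binary", tau_clock=tau_clock),
    )


def _quantile_intervals(tau_geom: int, tau_gap: int, n: int) -> np.ndarray:
    """Interval multiset matching geometric quantiles (i - 1/2)/n + gap."""
    q = (np.arange(1, n + 1) - 0.5) / n
    base = geom.ppf(q, 1.0 / tau_geom).astype(int) if tau_geom > 1 else np.ones(n, int)
    return base + tau_gap


def draw_interval_sequence(
    tau_geom: int,
    tau_gap: int,
    budget: int,
    seed,
    kind: str = "interval_gap",
) -> PulseSequence:
    """Draw a shuffled quantile-matched interval-encoded pulse sequence.

    The inter-pulse interval multiset is chosen deterministically to match
    the geometric(1/``tau_geom``) distribution shifted by ``tau_gap``
    (quantiles at ``(i - 1/2)/n`` for ``n = floor(budget/(tau_geom +
    tau_gap))`` intervals), then randomly shuffled with ``seed``.
    """
    spec = ProtocolSpec(kind=kind, tau_geom=int(tau_geom), tau_gap=int(tau_gap))
    n = int(budget // (tau_geom + tau_gap))
    if n < 1:
        raise ValueError("time budget too small for a single interval")
    intervals = _quantile_intervals(int(tau_geom), int(tau_gap), n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intervals = rng.permutation(intervals)
    times = np.cumsum(intervals)
    times = times[times < budget]
    return PulseSequence(
        duration=int(budget), pulse_times=tuple(int(t) for t in times), protocol=spec
    )


def entropy_rate_binary(tau_clock: int) -> float:
    """Input entropy rate of the binary protocol, bits per minute.

    One equiprobable 0/1 digit per clock period: ``1/tau_clock``.
    """
    if tau_clock <= 0:
        raise ValueError("tau_clock must be positive")
    return 1.0 / tau_clock


def entropy_rate_interval(tau_geom: float, tau_gap: float = 0.0) -> float:
    """Input entropy rate of the (gapped) interval protocol, bits per minute.

    The geometric interval distribution with mean ``tau`` has entropy
    ``tau*log2(tau) - (tau-1)*log2(tau-1)`` bits per interval; dividing by
    the mean inter-pulse interval ``tau + tau_gap`` gives bits per minute
    (equivalently, bits per 1-min digit).
    """
    if tau_geom < 1:
        raise ValueError("tau_geom must be >= 1 minute")
    if tau_gap < 0:
        raise ValueError("tau_gap must be nonnegative")
    tau = float(tau_geom)
    if tau == 1.0:
        return 0.0  # deterministic intervals carry no information
    h = tau * np.log2(tau) - (tau - 1.0) * np.log2(tau - 1.0)
    return float(h / (tau + tau_gap))


def optimize_tau_geom(tau_gap: int, search_range=(1, 120)) -> int:
    """Integer ``tau_geom`` maximizing the gapped-interval entropy rate.

    Exhaustive search over ``search_range`` on the 1-min grid; ties are
    broken toward the smaller ``tau_geom``.
    """
    if tau_gap < 0:
        raise ValueError("tau_gap must be nonnegative")
    lo, hi = search_range
    taus = np.arange(lo, hi + 1)
    rates = np.array([entropy_rate_interval(t, tau_gap) for t in taus])
    return int(taus[int(np.argmax(rates))])  # argmax takes the first maximum


def input_entropy(protocol: ProtocolSpec, n_digits: int) -> float:
    """Total input entropy of ``n_digits`` digits, in bits.

    Digits are clock slots for binary protocols (1 bit each) and minutes
    for interval protocols (``entropy_rate_interval`` bits each).
    """
    if n_digits < 0:
        raise ValueError("n_digits must be nonnegative")
    return protocol.entropy_per_digit * n_digits
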