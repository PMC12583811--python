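"""Time-varying forcing of model parameters.

A :class:`Rule` binds a parameter (or constant external species) symbol to a
waveform.  During simulation the symbol's value is re-evaluated at every
right-hand-side call, so inducer levels, light intensities etc. can follow
square waves (day/night light pulses), sinusoids or tabulated schedules.
Square waves report their discontinuities as solver breakpoints so stiff
integrators never step across a jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Waveform",
    "Constant",
    "Square",
    "Sine",
    "Table",
    "Rule",
]


class Waveform:
    """Base class: a callable value of time (minutes)."""

    def __call__(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """Discontinuity times inside ``(t0, t1)``; empty for smooth waveforms."""
        return np.empty(0)


@dataclass(frozen=True)
class Constant(Waveform):
    value: float

    def __call__(self, t):
        return self.value if np.isscalar(t) else np.full(np.shape(t), self.value)


@dataclass(frozen=True)
class Square(Waveform):
    """Square wave: ``high`` for the first ``duty`` fraction of each period."""

    period: float
    duty: float
    low: float
    high: float
    phase: float = 0.0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("square wave period must be positive")
        if not 0.0 <= self.duty <= 1.0:
            raise ValueError("duty fraction must lie in [0, 1]")

    def __call__(self, t):
        frac = np.mod(np.asarray(t, dtype=float) - self.phase, self.period) / self.period
        out = np.where(frac < self.duty, self.high, self.low)
        return float(out) if np.isscalar(t) else out

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        k0 = int(np.floor((t0 - self.phase) / self.period)) - 1
        k1 = int(np.ceil((t1 - self.phase) / self.period)) + 1
        edges = []
        for k in range(k0, k1 + 1):
            rise = self.phase + k * self.period
            fall = rise + self.duty * self.period
            edges.extend((rise, fall))
        edges = np.array(edges)
        return np.unique(edges[(edges > t0) & (edges < t1)])


@dataclass(frozen=True)
class Sine(Waveform):
    period: float
    mean: float
    amplitude: float
    phase: float = 0.0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("sine period must be positive")

    def __call__(self, t):
        return self.mean + self.amplitude * np.sin(
            2.0 * np.pi * (np.asarray(t, dtype=float) - self.phase) / self.period
        )


@dataclass(frozen=True)
class Table(Waveform):
    """Piecewise-linear interpolation of tabulated (time, value) samples."""

    times: Sequence[float]
    values: Sequence[float]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("table times must be strictly increasing, length >= 2")
        if len(self.values) != len(t):
            raise ValueError("times and values must have equal length")

    def __call__(self, t):
        return np.interp(t, np.asarray(self.times, float), np.asarray(self.values, float))

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        t = np.asarray(self.times, float)
        return t[(t > t0) & (t < t1)]


@dataclass(frozen=True)
class Rule:
    """Bind ``symbol`` (a model parameter) to a waveform."""

    symbol: str
    waveform: Waveform = field(default_factory=lambda: Constant(0.0))
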