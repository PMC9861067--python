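"""Core array containers exchanged between pipeline stages.

An impulse-radar recording is a real-valued fast-time x slow-time matrix:
each column is one received pulse sampled at the fast-time rate (range
axis), and successive columns are successive pulses (frame axis). After
clutter suppression and range-gate selection the data collapse to a single
slow-time series carrying the chest-motion modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Propagation speed used for range/delay conversion (m/s).
C_LIGHT = 2.998e8


@dataclass
class EchoMatrix:
    """Fast-time x slow-time radar echo matrix with axis metadata.

    Parameters
    ----------
    values : (M, N) ndarray
        Real echo samples; rows are fast-time (range) bins, columns are
        slow-time frames.
    delta_T : float
        Fast-time sampling interval in seconds.
    Ts : float
        Slow-time (frame) sampling interval in seconds.
    """

    values: np.ndarray
    delta_T: float
    Ts: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("echo matrix must be two-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("echo matrix contains non-finite entries")
        if self.delta_T <= 0 or self.Ts <= 0:
            raise ValueError("sampling intervals must be positive")

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]

    @property
    def range_axis(self) -> np.ndarray:
        """Per-row range in metres: row m maps to m * delta_T * c / 2."""
        return np.arange(self.M) * self.delta_T * C_LIGHT / 2.0

    @property
    def slow_time_axis(self) -> np.ndarray:
        return np.arange(self.N) * self.Ts


@dataclass
class SlowTimeSignal:
    """One-dimensional vital-sign series sampled at the frame rate."""

    values: np.ndarray
    Ts: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("slow-time signal needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("slow-time signal contains non-finite entries")
        if self.Ts <= 0:
            raise ValueError("Ts must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def fs(self) -> float:
        """Slow-time sampling rate in Hz."""
        return 1.0 / self.Ts

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.Ts
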