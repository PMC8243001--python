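"""Stimulation protocol descriptions: clamp pulses, two-pulse series, trains."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ClampProtocol", "TwoPulseProtocol", "PulseTrainProtocol"]


@dataclass(frozen=True)
class ClampProtocol:
    """A rectangular optical pulse under voltage clamp.

    Attributes
    ----------
    V : clamp potential (mV)
    I : irradiance during the pulse (W/m^2, constant)
    t_on, t_off : pulse edges (s)
    t_end : end of the recorded trace (s)
    """

    V: float
    I: float
    t_on: float
    t_off: float
    t_end: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.V, self.I, self.t_on, self.t_off, self.t_end])):
            raise ValueError("protocol fields must be finite")
        if self.I < 0:
            raise ValueError(f"irradiance must be >= 0, got {self.I}")
        if not (0.0 <= self.t_on < self.t_off <= self.t_end):
            raise ValueError(
                f"need 0 <= t_on < t_off <= t_end, got {self.t_on}, {self.t_off}, {self.t_end}"
            )

    @property
    def pulse_duration(self) -> float:
        return self.t_off - self.t_on


@dataclass(frozen=True)
class TwoPulseProtocol:
    """Recovery protocol: a conditioning pulse, a dark gap, a probe pulse.

    The gap is varied over ``interpulse_intervals`` (strictly increasing,
    seconds) while both pulses share irradiance and voltage.
    """

    pulse1: ClampProtocol
    interpulse_intervals: tuple[float, ...]
    pulse2_duration: float

    def __post_init__(self) -> None:
        iv = tuple(float(x) for x in self.interpulse_intervals)
        object.__setattr__(self, "interpulse_intervals", iv)
        if len(iv) == 0:
            raise ValueError("need at least one interpulse interval")
        if any(x <= 0 for x in iv) or any(b <= a for a, b in zip(iv, iv[1:])):
            raise ValueError("intervals must be strictly increasing and > 0")
        if self.pulse2_duration <= 0:
            raise ValueError("pulse2_duration must be > 0")


@dataclass(frozen=True)
class PulseTrainProtocol:
    """Periodic light train for current-clamp (free membrane) simulation.

    Attributes
    ----------
    irradiance : W/m^2 during the on-phase
    prf_hz : pulse repetition frequency (Hz)
    duty : on-fraction of each cycle, in (0, 1]
    stim_s : total stimulation span (s); pulses beyond it are truncated
    total_s : total simulated time (s)
    """

    irradiance: float
    prf_hz: float
    duty: float
    stim_s: float
    total_s: float

    def __post_init__(self) -> None:
        if self.irradiance < 0:
            raise ValueError("irradiance must be >= 0")
        if self.prf_hz <= 0 or self.stim_s <= 0 or self.total_s < self.stim_s:
            raise ValueError("need prf_hz > 0, 0 < stim_s <= total_s")
        if not 0.0 < self.duty <= 1.0:
            raise ValueError(f"duty cycle must be in (0,1], got {self.duty}")

    def on_windows(self) -> list[tuple[float, float]]:
        """Light-on intervals [(start, stop), ...] within the stimulation span."""
        period = 1.0 / self.prf_hz
        out = []
        t = 0.0
        while t < self.stim_s - 1e-12:
            stop = min(t + self.duty * period, self.stim_s)
            out.append((t, stop))
            t += period
        return out

    @property
    def total_on_time(self) -> float:
        return sum(b - a for a, b in self.on_windows())
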