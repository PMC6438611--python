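"""Intrapleural driving-pressure waveform for quiet breathing.

The pleural suction ramps sinusoidally from 0 (functional residual
capacity) to -p0 = -244 Pa (~ -2.5 cmH2O) and back over a 4 s cycle:

    p_IP(t) = -p0 * (1/2 - 1/2 cos(omega t)),   omega = pi/2 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BreathingWaveform", "intrapleural_pressure"]


@dataclass(frozen=True)
class BreathingWaveform:
    p0: float = 244.0  # Pa
    omega: float = math.pi / 2.0  # 1/s

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega

    def __post_init__(self):
        if self.p0 < 0 or self.omega <= 0:
            raise ValueError("waveform requires p0 >= 0 and omega > 0")


def intrapleural_pressure(t, w: BreathingWaveform = BreathingWaveform()):
    """Pleural pressure (Pa) at time t (s); in [-p0, 0], zero at t = 0."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = -w.p0 * (0.5 - 0.5 * np.cos(w.omega * t))
    return float(out) if out.ndim == 0 else out
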