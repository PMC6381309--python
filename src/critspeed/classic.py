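"""Classic all-out-test metrics from fixed time windows.

Critical speed (CS) is the mean speed over the final 30 s of the 180 s
bout — by then the finite capacity D' is assumed fully spent — and D' is
the excess distance above CS accumulated over the first 150 s:

    CS = mean v(t), t ∈ [150, 180)
    D' = (mean v(t), t ∈ [0, 150) − CS) · 150 s

Window conventions are half-open on the 1 Hz grid, giving exactly 30 and
150 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SpeedTimeSeries

__all__ = ["ClassicMetrics", "critical_speed_classic", "d_prime_classic", "classic_metrics"]

_END = 180.0
_SPLIT = 150.0


def _check_grid(s: SpeedTimeSeries) -> None:
    if s.t[0] > 1e-9 or s.t[-1] < _END - 1e-9:
        raise ValueError(
            f"series covers [{s.t[0]:g}, {s.t[-1]:g}] s; classic metrics need an "
            f"aligned 1 Hz series over [0, {_END:g}]"
        )


@dataclass(frozen=True)
class ClassicMetrics:
    """CS, D' and the 150 s mean speed they are computed from.

    ``d_prime`` can come out negative for paced (non-all-out) bouts;
    it is reported as-is with ``pacing_flag`` set, never clamped.
    """

    cs: float
    d_prime: float
    mean_speed_150: float

    @property
    def pacing_flag(self) -> bool:
        return self.d_prime < 0

    def to_dict(self) -> dict:
        return {
            "cs": self.cs,
            "d_prime": self.d_prime,
            "mean_speed_150": self.mean_speed_150,
            "pacing_flag": self.pacing_flag,
        }


def critical_speed_classic(s: SpeedTimeSeries) -> float:
    """Mean speed over t ∈ [150, 180) — 30 samples at 1 Hz."""
    _check_grid(s)
    mask = (s.t >= _SPLIT - 1e-9) & (s.t < _END - 1e-9)
    return float(np.mean(s.v[mask]))


def d_prime_classic(s: SpeedTimeSeries) -> float:
    """(mean speed over t ∈ [0, 150) − CS) · 150 s, in metres."""
    _check_grid(s)
    cs = critical_speed_classic(s)
    mask = (s.t >= -1e-9) & (s.t < _SPLIT - 1e-9)
    return (float(np.mean(s.v[mask])) - cs) * _SPLIT


def classic_metrics(s: SpeedTimeSeries) -> ClassicMetrics:
    _check_grid(s)
    cs = critical_speed_classic(s)
    mask = (s.t >= -1e-9) & (s.t < _SPLIT - 1e-9)
    mean150 = float(np.mean(s.v[mask]))
    return ClassicMetrics(cs=cs, d_prime=(mean150 - cs) * _SPLIT, mean_speed_150=mean150)
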