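"""Parameter containers for the all-out-test speed models.

Two models live here:

* the bi-exponential speed-time model of a single ~180 s all-out bout
  (:class:`BiExpParams`), and
* the classic two-parameter speed-time hyperbola
  (:class:`HyperbolicParams`) with critical speed CS and curvature
  constant D'.

All speeds are m·s⁻¹, times are seconds from movement onset, distances
are metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

__all__ = ["BiExpParams", "HyperbolicParams", "DerivedMetrics", "PARAM_NAMES"]

#: canonical ordering used by the fitter and array round-trips
PARAM_NAMES = ("s0", "a_d", "a_g", "t_c", "tau_g", "tau_d")


@dataclass(frozen=True)
class BiExpParams:
    """Parameters of the piecewise growth/decay exponential speed curve.

    The modelled speed rises from near rest to its peak ``s0 + a_d`` at
    time ``t_c`` with growth time constant ``tau_g``, then decays
    exponentially toward the asymptote ``s0`` (the model's surrogate for
    critical speed) with time constant ``tau_d``.

    Attributes
    ----------
    s0 : float
        Speed asymptote S0 (m·s⁻¹), surrogate of critical speed.
    a_d : float
        Decay amplitude Ad (m·s⁻¹); the gap between peak speed and S0.
    a_g : float
        Growth amplitude Ag (m·s⁻¹).
    t_c : float
        Time offset between growth and decay (s); the time of peak speed.
    tau_g, tau_d : float
        Growth and decay time constants (s).
    """

    s0: float
    a_d: float
    a_g: float
    t_c: float
    tau_g: float
    tau_d: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(getattr(self, f.name)) for f in fields(self)):
            raise ValueError("all parameters must be finite")
        if self.s0 < 0:
            raise ValueError(f"s0 must be >= 0, got {self.s0}")
        for name in ("a_d", "a_g", "t_c", "tau_g", "tau_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def smax(self) -> float:
        """Peak modelled speed, S0 + Ad, attained at t = t_c."""
        return self.s0 + self.a_d

    @classmethod
    def from_rest(
        cls, s0: float, a_d: float, t_c: float, tau_g: float, tau_d: float
    ) -> "BiExpParams":
        """Construct params with ``a_g`` fixed by the start-from-rest
        constraint S(0) = 0, i.e. a_g = (s0 + a_d) / (1 − e^(−t_c/τg))."""
        a_g = (s0 + a_d) / (1.0 - math.exp(-t_c / tau_g))
        return cls(s0=s0, a_d=a_d, a_g=a_g, t_c=t_c, tau_g=tau_g, tau_d=tau_d)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "BiExpParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, theta))))

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}


@dataclass(frozen=True)
class HyperbolicParams:
    """Critical speed CS (m·s⁻¹) and curvature constant D' (m) of the
    speed–time-to-exhaustion hyperbola."""

    cs: float
    d_prime: float

    def __post_init__(self) -> None:
        if not (self.cs > 0):
            raise ValueError(f"cs must be > 0, got {self.cs}")
        if self.d_prime < 0:
            raise ValueError(f"d_prime must be >= 0, got {self.d_prime}")


@dataclass(frozen=True)
class DerivedMetrics:
    """Closed-form quantities derived from a fitted bi-exponential curve.

    ``s_prime`` is the area under the curve above S0 over the bout
    (the model-based analogue of D'); ``t_star`` is the time at which
    the growth branch first reaches S0, or ``None`` when the curve never
    dips below S0 (then the area integral starts at t = 0).
    """

    s_max: float
    fi_percent: float
    s_prime: float
    total_distance: float
    anaerobic_fraction: float
    t_star: Optional[float]

    def to_dict(self) -> dict:
        return {
            "s_max": self.s_max,
            "fi_percent": self.fi_percent,
            "s_prime": self.s_prime,
            "total_distance": self.total_distance,
            "anaerobic_fraction": self.anaerobic_fraction,
            "t_star": self.t_star,
        }
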