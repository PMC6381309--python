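"""Synthetic all-out-test traces with known ground truth.

Emulates the two recording modes seen in the field: a GPS-like 1 Hz
linear bout and a video-like up-to-100 Hz shuttle bout in which the
runner decelerates into each 180° turn. The base curve is the
bi-exponential model itself; shuttle mode multiplies it by a periodic
envelope that dips at each turn, with turn times placed where the base
curve's cumulative distance reaches successive multiples of the shuttle
length. Additive Gaussian measurement noise is seeded and reproducible
bit-for-bit.

The cohort generator draws per-subject truths from truncated normal
distributions whose means ± SDs default to the published group values
for each condition; the growth parameters, which group tables do not
report, default to τg = 1.5 s with Ag fixed by the start-from-rest
constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, stats

from . import model as _model
from .fitting import DEFAULT_BOUNDS
from .params import BiExpParams
from .preprocess import DisplacementSeries, SpeedTimeSeries

__all__ = [
    "SimulationSpec",
    "generate_trace",
    "generate_cohort",
    "integrate_to_displacement",
    "COHORT_DEFAULTS",
]

#: per-condition (mean, sd) of the sampled truth parameters; group-level
#: field values for 14 male team-sport athletes
COHORT_DEFAULTS = {
    "linear": {"s0": (3.52, 0.66), "a_d": (5.37, 0.89), "t_c": (6.42, 1.96), "tau_d": (43.96, 12.73)},
    "shuttle50": {"s0": (3.57, 0.51), "a_d": (4.19, 0.98), "t_c": (3.10, 0.82), "tau_d": (50.16, 15.69)},
    "shuttle25": {"s0": (3.35, 0.48), "a_d": (3.83, 0.82), "t_c": (2.84, 0.37), "tau_d": (57.90, 15.61)},
}

#: growth time constant default (s); group tables omit it
TAU_G_DEFAULT = 1.5
TAU_G_SD_DEFAULT = 0.3

TURN_DIP_WIDTH = 1.5  # s, full width of the cosine notch at each turn


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic bout."""

    truth: BiExpParams
    duration: float = 180.0
    rate: float = 1.0  # Hz; 1 for GPS-like, 100 for video-like
    noise_sd: float = 0.0
    mode: str = "linear"  # or "shuttle"
    shuttle_length: Optional[float] = None  # m, 25 or 50 in practice
    turn_dip_fraction: float = 0.0  # speed dips to (1 - fraction) at turns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration <= self.truth.t_c:
            raise ValueError("duration must exceed the truth's t_c")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.mode not in ("linear", "shuttle"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "shuttle":
            if not self.shuttle_length or self.shuttle_length <= 0:
                raise ValueError("shuttle mode requires a positive shuttle_length")
            if not (0 <= self.turn_dip_fraction < 1):
                raise ValueError("turn_dip_fraction must be in [0, 1)")
        elif self.shuttle_length is not None:
            raise ValueError("shuttle_length only applies to shuttle mode")


def _turn_times(truth: BiExpParams, duration: float, shuttle_length: float) -> np.ndarray:
    """Times at which the base curve's cumulative distance crosses
    successive multiples of the shuttle length (fine-grid interpolation)."""
    tt = np.arange(0.0, duration + 0.005, 0.01)
    v = _model.evaluate_speed(truth, tt)
    dist = integrate.cumulative_trapezoid(v, tt, initial=0.0)
    n_turns = int(math.floor(dist[-1] / shuttle_length))
    marks = shuttle_length * np.arange(1, n_turns + 1)
    return np.interp(marks, dist, tt)


def _turn_envelope(t: np.ndarray, turn_times: np.ndarray, dip: float) -> np.ndarray:
    """Multiplicative envelope: smooth cosine notches of full width
    TURN_DIP_WIDTH centred on each turn, reaching (1 - dip) at the turn."""
    env = np.ones_like(t)
    half = TURN_DIP_WIDTH / 2.0
    for tc in turn_times:
        mask = np.abs(t - tc) <= half
        if mask.any():
            env[mask] -= dip * 0.5 * (1.0 + np.cos(np.pi * (t[mask] - tc) / half))
    return env


def generate_trace(spec: SimulationSpec) -> SpeedTimeSeries:
    """Generate one speed trace per the spec; deterministic given seed."""
    dt = 1.0 / spec.rate
    t = np.arange(0.0, spec.duration + dt / 2.0, dt)
    v = np.asarray(_model.evaluate_speed(spec.truth, t), dtype=float)
    meta: dict = {"truth": spec.truth.to_dict(), "mode": spec.mode, "noise_sd": spec.noise_sd}
    if spec.mode == "shuttle":
        turns = _turn_times(spec.truth, spec.duration, spec.shuttle_length)
        v = v * _turn_envelope(t, turns, spec.turn_dip_fraction)
        meta.update(
            shuttle_length=spec.shuttle_length,
            turn_times=turns.tolist(),
            turn_dip_fraction=spec.turn_dip_fraction,
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=v.size)
    v = np.clip(v, 0.0, None)
    return SpeedTimeSeries(t=t, v=v, source="synthetic", meta=meta)


def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    n: int,
    conditions=("linear", "shuttle50", "shuttle25"),
    seed: int = 0,
    param_stats: Optional[dict] = None,
    noise_sd: float = 0.15,
    rate: float = 1.0,
    duration: float = 180.0,
    turn_dip_fraction: float = 0.2,
):
    """Draw a cohort of synthetic bouts with a hidden truth table.

    Returns ``(bouts, truth_df)`` where ``bouts`` is a list of
    ``(subject, condition, SpeedTimeSeries)`` and ``truth_df`` records
    the true parameters per bout for recovery scoring. Truths are drawn
    from truncated normals confined to the fitting bounds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    stats_by_cond = param_stats or COHORT_DEFAULTS
    rng = np.random.default_rng(seed)
    bouts = []
    truth_rows = []
    for condition in conditions:
        cstats = stats_by_cond[condition]
        draws = {}
        for name in ("s0", "a_d", "t_c", "tau_d"):
            mean, sd = cstats[name]
            lo, hi = DEFAULT_BOUNDS[name]
            draws[name] = _truncnorm_draw(rng, mean, sd, lo, hi, n)
        draws["tau_g"] = _truncnorm_draw(
            rng, TAU_G_DEFAULT, TAU_G_SD_DEFAULT, *DEFAULT_BOUNDS["tau_g"], n
        )
        shuttle_length = {"shuttle50": 50.0, "shuttle25": 25.0}.get(condition)
        for i in range(n):
            truth = BiExpParams.from_rest(
                s0=float(draws["s0"][i]),
                a_d=float(draws["a_d"][i]),
                t_c=float(draws["t_c"][i]),
                tau_g=float(draws["tau_g"][i]),
                tau_d=float(draws["tau_d"][i]),
            )
            spec = SimulationSpec(
                truth=truth,
                duration=duration,
                rate=rate,
                noise_sd=noise_sd,
                mode="linear" if shuttle_length is None else "shuttle",
                shuttle_length=shuttle_length,
                turn_dip_fraction=0.0 if shuttle_length is None else turn_dip_fraction,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            subject = f"S{i + 1:02d}"
            bouts.append((subject, condition, generate_trace(spec)))
            truth_rows.append({"subject": subject, "condition": condition, **truth.to_dict()})
    return bouts, pd.DataFrame(truth_rows)


def integrate_to_displacement(
    s: SpeedTimeSeries, mode: str = "linear", shuttle_length: Optional[float] = None
) -> DisplacementSeries:
    """Cumulative-trapezoid integral of speed; shuttle mode folds the
    along-track distance into [0, L] with direction reversal at turns."""
    d = integrate.cumulative_trapezoid(s.v, s.t, initial=0.0)
    if mode == "shuttle":
        if not shuttle_length or shuttle_length <= 0:
            raise ValueError("shuttle mode requires a positive shuttle_length")
        L = shuttle_length
        x = L - np.abs(np.mod(d, 2.0 * L) - L)
    elif mode == "linear":
        x = d
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rate = 1.0 / s.sample_interval if s.t.size > 1 else None
    return DisplacementSeries(t=s.t.copy(), x=x, sample_rate_hint=rate)
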