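"""Closed-form operations on the bi-exponential speed curve and the
classic speed–time hyperbola.

The speed curve is

    S(t) = S0 + Ad + Ag·(e^(−tc/τg) − e^(−t/τg))   for t ≤ tc   (growth)
    S(t) = S0 + Ad·e^(−(t−tc)/τd)                  for t > tc   (decay)

Both branches equal S0 + Ad at t = tc, so the curve is continuous by
construction and attains its maximum Smax = S0 + Ad exactly at tc.
Everything below is exact arithmetic on the parameters — no quadrature.
"""

from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np

from .params import BiExpParams, DerivedMetrics, HyperbolicParams

__all__ = [
    "evaluate_speed",
    "smax",
    "fatigue_index",
    "s0_crossing_time",
    "s_prime_area",
    "total_distance",
    "anaerobic_fraction",
    "derived_metrics",
    "predict_speed",
    "predict_tlim",
]

ArrayLike = Union[float, np.ndarray]


def evaluate_speed(params: BiExpParams, t: ArrayLike) -> ArrayLike:
    """Modelled speed at time(s) ``t`` (s from movement onset).

    Accepts a scalar or array; negative times are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    e_c = math.exp(-params.t_c / params.tau_g)
    growth = params.s0 + params.a_d + params.a_g * (e_c - np.exp(-t_arr / params.tau_g))
    decay = params.s0 + params.a_d * np.exp(-(t_arr - params.t_c) / params.tau_d)
    out = np.where(t_arr <= params.t_c, growth, decay)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def smax(params: BiExpParams) -> float:
    """Peak modelled speed Smax = S0 + Ad (m·s⁻¹), attained at t = tc."""
    return params.smax


def fatigue_index(params: BiExpParams) -> float:
    """Fatigue index FI% = 100·Ad/(S0 + Ad) = 100·(Smax − S0)/Smax.

    The relative speed reserve above the asymptote: small values mark
    athletes whose sustainable speed sits close to their peak speed.
    """
    s_max = params.smax
    if s_max <= 0:
        raise ZeroDivisionError("Smax must be positive to form a fatigue index")
    return 100.0 * params.a_d / s_max


def s0_crossing_time(params: BiExpParams) -> Optional[float]:
    """Time t* at which the growth branch first reaches S0.

    The growth branch starts below S0 whenever the bout starts from
    (near) rest; solving S(t*) = S0 on the growth branch gives

        t* = −τg · ln(Ad/Ag + e^(−tc/τg)).

    Returns ``None`` when the curve never dips below S0 (the log
    argument is ≥ 1, i.e. S(0) ≥ S0); callers integrating the region
    above S0 then start at t = 0.
    """
    arg = params.a_d / params.a_g + math.exp(-params.t_c / params.tau_g)
    if arg >= 1.0:
        return None
    return -params.tau_g * math.log(arg)


def _growth_area_above_s0(params: BiExpParams, t_lo: float, t_hi: float) -> float:
    # ∫ (S(t) − s0) dt over [t_lo, t_hi] on the growth branch, exact
    e_c = math.exp(-params.t_c / params.tau_g)
    lin = (params.a_d + params.a_g * e_c) * (t_hi - t_lo)
    expo = params.a_g * params.tau_g * (
        math.exp(-t_lo / params.tau_g) - math.exp(-t_hi / params.tau_g)
    )
    return lin - expo


def s_prime_area(params: BiExpParams, duration: float = 180.0) -> float:
    """S' (m): area under the speed curve above S0 over the bout.

    Integration starts at the S0-crossing time t* (the start-from-rest
    region below S0 is excluded) and uses exact antiderivatives of both
    branches:

        decay part  = Ad·τd·(1 − e^(−(T−tc)/τd))
        growth part = ∫_{t*}^{tc} (S(t) − S0) dt.
    """
    if duration <= params.t_c:
        raise ValueError("duration must exceed t_c")
    t_star = s0_crossing_time(params)
    t_lo = 0.0 if t_star is None else t_star
    growth_part = _growth_area_above_s0(params, t_lo, params.t_c)
    decay_part = params.a_d * params.tau_d * (
        1.0 - math.exp(-(duration - params.t_c) / params.tau_d)
    )
    return growth_part + decay_part


def total_distance(params: BiExpParams, duration: float = 180.0) -> float:
    """Total modelled distance (m): ∫₀^T S(t) dt by exact antiderivatives."""
    if duration <= params.t_c:
        raise ValueError("duration must exceed t_c")
    growth_part = params.s0 * params.t_c + _growth_area_above_s0(params, 0.0, params.t_c)
    decay_part = params.s0 * (duration - params.t_c) + params.a_d * params.tau_d * (
        1.0 - math.exp(-(duration - params.t_c) / params.tau_d)
    )
    return growth_part + decay_part


def anaerobic_fraction(params: BiExpParams, duration: float = 180.0) -> float:
    """Percentage of the bout's distance run above S0: 100·S'/total distance.

    Interpreted as the proportion of distance supported predominantly by
    anaerobic energy sources.
    """
    dist = total_distance(params, duration)
    if dist <= 0:
        raise ZeroDivisionError("total distance must be positive")
    return 100.0 * s_prime_area(params, duration) / dist


def derived_metrics(params: BiExpParams, duration: float = 180.0) -> DerivedMetrics:
    """Bundle Smax, FI%, S', total distance, anaerobic fraction and t*."""
    return DerivedMetrics(
        s_max=smax(params),
        fi_percent=fatigue_index(params),
        s_prime=s_prime_area(params, duration),
        total_distance=total_distance(params, duration),
        anaerobic_fraction=anaerobic_fraction(params, duration),
        t_star=s0_crossing_time(params),
    )


def predict_speed(h: HyperbolicParams, t_lim: float) -> float:
    """Speed sustainable for ``t_lim`` seconds: D'/t_lim + CS."""
    if t_lim <= 0:
        raise ValueError("t_lim must be > 0")
    return h.d_prime / t_lim + h.cs


def predict_tlim(h: HyperbolicParams, distance: float) -> float:
    """Time to cover ``distance`` at all-out effort: (D − D')/CS.

    Undefined (raises) for distances below D', which would be covered
    entirely from the finite capacity.
    """
    if distance < h.d_prime:
        raise ValueError(
            f"distance {distance} m is below D' = {h.d_prime} m; time-to-limit undefined"
        )
    return (distance - h.d_prime) / h.cs
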