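"""Bounded nonlinear least-squares estimation of the bi-exponential
speed curve, wrapped in a statsmodels-style Model/Results pair.

``AllOutTest`` holds a preprocessed 1 Hz speed series; ``fit()`` returns
``AllOutTestResults`` carrying the six parameter estimates, their
asymptotic standard errors, goodness of fit (Pearson r, RMSE), the
classic window metrics and the closed-form derived metrics, plus a
``summary()`` table.

The time offset tc is treated as a continuous parameter; each residual
switches branch by comparing its sample time with tc, so the objective
is piecewise smooth with a nondifferentiable seam. The bounded
trust-region solver (scipy's ``least_squares`` with method ``trf``)
handles this robustly; a fixed 3×3 multi-start grid over (tc, τd) is
used as a deterministic fallback when the single start fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from . import model as _model
from .classic import ClassicMetrics, classic_metrics
from .params import PARAM_NAMES, BiExpParams, DerivedMetrics
from .preprocess import SpeedTimeSeries

__all__ = [
    "DEFAULT_BOUNDS",
    "FitResult",
    "initial_guess",
    "fit_biexp",
    "goodness_of_fit",
    "AllOutTest",
    "AllOutTestResults",
]

#: optimiser box constraints, (lower, upper) per parameter in PARAM_NAMES
#: order (s0, a_d, a_g, t_c, tau_g, tau_d); a safety box wide enough for
#: any plausible human bout, not a physiological statement
DEFAULT_BOUNDS = {
    "s0": (0.5, 8.0),
    "a_d": (0.5, 10.0),
    "a_g": (0.1, 50.0),
    "t_c": (1.0, 20.0),
    "tau_g": (0.2, 10.0),
    "tau_d": (5.0, 200.0),
}

_FALLBACK_TC = (2.0, 6.5, 12.0)
_FALLBACK_TAUD = (20.0, 45.0, 90.0)


@dataclass
class FitResult:
    """Outcome of one bounded least-squares fit."""

    params: BiExpParams
    r: float
    rmse: float
    converged: bool
    n_iter: int
    residuals: np.ndarray
    bse: Optional[dict] = None  # asymptotic standard errors per parameter
    cost: float = 0.0
    message: str = ""
    multistart_used: bool = field(default=False)


def _bounds_arrays(bounds: dict) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([bounds[n][1] for n in PARAM_NAMES])
    return lo, hi


def _clip(value: float, lo: float, hi: float) -> float:
    return min(max(value, lo), hi)


def initial_guess(s: SpeedTimeSeries, bounds: Optional[dict] = None) -> BiExpParams:
    """Data-driven starting values, clipped into the optimiser bounds.

    s0 from the last 30 s mean, Ad from the peak above it, tc from the
    peak location, τd from a log-linear regression of (v − s0) on the
    decay segment, τg = tc/3, and Ag from the start-from-rest constraint.
    """
    if s.duration < 60.0:
        raise ValueError("need an aligned series of at least 60 s for an initial guess")
    bounds = bounds or DEFAULT_BOUNDS
    t, v = s.t, s.v
    s0_hat = float(np.mean(v[t >= t[-1] - 30.0]))
    vmax = float(np.max(v))
    if vmax - s0_hat < 0.1:
        raise ValueError("no decay to fit: peak speed within 0.1 m/s of the final 30 s mean")
    t_c_hat = float(t[int(np.argmax(v))])
    a_d_hat = vmax - s0_hat

    # log-linear decay-rate estimate on samples past the peak and clearly
    # above s0 (a 10% amplitude floor keeps the log roughly linear despite
    # the upward bias of the last-30-s s0 estimate)
    mask = (t > t_c_hat) & (v - s0_hat > 0.1 * a_d_hat)
    tau_d_hat = 45.0
    if mask.sum() >= 3:
        y = np.log(v[mask] - 0.999 * s0_hat)
        slope = np.polyfit(t[mask], y, 1)[0]
        if slope < -1e-6:
            tau_d_hat = -1.0 / slope

    t_c_hat = _clip(t_c_hat, *bounds["t_c"])
    tau_g_hat = _clip(t_c_hat / 3.0, *bounds["tau_g"])
    a_g_hat = (s0_hat + a_d_hat) / (1.0 - math.exp(-t_c_hat / tau_g_hat))
    return BiExpParams(
        s0=_clip(s0_hat, *bounds["s0"]),
        a_d=_clip(a_d_hat, *bounds["a_d"]),
        a_g=_clip(a_g_hat, *bounds["a_g"]),
        t_c=t_c_hat,
        tau_g=tau_g_hat,
        tau_d=_clip(tau_d_hat, *bounds["tau_d"]),
    )


def _residual_fn(t: np.ndarray, v: np.ndarray):
    e = np.exp

    def resid(theta: np.ndarray) -> np.ndarray:
        s0, a_d, a_g, t_c, tau_g, tau_d = theta
        growth = s0 + a_d + a_g * (e(-t_c / tau_g) - e(-t / tau_g))
        decay = s0 + a_d * e(-(t - t_c) / tau_d)
        return np.where(t <= t_c, growth, decay) - v

    return resid


def _run_ls(resid, theta0, lo, hi, max_nfev):
    return optimize.least_squares(
        resid,
        np.clip(theta0, lo, hi),
        bounds=(lo, hi),
        method="trf",
        ftol=1e-15,
        xtol=1e-15,
        gtol=1e-15,
        max_nfev=max_nfev,
    )


def _standard_errors(res) -> Optional[dict]:
    # asymptotic SEs from sigma^2 * (J'J)^-1 at the solution
    m, k = res.jac.shape
    if m <= k:
        return None
    sigma2 = 2.0 * res.cost / (m - k)
    try:
        cov = sigma2 * np.linalg.pinv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return None
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return dict(zip(PARAM_NAMES, map(float, se)))


def fit_biexp(
    s: SpeedTimeSeries,
    bounds: Optional[dict] = None,
    max_nfev: int = 2000,
    multistart_on_failure: bool = True,
) -> FitResult:
    """Fit the bi-exponential curve to a preprocessed speed series.

    Unweighted least squares over all samples; deterministic given the
    series and options. Non-convergence is reported through
    ``converged=False``, never silently.
    """
    if s.duration < 150.0:
        raise ValueError("series too short: need at least 150 s of aligned data")
    bounds = bounds or DEFAULT_BOUNDS
    lo, hi = _bounds_arrays(bounds)
    guess = initial_guess(s, bounds)
    resid = _residual_fn(s.t, s.v)

    res = _run_ls(resid, guess.to_array(), lo, hi, max_nfev)
    multistart_used = False
    if (res.status <= 0 or not res.success) and multistart_on_failure:
        multistart_used = True
        candidates = [res] if res.status > 0 else []
        g = guess.to_array()
        for tc0 in _FALLBACK_TC:
            for taud0 in _FALLBACK_TAUD:
                theta0 = g.copy()
                theta0[PARAM_NAMES.index("t_c")] = tc0
                theta0[PARAM_NAMES.index("tau_d")] = taud0
                r2 = _run_ls(resid, theta0, lo, hi, max_nfev)
                if r2.status > 0:
                    candidates.append(r2)
        if candidates:
            res = min(candidates, key=lambda r_: r_.cost)

    params = BiExpParams.from_array(res.x)
    fitted = _model.evaluate_speed(params, s.t)
    rmse = float(np.sqrt(np.mean((fitted - s.v) ** 2)))
    r = goodness_of_fit(s, params) if np.std(s.v) > 0 else float("nan")
    return FitResult(
        params=params,
        r=r,
        rmse=rmse,
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
        residuals=np.asarray(res.fun),
        bse=_standard_errors(res),
        cost=float(res.cost),
        message=str(res.message),
        multistart_used=multistart_used,
    )


def goodness_of_fit(s: SpeedTimeSeries, params: BiExpParams) -> float:
    """Pearson correlation between observed and model-predicted speeds."""
    if np.std(s.v) == 0:
        raise ValueError("observed series is constant; correlation undefined")
    fitted = _model.evaluate_speed(params, s.t)
    return float(stats.pearsonr(s.v, fitted)[0])


class AllOutTest:
    """Bi-exponential speed-curve model for one 3-min all-out bout.

    Parameters
    ----------
    series : SpeedTimeSeries
        Aligned speed series; fitting expects a 1 Hz grid over the bout.
    duration : float
        Bout duration in seconds used for the closed-form integrals
        (default 180 s, the standard 3-min test).

    Examples
    --------
    >>> aot = AllOutTest(series)
    >>> res = aot.fit()
    >>> res.params.s0, res.derived.s_prime
    """

    def __init__(self, series: SpeedTimeSeries, duration: float = 180.0):
        self.series = series
        self.duration = float(duration)

    @classmethod
    def from_dataframe(
        cls,
        df,
        time_col: str = "time_s",
        speed_col: str = "value",
        duration: float = 180.0,
        preprocess: bool = True,
        onset_threshold: float = 0.5,
    ) -> "AllOutTest":
        """Build the model from a tidy DataFrame of time and speed.

        With ``preprocess=True`` the series is aligned to bout onset and
        resampled to the 1 Hz analysis grid first.
        """
        from .preprocess import align_to_start, resample_1hz

        s = SpeedTimeSeries(
            t=df[time_col].to_numpy(dtype=float),
            v=df[speed_col].to_numpy(dtype=float),
        )
        if preprocess:
            s = resample_1hz(s, duration=duration)
            s = align_to_start(s, onset_threshold=onset_threshold)
        return cls(s, duration=duration)

    @classmethod
    def from_displacement(
        cls,
        disp,
        cutoff: float = 4.0,
        filter_order: int = 4,
        duration: float = 180.0,
        onset_threshold: float = 0.5,
    ) -> "AllOutTest":
        """Full pipeline from raw displacement: differentiate → zero-lag
        Butterworth filter (skipped when the cutoff is not below Nyquist,
        e.g. 1 Hz GPS) → resample to 1 Hz → align to onset."""
        from .preprocess import (
            align_to_start,
            butterworth_zero_lag,
            differentiate,
            resample_1hz,
        )

        s = differentiate(disp)
        nyquist = 0.5 / s.sample_interval
        stages = ["differentiate"]
        if cutoff < nyquist:
            s = butterworth_zero_lag(s, cutoff=cutoff, order=filter_order)
            stages.append("butterworth_zero_lag")
        s = resample_1hz(s, duration=duration)
        s = align_to_start(s, onset_threshold=onset_threshold)
        stages += ["resample_1hz", "align_to_start"]
        s.meta["stages"] = stages
        return cls(s, duration=duration)

    def fit(self, bounds: Optional[dict] = None, **kwargs) -> "AllOutTestResults":
        fit = fit_biexp(self.series, bounds=bounds, **kwargs)
        return AllOutTestResults(self, fit)

    def predict(self, params: BiExpParams, t=None):
        t = self.series.t if t is None else t
        return _model.evaluate_speed(params, t)


class AllOutTestResults:
    """Estimates, uncertainties and diagnostics for one fitted bout."""

    def __init__(self, model_obj: AllOutTest, fit: FitResult):
        self.model = model_obj
        self.fit_result = fit
        self.params: BiExpParams = fit.params
        self.bse: Optional[dict] = fit.bse
        self.r: float = fit.r
        self.rmse: float = fit.rmse
        self.converged: bool = fit.converged
        self.derived: DerivedMetrics = _model.derived_metrics(
            fit.params, duration=model_obj.duration
        )
        self.classic: Optional[ClassicMetrics] = None
        s = model_obj.series
        if s.t[0] <= 1e-9 and s.t[-1] >= 180.0 - 1e-9:
            self.classic = classic_metrics(s)

    def predict(self, t=None):
        """Model-predicted speed at ``t`` (defaults to the fitted grid)."""
        return self.model.predict(self.params, t)

    def simulate(self, noise_sd: float = 0.0, seed: Optional[int] = None) -> SpeedTimeSeries:
        """Draw a synthetic replicate bout from the fitted parameters."""
        from .simulate import SimulationSpec, generate_trace

        spec = SimulationSpec(
            truth=self.params,
            duration=self.model.duration,
            rate=1.0,
            noise_sd=noise_sd,
            seed=0 if seed is None else seed,
        )
        return generate_trace(spec)

    def to_dict(self) -> dict:
        out = {
            "params": self.params.to_dict(),
            "bse": self.bse,
            "r": self.r,
            "rmse": self.rmse,
            "converged": self.converged,
            "n_iter": self.fit_result.n_iter,
            "derived": self.derived.to_dict(),
        }
        out["classic"] = self.classic.to_dict() if self.classic else None
        return out

    def summary(self) -> str:
        """Human-readable parameter and diagnostics table."""
        from statsmodels.iolib.table import SimpleTable

        rows = []
        for name, label, unit in [
            ("s0", "S0 (asymptote)", "m/s"),
            ("a_d", "Ad (decay amp.)", "m/s"),
            ("a_g", "Ag (growth amp.)", "m/s"),
            ("t_c", "tc (time of peak)", "s"),
            ("tau_g", "tau_g", "s"),
            ("tau_d", "tau_d", "s"),
        ]:
            est = getattr(self.params, name)
            se = self.bse.get(name) if self.bse else None
            rows.append(
                [label, f"{est:.3f}", "-" if se is None else f"{se:.3f}", unit]
            )
        tbl = SimpleTable(
            rows,
            headers=["parameter", "estimate", "std err", "unit"],
            title="All-out test bi-exponential fit",
        )
        d = self.derived
        lines = [
            str(tbl),
            f"r = {self.r:.4f}   rmse = {self.rmse:.4f} m/s   converged = {self.converged}",
            (
                f"Smax = {d.s_max:.3f} m/s   FI = {d.fi_percent:.2f} %   "
                f"S' = {d.s_prime:.1f} m   distance = {d.total_distance:.1f} m   "
                f"anaerobic fraction = {d.anaerobic_fraction:.1f} %"
            ),
        ]
        if self.classic:
            c = self.classic
            lines.append(
                f"classic CS = {c.cs:.3f} m/s   classic D' = {c.d_prime:.1f} m"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: observed speeds, fitted curve, S0 and Smax."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        s = self.model.series
        ax.plot(s.t, s.v, ".", ms=3, alpha=0.6, label="observed")
        tt = np.linspace(s.t[0], s.t[-1], 720)
        ax.plot(tt, _model.evaluate_speed(self.params, tt), "-", lw=2, label="fitted")
        ax.axhline(self.params.s0, ls="--", lw=1, color="grey", label="S0")
        ax.axvline(self.params.t_c, ls=":", lw=1, color="grey")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("speed (m/s)")
        ax.legend(frameon=False)
        return ax
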