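"""Cohort-level statistics across subjects and test conditions.

Covers the S' multiple regression (S' = β1·FI + β2·τd + β3), the
agreement statistics used to compare surrogate against criterion
measures (two-way consistency ICC, typical error, CV%), and the GXT
midpoint speed sΔ50%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "AgreementResult",
    "fit_sprime_regression",
    "predict_sprime",
    "icc_alpha",
    "typical_error",
    "cv_percent",
    "agreement",
    "delta50_speed",
    "CohortTable",
]

#: CSV column order for cohort tables (field-standard parameter names)
COHORT_COLUMNS = ["subject", "condition", "Smax", "tc", "taud", "Ad", "FI", "S0", "Sprime"]

CONDITIONS = ("linear", "shuttle50", "shuttle25")


@dataclass(frozen=True)
class RegressionResult:
    """OLS estimates for S' = β1·FI + β2·τd + β3 and fit diagnostics.

    ``see_m`` is the standard error of the estimate √(SSE/(n−3)) in
    metres; ``see_percent`` expresses it relative to the mean S'.
    """

    beta_fi: float
    beta_taud: float
    intercept: float
    r: float
    r2: float
    adj_r2: float
    see_m: float
    see_percent: float
    f_stat: float
    f_pvalue: float
    p_beta_fi: float
    p_beta_taud: float
    p_intercept: float
    n: int

    def predict(self, fi: float, taud: float) -> float:
        return predict_sprime(self.beta_fi, self.beta_taud, self.intercept, fi, taud)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class AgreementResult:
    """Two-measure agreement: consistency ICC (alpha form), typical
    error in the measure's units, and CV% relative to the grand mean."""

    icc_alpha: float
    te: float
    cv_percent: float
    icc_form: str = "two-way mixed, consistency, average measures (ICC(3,k), k=2)"

    def to_dict(self) -> dict:
        return {
            "icc_alpha": self.icc_alpha,
            "te": self.te,
            "cv_percent": self.cv_percent,
            "icc_form": self.icc_form,
        }


def fit_sprime_regression(fi, taud, sprime) -> RegressionResult:
    """Ordinary least squares of S' on fatigue index and decay constant.

    Requires n ≥ 4 (three coefficients) and a full-rank design.
    """
    fi = np.asarray(fi, dtype=float)
    taud = np.asarray(taud, dtype=float)
    sprime = np.asarray(sprime, dtype=float)
    if not (fi.size == taud.size == sprime.size):
        raise ValueError("fi, taud and sprime must have equal lengths")
    n = fi.size
    if n < 4:
        raise ValueError("need at least 4 observations for the 3-coefficient regression")
    X = sm.add_constant(np.column_stack([fi, taud]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: FI and tau_d are collinear")
    ols = sm.OLS(sprime, X).fit()
    sse = float(np.sum(ols.resid**2))
    see = float(np.sqrt(sse / (n - 3)))
    return RegressionResult(
        beta_fi=float(ols.params[1]),
        beta_taud=float(ols.params[2]),
        intercept=float(ols.params[0]),
        r=float(np.sqrt(max(ols.rsquared, 0.0))),
        r2=float(ols.rsquared),
        adj_r2=float(ols.rsquared_adj),
        see_m=see,
        see_percent=100.0 * see / float(np.mean(sprime)),
        f_stat=float(ols.fvalue),
        f_pvalue=float(ols.f_pvalue),
        p_beta_fi=float(ols.pvalues[1]),
        p_beta_taud=float(ols.pvalues[2]),
        p_intercept=float(ols.pvalues[0]),
        n=int(n),
    )


def predict_sprime(beta1: float, beta2: float, beta3: float, fi: float, taud: float) -> float:
    """Plug-in prediction S' = β1·FI + β2·τd + β3 (metres)."""
    return beta1 * fi + beta2 * taud + beta3


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal lengths")
    return x, y


def icc_alpha(x, y) -> float:
    """Two-way mixed, consistency, average-measures ICC for two measures.

    Computed from the ANOVA mean squares of the n×2 table as
    (MS_rows − MS_error)/MS_rows — the Cronbach's-alpha-equivalent form.
    A constant offset between the measures does not lower it.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations for an ICC")
    table = np.column_stack([x, y])
    if np.allclose(table.std(axis=0), 0.0):
        raise ValueError("ICC undefined: no between-subject variance in either measure")
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    k = 2
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        raise ValueError("ICC undefined: zero between-subject mean square")
    return float((ms_rows - ms_err) / ms_rows)


def typical_error(x, y) -> float:
    """Hopkins' typical error: SD of the paired differences over √2."""
    x, y = _paired(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 pairs for a typical error")
    return float(np.std(x - y, ddof=1) / np.sqrt(2.0))


def cv_percent(x, y) -> float:
    """Typical error as a percentage of the grand mean of all observations."""
    x, y = _paired(x, y)
    grand = float(np.concatenate([x, y]).mean())
    if grand <= 0:
        raise ValueError("CV% undefined for non-positive grand mean")
    return 100.0 * typical_error(x, y) / grand


def agreement(x, y) -> AgreementResult:
    return AgreementResult(
        icc_alpha=icc_alpha(x, y), te=typical_error(x, y), cv_percent=cv_percent(x, y)
    )


def delta50_speed(s_get: float, s_vo2max: float) -> float:
    """sΔ50%: the speed midway between the gas-exchange-threshold speed
    and the speed at V̇O2max from a graded exercise test."""
    if not (0 < s_get <= s_vo2max):
        raise ValueError("require 0 < s_get <= s_vo2max")
    return s_get + 0.5 * (s_vo2max - s_get)


class CohortTable:
    """Per-subject, per-condition parameter table.

    One row per subject × condition with the bi-exponential parameters,
    derived metrics and classic window metrics; round-trips as CSV with
    the field-standard column names (Smax, tc, taud, Ad, FI, S0, Sprime).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        dup = df.duplicated(subset=["subject", "condition"])
        if dup.any():
            raise ValueError("one row per subject x condition required")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_results(cls, rows: Iterable[tuple]) -> "CohortTable":
        """Build from (subject, condition, AllOutTestResults) triples."""
        records = []
        for subject, condition, res in rows:
            p, d = res.params, res.derived
            rec = {
                "subject": subject,
                "condition": condition,
                "Smax": d.s_max,
                "tc": p.t_c,
                "taud": p.tau_d,
                "Ad": p.a_d,
                "FI": d.fi_percent,
                "S0": p.s0,
                "Sprime": d.s_prime,
                "r": res.r,
            }
            if res.classic is not None:
                rec["CS"] = res.classic.cs
                rec["Dprime"] = res.classic.d_prime
            records.append(rec)
        return cls(pd.DataFrame.from_records(records))

    def to_csv(self, path) -> None:
        cols = COHORT_COLUMNS + [c for c in self.df.columns if c not in COHORT_COLUMNS]
        self.df[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def summary(self) -> pd.DataFrame:
        """Per-condition mean ± SD of the model parameters (long form:
        one row per condition with <param> and <param>_sd columns)."""
        value_cols = [c for c in ["Smax", "tc", "taud", "Ad", "FI", "S0", "Sprime"] if c in self.df]
        g = self.df.groupby("condition")[value_cols]
        means = g.mean()
        sds = g.std(ddof=1).add_suffix("_sd")
        return means.join(sds)

    def sprime_regression(self, condition: Optional[str] = None) -> RegressionResult:
        df = self.df if condition is None else self.df[self.df["condition"] == condition]
        return fit_sprime_regression(df["FI"], df["taud"], df["Sprime"])

    def dprime_sprime_agreement(self, condition: str = "linear") -> AgreementResult:
        df = self.df[self.df["condition"] == condition]
        if "Dprime" not in df or df["Dprime"].isna().any():
            raise ValueError("classic D' not available for this condition")
        return agreement(df["Dprime"].to_numpy(), df["Sprime"].to_numpy())
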