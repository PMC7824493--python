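"""Cohort-level statistics: descriptive tables and threshold regressions.

For a cohort of patients with measured motor threshold (MT), sensory
threshold (ST), their ratio, BMI and subcutaneous-adipose (SAT) thickness,
this module produces

* a descriptive row per quantity - mean, sample SD, standard error,
  range, skewness, raw kurtosis and the Jarque-Bera normality p-value; and
* simple ordinary-least-squares regressions of MT and MT/ST against BMI and
  SAT thickness, summarised by slope, intercept and the coefficient of
  determination R^2.

The MT/ST ratio is computed per patient and then averaged (the mean of
ratios, not the ratio of means).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .activation import jarque_bera, kurtosis, skewness

__all__ = [
    "DescriptiveRow",
    "RegressionResult",
    "CohortReport",
    "standard_error",
    "describe",
    "linregress",
    "cohort_report",
]

REQUIRED_COLUMNS = ("mt_mA", "st_mA", "bmi", "sat_mm")

#: The four regressions of the threshold-versus-nutritional-status analysis.
REGRESSION_PAIRS = (
    ("mt_vs_bmi", "mt_mA", "bmi"),
    ("mt_vs_sat", "mt_mA", "sat_mm"),
    ("ratio_vs_bmi", "ratio", "bmi"),
    ("ratio_vs_sat", "ratio", "sat_mm"),
)


def standard_error(sd: float, n: int) -> float:
    """Standard error of the mean, ``sd / sqrt(n)``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return sd / np.sqrt(n)


@dataclass(frozen=True)
class DescriptiveRow:
    """Descriptive statistics of one cohort quantity."""

    n: int
    mean: float
    sd: float
    se: float
    min: float
    max: float
    skewness: float
    kurtosis: float  # raw; 3 for a normal distribution
    jb_p: float
    jb_method: str

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "se": self.se,
            "min": self.min,
            "max": self.max,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "jb_p": self.jb_p,
            "jb_method": self.jb_method,
        }


def describe(
    x: np.ndarray,
    jb_method: str = "asymptotic",
    mc_reps: int = 10_000,
    seed: int | None = None,
) -> DescriptiveRow:
    """Descriptive row of one sample (needs n >= 8 for the normality test)."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError(f"describe needs at least 8 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("sample is degenerate (zero variance)")
    jb = jarque_bera(x, method=jb_method, mc_reps=mc_reps, seed=seed)
    return DescriptiveRow(
        n=x.size,
        mean=float(x.mean()),
        sd=sd,
        se=float(standard_error(sd, x.size)),
        min=float(x.min()),
        max=float(x.max()),
        skewness=skewness(x),
        kurtosis=kurtosis(x),
        jb_p=jb.p_value,
        jb_method=jb_method,
    )


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS fit ``y = slope * x + intercept`` with its R^2."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
        }


def linregress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x``; ``R^2 = 1 - SSres/SStot``.

    A constant response gives slope 0 and, by convention, ``R^2 = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"x and y differ in length ({x.size} vs {y.size})")
    if x.size < 3:
        raise ValueError(f"regression needs at least 3 points, got {x.size}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("predictor has zero variance")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return RegressionResult(slope=slope, intercept=intercept, r_squared=0.0, n=x.size)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    return RegressionResult(
        slope=slope, intercept=intercept, r_squared=1.0 - ss_res / ss_tot, n=x.size
    )


@dataclass(frozen=True)
class CohortReport:
    """Descriptive rows for MT, ST and their ratio, plus four regressions."""

    descriptives: dict[str, DescriptiveRow]
    regressions: dict[str, RegressionResult]
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "descriptives": {k: v.to_dict() for k, v in self.descriptives.items()},
            "regressions": {k: v.to_dict() for k, v in self.regressions.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def descriptives_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {k: v.to_dict() for k, v in self.descriptives.items()}
        ).T.rename_axis("quantity")

    def regressions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {k: v.to_dict() for k, v in self.regressions.items()}
        ).T.rename_axis("regression")


def cohort_report(
    cohort: pd.DataFrame,
    jb_method: str = "asymptotic",
    mc_reps: int = 10_000,
    seed: int | None = None,
) -> CohortReport:
    """Assemble the full cohort analysis from a patient table.

    ``cohort`` must provide columns ``mt_mA, st_mA, bmi, sat_mm``; the MT/ST
    ratio column is computed per patient when absent.  Needs at least 8
    complete records for the normality assessment.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {', '.join(missing)}")
    df = cohort.dropna(subset=list(REQUIRED_COLUMNS)).copy()
    if len(df) < 8:
        raise ValueError(
            f"need at least 8 complete records, got {len(df)}"
        )
    if "ratio" not in df.columns:
        df["ratio"] = df["mt_mA"] / df["st_mA"]
    descriptives = {
        name: describe(df[col].to_numpy(), jb_method=jb_method, mc_reps=mc_reps, seed=seed)
        for name, col in (("mt_mA", "mt_mA"), ("st_mA", "st_mA"), ("ratio", "ratio"))
    }
    regressions = {
        name: linregress(df[xcol].to_numpy(), df[ycol].to_numpy())
        for name, ycol, xcol in REGRESSION_PAIRS
    }
    return CohortReport(descriptives=descriptives, regressions=regressions, n=len(df))
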