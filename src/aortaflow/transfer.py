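"""Ascending-to-descending linear relation and threshold transfer.

Fits the ordinary-least-squares relation between the ascending-aorta
reference metric and its descending-aorta counterpart, then maps the
outcome-based ascending cut-offs (RVol > 42 mL, RF > 33%) through the
fitted line to obtain descending-aorta severity thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearFit",
    "ThresholdSet",
    "fit_linear",
    "derive_threshold",
    "derive_threshold_set",
    "invert_threshold",
]


@dataclass
class LinearFit:
    """OLS fit of the descending metric on the ascending metric.

    ``rmse`` is the residual root-mean-square with an ``n - 2``
    denominator (the residual SD of the fit); ``r_ci`` is the Fisher-z
    95% confidence interval of the Pearson correlation.
    """

    slope: float
    intercept: float
    r: float
    r_ci: tuple[float, float]
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r must lie in [-1, 1]")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if self.n < 3:
            raise ValueError("fit requires n >= 3")

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class ThresholdSet:
    """Descending-aorta thresholds derived from the ascending references."""

    reference_rvol: float  # mL
    reference_rf: float  # %
    derived_rvol_da: int  # mL, rounded
    derived_rf_da: int  # %, rounded
    raw_rvol_da: float
    raw_rf_da: float
    rounding: str = "nearest"


def fit_linear(pairs: pd.DataFrame | np.ndarray, y: np.ndarray | None = None) -> LinearFit:
    """Ordinary least squares of the descending metric on the ascending one.

    Accepts either a cohort table with ``x_aao`` / ``y_da`` columns or two
    arrays ``(x, y)``.  Pearson r carries a Fisher-z 95% CI
    (``tanh(atanh(r) +/- 1.96 / sqrt(n - 3))``).
    """
    if y is None:
        x_arr = np.asarray(pairs["x_aao"], dtype=float)
        y_arr = np.asarray(pairs["y_da"], dtype=float)
    else:
        x_arr = np.asarray(pairs, dtype=float)
        y_arr = np.asarray(y, dtype=float)
    if x_arr.size != y_arr.size:
        raise ValueError("x and y must have equal length")
    n = x_arr.size
    if n < 3:
        raise ValueError("linear fit requires at least 3 pairs")
    if np.any(~np.isfinite(x_arr)) or np.any(~np.isfinite(y_arr)):
        raise ValueError("x and y must be finite (no missing values)")
    if np.ptp(x_arr) == 0:
        raise ValueError("x is constant; fit undefined")

    res = stats.linregress(x_arr, y_arr)
    resid = y_arr - (res.slope * x_arr + res.intercept)
    rmse = math.sqrt(float(np.sum(resid**2)) / (n - 2))

    r = float(np.clip(res.rvalue, -1.0, 1.0))
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        r_ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        r_ci = (r, r)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        r_ci=r_ci,
        rmse=rmse,
        n=n,
    )


def derive_threshold(
    fit: LinearFit,
    reference: float,
    rounding: str = "nearest",
) -> tuple[int, float]:
    """Map an ascending reference through the fit: ``slope * ref + intercept``.

    Returns ``(rounded, raw)``; rounding is to the nearest integer by
    default (``'floor'`` also supported).
    """
    raw = fit.slope * reference + fit.intercept
    if rounding == "nearest":
        rounded = int(np.rint(raw))
    elif rounding == "floor":
        rounded = int(math.floor(raw))
    else:
        raise ValueError(f"unknown rounding convention {rounding!r}")
    return rounded, float(raw)


def derive_threshold_set(
    fit_rvol: LinearFit,
    fit_rf: LinearFit,
    reference_rvol: float = 42.0,
    reference_rf: float = 33.0,
    rounding: str = "nearest",
) -> ThresholdSet:
    """Derive the full descending-aorta threshold set from both fits."""
    rvol_da, raw_rvol = derive_threshold(fit_rvol, reference_rvol, rounding)
    rf_da, raw_rf = derive_threshold(fit_rf, reference_rf, rounding)
    return ThresholdSet(
        reference_rvol=reference_rvol,
        reference_rf=reference_rf,
        derived_rvol_da=rvol_da,
        derived_rf_da=rf_da,
        raw_rvol_da=raw_rvol,
        raw_rf_da=raw_rf,
        rounding=rounding,
    )


def invert_threshold(fit: LinearFit, da_value: float) -> float:
    """Implied ascending value for a descending one: ``(y - b) / a``."""
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope fit")
    return (da_value - fit.intercept) / fit.slope
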