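"""Assay-performance statistics: dilution linearity and repeatability.

Linearity is ordinary least squares of measured against expected values,
on a linear or log-log scale (natural log; the base changes slope and
intercept but not R^2).  Repeatability is the inter-assay coefficient of
variation, CV% = 100 * sample SD / mean, per dilution condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LinearityReport",
    "RepeatabilityReport",
    "dilution_linearity",
    "inter_assay_cv",
]


@dataclass
class LinearityReport:
    slope: float
    intercept: float
    r_squared: float
    scale: str  # "linear" or "log-log" (natural log)
    n_points: int


@dataclass
class RepeatabilityReport:
    per_condition_cv: dict[str, float]  # condition -> CV%
    max_cv: float
    n_timepoints: int


def dilution_linearity(expected, measured, scale: str = "linear") -> LinearityReport:
    """OLS fit of measured vs expected concentrations; R^2 = 1 - SSres/SStot."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expected and measured must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a linearity fit")
    if scale == "log-log":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log-log scale requires strictly positive values")
        x, y = np.log(x), np.log(y)
    elif scale != "linear":
        raise ValueError(f"unknown scale: {scale!r}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in expected values: degenerate regression")
    fit = stats.linregress(x, y)
    return LinearityReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        scale=scale,
        n_points=int(x.size),
    )


def inter_assay_cv(measurements_by_condition: dict) -> RepeatabilityReport:
    """CV% per condition across repeat runs; max over conditions reported."""
    if not measurements_by_condition:
        raise ValueError("need at least one condition")
    cvs: dict[str, float] = {}
    n_timepoints = None
    for cond, values in measurements_by_condition.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"condition {cond!r}: need >= 2 replicate values")
        mean = v.mean()
        if mean == 0:
            raise ValueError(f"condition {cond!r}: zero mean, CV undefined")
        cvs[str(cond)] = float(100.0 * v.std(ddof=1) / mean)
        n_timepoints = v.size if n_timepoints is None else min(n_timepoints, v.size)
    return RepeatabilityReport(
        per_condition_cv=cvs,
        max_cv=max(cvs.values()),
        n_timepoints=int(n_timepoints),
    )
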