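"""Trendline fitting and the sorted log-log activity correlation.

Five spreadsheet trendline families are supported.  Exponential and power
fits follow the spreadsheet convention: ordinary least squares on the
log-transformed model, with R^2 reported on the transformed scale.  The
sorted correlation pairs two independently rank-ordered log series — a
procedure that destroys sample identity and yields a rank-alignment
curve, not a per-sample correlation; the result carries an explicit
methodological warning to that effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import RegressionFit

FAMILIES = ("linear", "quadratic", "exponential", "power", "logarithmic")

RANK_PAIRING_WARNING = (
    "rank-pairing of independently sorted series destroys sample identity; "
    "the fit describes rank alignment, not a per-sample correlation"
)


class FitError(ValueError):
    """Insufficient or degenerate data for the requested fit."""


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0  # constant response: R^2 defined as 0 by convention
    return 1.0 - ss_res / ss_tot


def _polyfit(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)[::-1]  # highest first
    return coeffs, _r_squared(y, np.polyval(coeffs, x))


def fit_relation(x_values, y_values, family: str) -> RegressionFit:
    """Least-squares fit of one trendline family.

    Coefficients are reported in caption order: ``quadratic`` (a, b, c)
    for y = a x^2 + b x + c; ``linear`` (a, b) for y = a x + b;
    ``exponential`` (a, b) for y = a e^(bx); ``power`` (a, b) for
    y = a x^b; ``logarithmic`` (a, b) for y = a ln(x) + b.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown fit family {family!r}; use one of {FAMILIES}")
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-D arrays of equal length")
    arity = 3 if family == "quadratic" else 2
    if len(x) < arity:
        raise FitError(f"{family} fit needs at least {arity} points, got {len(x)}")

    if family in ("power", "logarithmic") and (x <= 0).any():
        raise FitError(f"{family} fit requires x > 0")
    if family in ("power", "exponential") and (y <= 0).any():
        raise FitError(f"{family} fit (log-transformed) requires y > 0")

    if family in ("linear", "quadratic"):
        tx, ty = x, y
    elif family == "exponential":
        tx, ty = x, np.log(y)
    elif family == "power":
        tx, ty = np.log(x), np.log(y)
    else:  # logarithmic
        tx, ty = np.log(x), y

    if np.ptp(tx) == 0.0:
        raise FitError("zero variance in x: degenerate fit")

    degree = 2 if family == "quadratic" else 1
    coeffs, r2 = _polyfit(tx, ty, degree)
    if family in ("exponential", "power"):
        slope, intercept = coeffs
        coeffs = np.array([math.exp(intercept), slope])

    return RegressionFit(
        family=family,
        coefficients=tuple(float(c) for c in coeffs),
        r_squared=float(r2),
        n=len(x),
    )


@dataclass
class SortedCorrelation:
    """Rank-paired log series and their quadratic rank-alignment fit."""

    pairs: list[tuple[float, float]]
    fit: RegressionFit
    n_excluded_x: int
    n_excluded_y: int
    warnings: tuple[str, ...] = field(default_factory=tuple)


def sorted_log_correlation(asf_values, activity_values) -> SortedCorrelation:
    """Pair log10(ASF) and log10(GI50) by descending rank and fit a quadratic.

    Both series are log10-transformed, independently sorted highest to
    lowest, truncated to the shorter length and paired by rank
    (x = log ASF, y = log GI50).  Non-positive values, whose logarithm
    does not exist, are excluded and counted.
    """
    x_raw = [float(v) for v in asf_values]
    y_raw = [float(v) for v in activity_values]
    if not x_raw or not y_raw:
        raise ValueError("both input lists must be non-empty")
    x_pos = [v for v in x_raw if v > 0]
    y_pos = [v for v in y_raw if v > 0]
    if not x_pos or not y_pos:
        raise ValueError("no positive values to log-transform")

    log_x = sorted((math.log10(v) for v in x_pos), reverse=True)
    log_y = sorted((math.log10(v) for v in y_pos), reverse=True)
    n = min(len(log_x), len(log_y))
    pairs = list(zip(log_x[:n], log_y[:n]))

    fit = fit_relation([p[0] for p in pairs], [p[1] for p in pairs], "quadratic")
    warnings = [RANK_PAIRING_WARNING]
    if len(log_x) != len(log_y):
        warnings.append(
            f"series lengths differ ({len(log_x)} vs {len(log_y)}); "
            f"truncated to the shorter length {n}"
        )
    return SortedCorrelation(
        pairs=pairs,
        fit=fit,
        n_excluded_x=len(x_raw) - len(x_pos),
        n_excluded_y=len(y_raw) - len(y_pos),
        warnings=tuple(warnings),
    )
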