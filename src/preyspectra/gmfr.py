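"""Geometric mean functional relationship (standardized major axis) fitting.

When both variables carry comparable measurement error — predator and prey
shell lengths measured the same way — ordinary least squares of y on x is
not a meaningful description of the relationship, because neither variable
is an error-free regressor. The GMFR/SMA line instead has slope
``sign(r) * s_y / s_x`` and passes through the centroid; its magnitude is
the geometric mean of the two OLS slopes. Association strength is reported
separately as r², the squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError


@dataclass(frozen=True)
class GMFRFit:
    """A fitted standardized-major-axis line.

    ``sign_of_r`` records the sign of the Pearson correlation; when r is
    exactly zero the slope sign is undefined in theory and the convention
    here is +1, flagged by ``sign_of_r = 0``.
    """

    slope: float
    intercept: float
    r2: float
    n: int
    sign_of_r: int


def _clean_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 points, got {x.size}")
    if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        raise DegenerateDataError("zero variance in x or y")
    return x, y


def fit_gmfr(x, y) -> GMFRFit:
    """Fit the GMFR/SMA line to paired size measurements.

    Standard deviations use the n-1 denominator; the slope ratio itself is
    denominator-invariant. Swapping the axes inverts the slope exactly, and
    rescaling y by c rescales the slope by c.
    """
    x, y = _clean_xy(x, y)
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 0 if r == 0 else (1 if r > 0 else -1)
    slope = (sign if sign != 0 else 1) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return GMFRFit(
        slope=float(slope),
        intercept=intercept,
        r2=r * r,
        n=int(x.size),
        sign_of_r=sign,
    )


def r_squared(x, y) -> float:
    """Squared Pearson correlation of two size vectors, in [0, 1]."""
    x, y = _clean_xy(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    return min(r * r, 1.0)
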