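"""Null distributions of angles between random directions in k dimensions.

Under the null hypothesis that two vectors are independent with no preferred
direction (each uniform on the unit hypersphere S^(k-1)), the angle theta
between them has density

    f(theta) = sin^(k-2)(theta) / B(1/2, (k-1)/2),   0 <= theta <= pi,

peaked at the right angle and increasingly concentrated there as the
dimensionality k grows.  Equivalently the vector correlation r = cos(theta)
has density (1 - r^2)^((k-3)/2) / B(1/2, (k-1)/2), the squared correlation
s = r^2 is Beta(1/2, (k-1)/2), and the monotone transform

    t = sqrt(k-1) * r / sqrt(1 - r^2) = sqrt(k-1) / tan(theta)

follows a t distribution with k-1 degrees of freedom.  All p-values here are
routed through these exact closed forms; no simulation is involved.

k is the *effective* dimensionality — the dimensions of free variation —
which can be below the nominal trait count when traits are linearly
dependent (e.g. Procrustes-aligned 2-D shape coordinates lose 4 df).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .result import TestResult

__all__ = [
    "AngleNull",
    "angle_density",
    "correlation_density",
    "angle_cdf",
    "angle_test",
    "angle_effect_size",
    "beta_moments_squared_correlation",
    "effective_dimensionality",
]

#: tolerance for clipping |r| slightly above 1 caused by floating point
_R_CLIP_TOL = 1e-12


@dataclass(frozen=True)
class AngleNull:
    """Null law of the angle between uniform random directions in k dims.

    Parameters
    ----------
    k : int
        Effective dimensionality of the trait space; must be >= 2.
    """

    k: int

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 2:
            raise ValueError(f"k must be an integer >= 2, got {self.k}")

    @property
    def _log_norm(self) -> float:
        # log B(1/2, (k-1)/2), the normalizing constant of every form
        return special.betaln(0.5, (self.k - 1) / 2.0)


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > math.pi)):
        raise ValueError("theta must lie in [0, pi]")
    return theta


def clip_correlation(r, tol: float = _R_CLIP_TOL):
    """Clip r into [-1, 1], tolerating floating-point overshoot up to tol.

    Overshoot larger than tol is a genuine error (the input is not a
    correlation), not numerical noise, and raises.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + tol):
        raise ValueError("correlation outside [-1, 1] beyond tolerance")
    return np.clip(r, -1.0, 1.0)


def angle_density(null: AngleNull, theta) -> np.ndarray | float:
    """Density of the angle between two uniform random k-directions.

    f(theta) = sin^(k-2)(theta) / B(1/2, (k-1)/2) on [0, pi]; uniform at
    k = 2 and symmetric about pi/2 for every k.
    """
    theta = _check_theta(theta)
    k = null.k
    if k == 2:  # sin^0 == 1 everywhere: the angle is uniform on [0, pi]
        out = np.full(theta.shape, np.exp(-null._log_norm))
    else:
        with np.errstate(divide="ignore"):
            out = np.exp((k - 2) * np.log(np.sin(theta)) - null._log_norm)
    return out if out.shape else float(out)


def correlation_density(null: AngleNull, r) -> np.ndarray | float:
    """Density of the vector correlation r = cos(theta) under the null.

    f(r) = (1 - r^2)^((k-3)/2) / B(1/2, (k-1)/2) on [-1, 1].  For k = 2 the
    density diverges at the endpoints; +inf is returned there (the CDF is
    still proper).
    """
    r = clip_correlation(r)
    k = null.k
    with np.errstate(divide="ignore"):
        out = np.exp((k - 3) / 2.0 * np.log1p(-np.square(r)) - null._log_norm)
    return out if out.shape else float(out)


def angle_cdf(null: AngleNull, theta) -> np.ndarray | float:
    """P(Theta <= theta) via the exact t-distribution route.

    t = sqrt(k-1) / tan(theta) is monotone decreasing in theta, so
    P(Theta <= theta) = P(T >= t) with T ~ t(k-1).  Endpoints map to 0 / 1.
    """
    theta = _check_theta(theta)
    k = null.k
    with np.errstate(divide="ignore"):
        t = math.sqrt(k - 1) / np.tan(theta)
    # tan(pi) is a tiny negative number in floats -> t = -inf, sf = 1: exact
    out = stats.t.sf(t, df=k - 1)
    out = np.where(theta == 0.0, 0.0, out)
    out = np.where(theta == math.pi, 1.0, out)
    return out if out.shape else float(out)


_ALTERNATIVES = ("two_sided", "parallel", "antiparallel", "axial")


def angle_test(theta: float, k: int,
               alternative: str = "two_sided") -> TestResult:
    """Test whether an observed angle departs from the uniform-direction null.

    Parameters
    ----------
    theta : float
        Observed angle in radians, in [0, pi].
    k : int
        Effective dimensionality of the trait space.
    alternative : {"two_sided", "parallel", "antiparallel", "axial"}
        "parallel" counts small angles as extreme, "antiparallel" large
        angles, "two_sided" both.  "axial" ignores vector polarity and
        refers cos^2(theta) to its Beta(1/2, (k-1)/2) null — appropriate
        for directionless axes such as eigenvectors.

    Returns
    -------
    TestResult
        With the angle (radians and degrees), r and the t statistic in
        ``details``.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    null = AngleNull(k)
    theta = float(_check_theta(theta))
    r = math.cos(theta)
    cdf = float(angle_cdf(null, theta))
    if alternative == "two_sided":
        p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    elif alternative == "parallel":
        p = cdf
    elif alternative == "antiparallel":
        p = 1.0 - cdf
    else:  # axial: upper tail of s = r^2 ~ Beta(1/2, (k-1)/2)
        p = float(stats.beta.sf(r * r, 0.5, (k - 1) / 2.0))
    sin_theta = math.sin(theta)
    t = math.sqrt(k - 1) * r / sin_theta if sin_theta > 0 else math.inf * np.sign(r)
    return TestResult(
        method="angle",
        statistic=theta,
        p_value=p,
        k=k,
        null_mean=math.pi / 2.0,
        alternative=alternative,
        details={
            "theta_rad": theta,
            "theta_deg": math.degrees(theta),
            "r": r,
            "t": t,
            "df": k - 1,
        },
    )


def angle_effect_size(theta: float, k: int) -> float:
    """Dimensionality-standardized deviation from orthogonality.

    Returns sqrt(k-2) * (pi/2 - theta): positive when the angle is closer
    to parallel than to orthogonal.  Under the uniform null this quantity
    converges to a standard normal as k grows, making angles comparable
    across trait spaces of different dimensionality.
    """
    if int(k) != k or k < 3:
        raise ValueError("k must be an integer >= 3 for the standardization")
    theta = float(_check_theta(theta))
    return math.sqrt(k - 2) * (math.pi / 2.0 - theta)


def beta_moments_squared_correlation(k: int) -> tuple[float, float]:
    """Mean and variance of the squared correlation under the null.

    cos^2(theta) ~ Beta(1/2, (k-1)/2), with mean 1/k and variance
    2(k-1) / (k^2 (k+2)).
    """
    if int(k) != k or k < 2:
        raise ValueError(f"k must be an integer >= 2, got {k}")
    mean = 1.0 / k
    var = 2.0 * (k - 1) / (k * k * (k + 2))
    return mean, var


def effective_dimensionality(p: int, lost_df: int = 0) -> int:
    """Effective dimensionality k = p - lost_df.

    Shape coordinates and other constrained traits carry fewer dimensions
    of free variation than their nominal count; e.g. Procrustes alignment
    of 2-D landmarks removes 4 degrees of freedom.
    """
    k = p - lost_df
    if lost_df < 0:
        raise ValueError("lost_df must be nonnegative")
    if k < 2:
        raise ValueError(f"effective dimensionality {k} < 2")
    return k
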