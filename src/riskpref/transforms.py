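"""Unconstrained <-> constrained parameter transforms.

Sampling works on an unconstrained space; parameters are mapped to their
admissible intervals with the exponential transform for positive-only
parameters and a Phi (standard-normal CDF) transform for two-sided bounds:

    (0, inf):  theta = exp(z)
    (a, b):    theta = a + (b - a) * Phi(z)

Both are strictly monotone with closed-form inverses and log-Jacobians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["Interval", "POSITIVE", "constrain", "unconstrain", "constrain_jac"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Interval:
    """Support of one parameter; ``upper = inf`` selects the exp transform."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError(f"empty interval ({self.lower}, {self.upper})")
        if math.isinf(self.lower):
            raise ValueError("lower bound must be finite")
        if math.isinf(self.upper) and self.lower != 0.0:
            raise ValueError("one-sided intervals must be (0, inf)")

    @property
    def two_sided(self) -> bool:
        return math.isfinite(self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower


POSITIVE = Interval(0.0, math.inf)


def constrain(z, bounds: Interval):
    """Map unconstrained z to the interval: exp(z) or a + (b-a)*Phi(z)."""
    z = np.asarray(z, dtype=float)
    if bounds.two_sided:
        out = bounds.lower + bounds.width * ndtr(z)
    else:
        out = np.exp(z)
    return out if out.ndim else float(out)


def unconstrain(theta, bounds: Interval):
    """Inverse of :func:`constrain`."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= bounds.lower) or (
        bounds.two_sided and np.any(theta >= bounds.upper)
    ):
        raise ValueError(f"value outside open interval ({bounds.lower}, {bounds.upper})")
    if bounds.two_sided:
        out = ndtri((theta - bounds.lower) / bounds.width)
    else:
        out = np.log(theta)
    return out if out.ndim else float(out)


def constrain_jac(z, bounds: Interval):
    """Derivative d(theta)/dz of the constraining map (always positive)."""
    z = np.asarray(z, dtype=float)
    if bounds.two_sided:
        out = bounds.width * np.exp(-0.5 * z**2 - _LOG_SQRT_2PI)
    else:
        out = np.exp(z)
    return out if out.ndim else float(out)
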