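"""Rank-dependent utility with probability weighting and Luce-form choice.

The decision model has three subject-level parameters:

* ``r`` — CRRA curvature, ``U(x) = x**r`` for gains and ``-(-x)**r`` for
  losses; ``r < 1`` is risk aversion in the gain domain.
* ``gamma`` — curvature of the probability weighting function (``alpha``
  for the one-parameter Prelec family); values above 1 give an S-shape.
* ``tau`` — inverse temperature (choice consistency), ``tau = 1/mu`` where
  ``mu`` is the logistic noise scale; ``tau -> inf`` is deterministic choice.

For a two-outcome lottery the best outcome receives decision weight
``w(p_best)`` and the worst outcome the complement ``1 - w(p_best)``.
Choice between options A and B follows the strict-utility (Luce) rule on
log expected utilities, with the ``1/r`` value-function rescaling that
decorrelates curvature and noise:

    P(A > B) = logistic(tau * (1/r) * ln(EU_A / EU_B))

In the loss domain both rank-dependent utilities are negative; the sign of
the log-ratio term is flipped so that the option with the larger (less
negative) utility is preferred in the deterministic limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .task import Lottery, LotteryPair

__all__ = [
    "FAMILIES",
    "PreferenceParams",
    "crra_utility",
    "prob_weight",
    "prob_weight_grad",
    "rdu_value",
    "choice_prob",
    "simulate_choice",
]

#: Closed enumeration of the weighting-function specifications.
FAMILIES = ("linear", "kahneman_tversky", "prelec1")

_EPS = 1e-12


@dataclass(frozen=True)
class PreferenceParams:
    """(r, gamma, tau) for one subject in one condition.

    ``gamma`` is ignored by the linear family (set it to 1.0 there).
    """

    r: float
    gamma: float
    tau: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown weighting family {family!r}; one of {FAMILIES}")


def crra_utility(x, r):
    """CRRA value function: ``x**r`` for gains, ``-(-x)**r`` for losses.

    Accepts scalars or arrays; ``r`` must be positive.
    """
    if np.any(np.asarray(r) <= 0):
        raise ValueError("r must be positive")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.abs(x) ** r
    return out if out.ndim else float(out)


def prob_weight(p, param, family: str):
    """Decision weight w(p) for the given family.

    linear: w(p) = p.
    kahneman_tversky: w(p) = p**g / (p**g + (1-p)**g) ** (1/g).
    prelec1: w(p) = exp(-(-ln p) ** a)  (endpoints taken as limits).
    """
    _check_family(family)
    if np.any(np.asarray(param) <= 0):
        raise ValueError("weighting parameter must be positive")
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    w, _ = _weight_and_grad(p_arr, np.asarray(param, dtype=float), family)
    return w if w.ndim or np.ndim(p) or np.ndim(param) else float(w)


def _weight_and_grad(p: np.ndarray, g: np.ndarray, family: str):
    """Vectorized (w(p), dw/dparam); endpoints w(0)=0, w(1)=1 exact with
    zero parameter sensitivity."""
    if family == "linear":
        w = p.copy()
        return w, np.zeros(np.broadcast_shapes(p.shape, np.shape(g)))
    interior = (p > 0.0) & (p < 1.0)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    if family == "kahneman_tversky":
        lp, lq = np.log(pc), np.log1p(-pc)
        pg, qg = np.exp(g * lp), np.exp(g * lq)
        s = pg + qg
        ls = np.log(s)
        logw = g * lp - ls / g
        w = np.exp(logw)
        dlogw = lp + ls / g**2 - (pg * lp + qg * lq) / (g * s)
        dw = w * dlogw
    else:  # prelec1
        nlp = -np.log(pc)  # > 0 in the interior
        t = nlp ** np.broadcast_to(g, np.shape(nlp)) if np.ndim(g) else nlp**g
        w = np.exp(-t)
        dw = -w * t * np.log(nlp)
    w = np.where(interior, w, p)  # exact endpoints
    dw = np.where(interior, dw, 0.0)
    return w, dw


def prob_weight_grad(p, param, family: str):
    """dw/dparam, matching :func:`prob_weight` (zero for the linear family)."""
    _check_family(family)
    _, dw = _weight_and_grad(
        np.asarray(p, dtype=float), np.asarray(param, dtype=float), family
    )
    return dw if dw.ndim or np.ndim(p) else float(dw)


def rdu_value(lottery: Lottery, params: PreferenceParams, family: str) -> float:
    """Rank-dependent utility of a two-outcome lottery:
    ``w(p_best) * U(x_best) + (1 - w(p_best)) * U(x_worst)``."""
    w = prob_weight(lottery.p_best, params.gamma, family)
    return float(
        w * crra_utility(lottery.x_best, params.r)
        + (1.0 - w) * crra_utility(lottery.x_worst, params.r)
    )


def choice_prob(
    pair: LotteryPair,
    params: PreferenceParams,
    family: str,
    domain: str = "gain",
) -> float:
    """Probability of choosing option A under the Luce rule.

    Raises if the two rank-dependent utilities differ in sign or either is
    zero (the log of their ratio is then undefined).
    """
    if domain not in ("gain", "loss"):
        raise ValueError(f"domain must be 'gain' or 'loss', got {domain!r}")
    eu_a = rdu_value(pair.option_a, params, family)
    eu_b = rdu_value(pair.option_b, params, family)
    if eu_a == 0.0 or eu_b == 0.0 or (eu_a > 0) != (eu_b > 0):
        raise ValueError(
            f"rank-dependent utilities must be nonzero with a common sign; "
            f"got EU_A={eu_a}, EU_B={eu_b}"
        )
    sign = 1.0 if domain == "gain" else -1.0
    z = sign * params.tau / params.r * (math.log(abs(eu_a)) - math.log(abs(eu_b)))
    # logistic, stable in both tails
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    return math.exp(z) / (1.0 + math.exp(z))


def simulate_choice(
    pair: LotteryPair,
    params: PreferenceParams,
    family: str,
    domain: str,
    rng: np.random.Generator,
) -> str:
    """Bernoulli draw from the choice rule: 'A' with probability
    ``choice_prob(...)``, else 'B'."""
    return "A" if rng.random() < choice_prob(pair, params, family, domain) else "B"


# ---------------------------------------------------------------------------
# Vectorized kernel shared with the inference module
# ---------------------------------------------------------------------------

def choice_logit_arrays(
    xa_best,
    xa_worst,
    xb_best,
    xb_worst,
    p_best,
    r,
    gamma,
    tau,
    family: str,
    sign,
):
    """Vectorized Luce-rule logit z with derivatives wrt (r, gamma, tau).

    All lottery arrays and parameter arrays broadcast trial-wise.  ``sign``
    is +1 for gain-domain trials and -1 for loss-domain trials.  Returns
    ``(z, dz_dr, dz_dgamma, dz_dtau)`` where ``P(A) = logistic(z)``.

    The derivative algebra: with ``L = ln|EU_A| - ln|EU_B|``,
    ``z = sign * tau/r * L``; ``dU/dr = U * ln|x|`` (zero at x = 0) and
    ``dEU/dgamma = dw/dgamma * (U_best - U_worst)``.
    """
    xa_best, xa_worst, xb_best, xb_worst, p_best = (
        np.asarray(a, dtype=float)
        for a in (xa_best, xa_worst, xb_best, xb_worst, p_best)
    )
    r = np.asarray(r, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    tau = np.asarray(tau, dtype=float)
    sign = np.asarray(sign, dtype=float)

    w, dw = _weight_and_grad(p_best, gamma, family)

    def _u_and_du(x):
        u = np.sign(x) * np.abs(x) ** r
        with np.errstate(divide="ignore"):
            lx = np.where(x == 0.0, 0.0, np.log(np.abs(np.where(x == 0.0, 1.0, x))))
        return u, u * lx

    u1a, du1a = _u_and_du(xa_best)
    u2a, du2a = _u_and_du(xa_worst)
    u1b, du1b = _u_and_du(xb_best)
    u2b, du2b = _u_and_du(xb_worst)

    eu_a = w * u1a + (1.0 - w) * u2a
    eu_b = w * u1b + (1.0 - w) * u2b
    if np.any(eu_a == 0.0) or np.any(eu_b == 0.0) or np.any((eu_a > 0) != (eu_b > 0)):
        raise FloatingPointError("degenerate expected-utility ratio")

    big_l = np.log(np.abs(eu_a)) - np.log(np.abs(eu_b))
    dl_dr = (w * du1a + (1.0 - w) * du2a) / eu_a - (w * du1b + (1.0 - w) * du2b) / eu_b
    dl_dg = dw * (u1a - u2a) / eu_a - dw * (u1b - u2b) / eu_b

    z = sign * tau / r * big_l
    dz_dr = sign * tau * (dl_dr / r - big_l / r**2)
    dz_dg = sign * tau / r * dl_dg
    dz_dtau = sign * big_l / r
    return z, dz_dr, dz_dg, dz_dtau
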