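"""Seed-deterministic Hamiltonian Monte Carlo with diagonal mass matrix.

Two samplers share the adaptation machinery:

* :func:`sample_nuts` — the No-U-Turn Sampler (recursive tree doubling
  with slice sampling across the trajectory), which self-tunes trajectory
  length and is the default for the strongly ridged posteriors of
  rank-dependent-utility models;
* :func:`sample_chain` — static-trajectory HMC with jittered leapfrog
  counts, kept for cheap targets and as a cross-check.

Warmup adapts the step size by dual averaging toward a target acceptance
statistic and (optionally) re-estimates the diagonal mass matrix from the
middle warmup window, after which step-size adaptation restarts against
the new metric.  Trajectories whose Hamiltonian error explodes are counted
as divergences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ChainResult", "DiagMetric", "DenseMetric", "sample_chain", "sample_nuts"]

_DIVERGENCE_ENERGY = 1000.0


class DiagMetric:
    """Diagonal kinetic-energy metric; ``inv_mass`` is the velocity scale
    (posterior variance estimate) per coordinate."""

    def __init__(self, inv_mass: np.ndarray):
        self.inv_mass = np.asarray(inv_mass, dtype=float)
        self._sqrt_mass = 1.0 / np.sqrt(self.inv_mass)

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.inv_mass.size) * self._sqrt_mass

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.inv_mass * p


class DenseMetric:
    """Dense metric M = precision (e.g. a posterior Hessian): momenta are
    N(0, M), velocities M^{-1} p.  ``precision`` is symmetrized and its
    eigenvalues floored to keep it positive definite."""

    def __init__(self, precision: np.ndarray, min_eig: float = 0.4):
        a = 0.5 * (precision + precision.T)
        w, v = np.linalg.eigh(a)
        # floor the eigenvalues: near-flat (ridge) directions would
        # otherwise propose arbitrarily long jumps into curved territory
        w = np.maximum(w, min_eig)
        self._chol = v * np.sqrt(w)          # chol-like factor of M
        self._inv = (v / w) @ v.T            # M^{-1}
        self.inv_mass = np.diag(self._inv)   # diagnostic only

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return self._chol @ rng.standard_normal(self._chol.shape[0])

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self._inv @ p


def _as_metric(metric) -> "DiagMetric | DenseMetric":
    if isinstance(metric, (DiagMetric, DenseMetric)):
        return metric
    return DiagMetric(np.asarray(metric, dtype=float))


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_draws, dim) unconstrained draws
    accept_rate: float
    divergences: int
    step_size: float
    inv_mass: np.ndarray


class _DualAveraging:
    """Nesterov dual averaging of log step size (standard constants)."""

    def __init__(self, step0: float, target: float):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.log_step = np.log(step0)
        self.log_step_bar = np.log(step0)
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_stat: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_stat)
        self.log_step = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** -self.kappa
        self.log_step_bar = eta * self.log_step + (1.0 - eta) * self.log_step_bar
        return np.exp(self.log_step)

    def restart(self, step0: float) -> None:
        self.mu = np.log(10.0 * step0)
        self.log_step = np.log(step0)
        self.log_step_bar = np.log(step0)
        self.h_bar = 0.0
        self.count = 0


def _leapfrog(logp_grad, z, p, step, n_steps, inv_mass):
    lp, grad = logp_grad(z)
    for _ in range(n_steps):
        p = p + 0.5 * step * grad
        z = z + step * inv_mass * p
        lp, grad = logp_grad(z)
        if not np.isfinite(lp):
            return z, p, -np.inf, grad
        p = p + 0.5 * step * grad
    return z, p, lp, grad


def sample_chain(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_leapfrog: int = 32,
    init_step: float = 0.1,
    inv_mass0: np.ndarray | None = None,
    adapt_mass: bool = True,
) -> ChainResult:
    """Run one HMC chain; returns kept (post-warmup) draws.

    ``inv_mass0`` seeds the diagonal metric (e.g. from curvature at a
    mode); warmup refines it from sample variances unless ``adapt_mass``
    is off.
    """
    z = np.asarray(z0, dtype=float).copy()
    dim = z.size
    inv_mass = np.ones(dim) if inv_mass0 is None else np.asarray(inv_mass0, float)
    sqrt_mass = 1.0 / np.sqrt(inv_mass)  # momentum scale
    step = init_step
    adapter = _DualAveraging(init_step, target_accept)

    # warmup windows: mass estimated from the middle stretch, then the
    # step size re-adapts against the new metric for the tail stretch
    collect_lo = int(0.25 * n_warmup)
    mass_switch = int(0.9 * n_warmup)
    buffer: list[np.ndarray] = []

    lp, _ = logp_grad(z)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    draws = np.empty((n_draws, dim))
    n_accept = 0
    divergences = 0
    lo = max(1, max_leapfrog // 2)

    for it in range(n_warmup + n_draws):
        p = rng.standard_normal(dim) * sqrt_mass
        h0 = lp - 0.5 * np.dot(p * inv_mass, p)
        n_steps = int(rng.integers(lo, max_leapfrog + 1))
        z_new, p_new, lp_new, _ = _leapfrog(logp_grad, z, p, step, n_steps, inv_mass)
        if np.isfinite(lp_new):
            h1 = lp_new - 0.5 * np.dot(p_new * inv_mass, p_new)
            delta = h1 - h0
        else:
            delta = -np.inf
        if delta < -_DIVERGENCE_ENERGY or not np.isfinite(delta):
            accept_stat, accept = 0.0, False
            divergences += 1 if it >= n_warmup else 0
        else:
            accept_stat = min(1.0, float(np.exp(delta)))
            accept = rng.random() < accept_stat
        if accept:
            z, lp = z_new, lp_new

        if it < n_warmup:
            step = adapter.update(accept_stat)
            if collect_lo <= it < mass_switch:
                buffer.append(z.copy())
            if adapt_mass and it == mass_switch - 1 and len(buffer) >= 10:
                var = np.var(np.asarray(buffer), axis=0)
                # regularized toward unity, as in windowed adaptation
                n = len(buffer)
                var = n / (n + 5.0) * var + 5.0 / (n + 5.0) * 1e-3
                inv_mass = np.maximum(var, 1e-8)
                sqrt_mass = 1.0 / np.sqrt(inv_mass)
                adapter.restart(float(np.exp(adapter.log_step_bar)))
            if it == n_warmup - 1:
                step = float(np.exp(adapter.log_step_bar))
        else:
            draws[it - n_warmup] = z
            n_accept += int(accept)

    return ChainResult(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        divergences=divergences,
        step_size=step,
        inv_mass=inv_mass,
    )


# ---------------------------------------------------------------------------
# No-U-Turn Sampler
# ---------------------------------------------------------------------------

class _Tree:
    """One NUTS trajectory tree (slice-sampling variant)."""

    __slots__ = (
        "z_minus", "p_minus", "g_minus", "z_plus", "p_plus", "g_plus",
        "z_prop", "lp_prop", "n", "s", "alpha", "n_alpha", "div",
    )


def _nuts_leapfrog(logp_grad, z, p, grad, step, metric):
    p = p + 0.5 * step * grad
    z = z + step * metric.velocity(p)
    lp, grad = logp_grad(z)
    p = p + 0.5 * step * grad
    return z, p, lp, grad


def _no_uturn(z_minus, z_plus, p_minus, p_plus, metric):
    dz = z_plus - z_minus
    return (
        np.dot(dz, metric.velocity(p_minus)) >= 0.0
        and np.dot(dz, metric.velocity(p_plus)) >= 0.0
    )


def _build_tree(logp_grad, z, p, grad, logu, v, j, step, metric, h0, rng):
    tree = _Tree()
    if j == 0:
        z1, p1, lp1, g1 = _nuts_leapfrog(logp_grad, z, p, grad, v * step, metric)
        h1 = lp1 - 0.5 * np.dot(p1, metric.velocity(p1)) if np.isfinite(lp1) else -np.inf
        tree.z_minus = tree.z_plus = tree.z_prop = z1
        tree.p_minus = tree.p_plus = p1
        tree.g_minus = tree.g_plus = g1
        tree.lp_prop = lp1
        tree.n = int(np.isfinite(h1) and logu <= h1)
        tree.s = int(np.isfinite(h1) and logu < h1 + _DIVERGENCE_ENERGY)
        tree.alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0)))) if np.isfinite(h1) else 0.0
        tree.n_alpha = 1
        tree.div = not tree.s
        return tree
    left = _build_tree(logp_grad, z, p, grad, logu, v, j - 1, step, metric, h0, rng)
    tree.z_prop, tree.lp_prop = left.z_prop, left.lp_prop
    tree.n, tree.s = left.n, left.s
    tree.alpha, tree.n_alpha = left.alpha, left.n_alpha
    tree.div = left.div
    if v == -1:
        tree.z_plus, tree.p_plus, tree.g_plus = left.z_plus, left.p_plus, left.g_plus
        tree.z_minus, tree.p_minus, tree.g_minus = (
            left.z_minus, left.p_minus, left.g_minus,
        )
    else:
        tree.z_minus, tree.p_minus, tree.g_minus = (
            left.z_minus, left.p_minus, left.g_minus,
        )
        tree.z_plus, tree.p_plus, tree.g_plus = left.z_plus, left.p_plus, left.g_plus
    if left.s:
        if v == -1:
            right = _build_tree(
                logp_grad, left.z_minus, left.p_minus, left.g_minus,
                logu, v, j - 1, step, metric, h0, rng,
            )
            tree.z_minus, tree.p_minus, tree.g_minus = (
                right.z_minus, right.p_minus, right.g_minus,
            )
        else:
            right = _build_tree(
                logp_grad, left.z_plus, left.p_plus, left.g_plus,
                logu, v, j - 1, step, metric, h0, rng,
            )
            tree.z_plus, tree.p_plus, tree.g_plus = (
                right.z_plus, right.p_plus, right.g_plus,
            )
        total = left.n + right.n
        if total > 0 and rng.random() < right.n / total:
            tree.z_prop, tree.lp_prop = right.z_prop, right.lp_prop
        tree.alpha = left.alpha + right.alpha
        tree.n_alpha = left.n_alpha + right.n_alpha
        tree.div = left.div or right.div
        tree.n = total
        tree.s = int(
            right.s
            and _no_uturn(tree.z_minus, tree.z_plus, tree.p_minus, tree.p_plus, metric)
        )
    return tree


def nuts_transition(
    logp_grad,
    z: np.ndarray,
    lp: float,
    grad: np.ndarray,
    step: float,
    metric,
    rng: np.random.Generator,
    max_treedepth: int = 8,
):
    """One NUTS update from (z, lp, grad); returns
    ``(z, lp, grad, accept_stat, diverged)``."""
    metric = _as_metric(metric)
    p0 = metric.sample_momentum(rng)
    h0 = lp - 0.5 * np.dot(p0, metric.velocity(p0))
    logu = h0 + np.log(rng.random())
    z_minus = z_plus = z
    p_minus = p_plus = p0
    g_minus = g_plus = grad
    z_new, lp_new = z, lp
    j, n, s = 0, 1, 1
    diverged = False
    tree = None
    while s and j < max_treedepth:
        v = -1 if rng.random() < 0.5 else 1
        if v == -1:
            tree = _build_tree(
                logp_grad, z_minus, p_minus, g_minus,
                logu, v, j, step, metric, h0, rng,
            )
            z_minus, p_minus, g_minus = tree.z_minus, tree.p_minus, tree.g_minus
        else:
            tree = _build_tree(
                logp_grad, z_plus, p_plus, g_plus,
                logu, v, j, step, metric, h0, rng,
            )
            z_plus, p_plus, g_plus = tree.z_plus, tree.p_plus, tree.g_plus
        if tree.s and tree.n > 0 and rng.random() < min(1.0, tree.n / n):
            z_new, lp_new = tree.z_prop, tree.lp_prop
        n += tree.n
        if tree.div:
            diverged = True
        s = tree.s and _no_uturn(z_minus, z_plus, p_minus, p_plus, metric)
        j += 1
    accept_stat = tree.alpha / max(tree.n_alpha, 1) if tree is not None else 0.0
    if z_new is not z:
        _, grad = logp_grad(z_new)
    return z_new, lp_new, grad, accept_stat, diverged


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_treedepth: int = 8,
    init_step: float = 0.1,
    inv_mass0: np.ndarray | None = None,
    adapt_mass: bool = True,
) -> ChainResult:
    """Run one NUTS chain; returns kept (post-warmup) draws.

    ``inv_mass0`` may be a vector (diagonal metric) or a DiagMetric /
    DenseMetric instance.
    """
    z = np.asarray(z0, dtype=float).copy()
    dim = z.size
    metric = _as_metric(np.ones(dim) if inv_mass0 is None else inv_mass0)
    step = init_step
    adapter = _DualAveraging(init_step, target_accept)

    # Stan-style warmup schedule: an initial step-size-only buffer, then
    # doubling windows each ending in a metric re-estimate, then a final
    # step-size-only buffer.
    init_buffer = min(75, max(10, int(0.15 * n_warmup)))
    term_buffer = min(50, max(10, int(0.1 * n_warmup)))
    window_ends = []
    if adapt_mass and n_warmup >= init_buffer + term_buffer + 20:
        w = 25
        pos = init_buffer
        while pos + w < n_warmup - term_buffer:
            nxt = pos + w
            if nxt + 2 * w >= n_warmup - term_buffer:
                nxt = n_warmup - term_buffer
            window_ends.append(nxt)
            pos = nxt
            w *= 2
    buffer: list[np.ndarray] = []

    lp, grad = logp_grad(z)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    draws = np.empty((n_draws, dim))
    divergences = 0
    alpha_hist = []

    for it in range(n_warmup + n_draws):
        z, lp, grad, accept_stat, diverged = nuts_transition(
            logp_grad, z, lp, grad, step, metric, rng, max_treedepth
        )
        if diverged and it >= n_warmup:
            divergences += 1
        if it < n_warmup:
            step = adapter.update(accept_stat)
            if window_ends and it >= init_buffer:
                buffer.append(z.copy())
                if it == window_ends[0] - 1:
                    if len(buffer) >= 10:
                        var = np.var(np.asarray(buffer), axis=0)
                        m = len(buffer)
                        var = m / (m + 5.0) * var + 5.0 / (m + 5.0) * 1e-3
                        metric = DiagMetric(np.maximum(var, 1e-8))
                        adapter.restart(float(np.exp(adapter.log_step_bar)))
                    buffer = []
                    window_ends.pop(0)
            if it == n_warmup - 1:
                step = float(np.exp(adapter.log_step_bar))
        else:
            draws[it - n_warmup] = z
            alpha_hist.append(accept_stat)

    return ChainResult(
        draws=draws,
        accept_rate=float(np.mean(alpha_hist)) if alpha_hist else 0.0,
        divergences=divergences,
        step_size=step,
        inv_mass=metric.inv_mass,
    )
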