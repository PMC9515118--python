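"""Hierarchical Bayesian estimation of the risk-preference model.

Model structure (per weighting family):

* group-level means carry weakly informative priors on each parameter's
  own scale — N(0,5) for the risk-coefficient baseline on (0,5), N(1,3)
  for weighting curvature on (0,6), N(0,10) for consistency on (0,inf);
  the six stimulation-shift means are uniform over their intervals
  (a matched standard normal through the scaled-Phi transform);
* group-level standard deviations are LogNormal(0, 3);
* subject-level parameters follow a normal hierarchy on their natural
  scale, truncated to the admissible interval: theta_i ~ N(m, sigma)
  restricted to the bounds.  Sampling works on an unconstrained space
  via the exp transform for positive-only parameters and a scaled Phi
  transform for two-sided bounds, with the change-of-variables Jacobians
  applied;
* the likelihood is Bernoulli over observed choices with the Luce-rule
  probability of the rank-dependent-utility model.

The posterior is explored with Hamiltonian Monte Carlo using analytic
gradients of the joint log density.  Reported group-level locations are
the constrained transforms of the group means (the scale on which credible
intervals and Bayes factors are stated).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from .hmc import DenseMetric, _DualAveraging, nuts_transition, sample_chain, sample_nuts
from .model import FAMILIES, PreferenceParams, choice_logit_arrays
from .params import CONDITIONS, ParamBlock, blocks_for_family
from .transforms import constrain, unconstrain

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "FULL_CONFIG",
    "TEST_CONFIG",
    "PosteriorDraws",
    "Diagnostics",
    "prepare_trials",
    "log_likelihood",
    "log_density",
    "fit",
    "diagnostics",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SIGMA_LOG_SD = 3.0  # LogNormal(0, 3) prior on group SDs


@dataclass(frozen=True)
class ModelSpec:
    """One model specification: weighting family and outcome domain(s)."""

    family: str = "kahneman_tversky"
    domain: str = "gain"  # "gain", "loss" or "both"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.domain not in ("gain", "loss", "both"):
            raise ValueError(f"domain must be gain/loss/both, got {self.domain!r}")

    @property
    def blocks(self) -> tuple[ParamBlock, ...]:
        return blocks_for_family(self.family)


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 8
    warmup: int = 1000
    draws: int = 4000
    target_accept: float = 0.85
    algorithm: str = "gibbs_nuts"  # "gibbs_nuts", "nuts" or "hmc"
    max_treedepth: int = 8       # NUTS doubling limit
    max_leapfrog: int = 32       # static-HMC trajectory cap
    init_step: float = 0.1

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws


#: Full-scale sampling configuration: 8 chains x (1000 warmup + 4000 kept).
FULL_CONFIG = MCMCConfig()
#: Reduced configuration so a full fit runs in well under a minute.
TEST_CONFIG = MCMCConfig(
    chains=2, warmup=200, draws=400, target_accept=0.9, max_treedepth=6
)


# ---------------------------------------------------------------------------
# Trial preparation
# ---------------------------------------------------------------------------

@dataclass
class TrialArrays:
    """Column-extracted trial table ready for vectorized likelihoods."""

    subjects: list            # original subject labels, index order
    subject_idx: np.ndarray   # (T,) int
    is_right: np.ndarray      # (T,) float 0/1
    is_left: np.ndarray       # (T,) float 0/1
    sign: np.ndarray          # (T,) +1 gain / -1 loss
    xa_best: np.ndarray
    xa_worst: np.ndarray
    xb_best: np.ndarray
    xb_worst: np.ndarray
    p_best: np.ndarray
    y: np.ndarray             # (T,) 1 if option A chosen

    @property
    def n_trials(self) -> int:
        return self.y.size

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def prepare_trials(table: pd.DataFrame, domain: str = "gain") -> TrialArrays:
    """Validate and columnize a long-format trial table.

    ``domain`` restricts to gain or loss rows ("both" keeps all).
    """
    required = {
        "subject", "condition", "domain", "xA_best", "xA_worst",
        "xB_best", "xB_worst", "p_best", "choice",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    if domain != "both":
        table = table[table["domain"] == domain]
    if len(table) == 0:
        raise ValueError("no trials left after domain filtering")
    bad = ~table["condition"].isin(CONDITIONS)
    if bad.any():
        raise ValueError(
            f"unknown condition labels: {sorted(table.loc[bad, 'condition'].unique())}"
        )
    if ((table["p_best"] < 0) | (table["p_best"] > 1)).any():
        raise ValueError("p_best outside [0, 1]")
    subjects = sorted(table["subject"].unique().tolist())
    sub_map = {s: i for i, s in enumerate(subjects)}
    return TrialArrays(
        subjects=subjects,
        subject_idx=table["subject"].map(sub_map).to_numpy(dtype=int),
        is_right=(table["condition"] == "right").to_numpy(dtype=float),
        is_left=(table["condition"] == "left").to_numpy(dtype=float),
        sign=np.where(table["domain"].to_numpy() == "gain", 1.0, -1.0),
        xa_best=table["xA_best"].to_numpy(dtype=float),
        xa_worst=table["xA_worst"].to_numpy(dtype=float),
        xb_best=table["xB_best"].to_numpy(dtype=float),
        xb_worst=table["xB_worst"].to_numpy(dtype=float),
        p_best=table["p_best"].to_numpy(dtype=float),
        y=(table["choice"] == "A").to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _compose_trialwise(theta: Mapping[str, np.ndarray], prep: TrialArrays, family: str):
    """Per-trial effective (r, gamma, tau) from per-subject block values."""
    s = prep.subject_idx
    r = theta["r0"][s]
    tau = theta["tau0"][s]
    r = r + theta["dr_right"][s] * prep.is_right + theta["dr_left"][s] * prep.is_left
    tau = (
        tau
        + theta["dtau_right"][s] * prep.is_right
        + theta["dtau_left"][s] * prep.is_left
    )
    if family == "linear":
        gamma = np.ones_like(r)
    else:
        gamma = (
            theta["gamma0"][s]
            + theta["dgamma_right"][s] * prep.is_right
            + theta["dgamma_left"][s] * prep.is_left
        )
    return r, gamma, tau


class _LikelihoodKernel:
    """Per-trial likelihood with trial-constant terms precomputed.

    Caches sign(x), log|x|, log p and log(1-p) so each density evaluation
    costs only the parameter-dependent exponentials.  Numerically identical
    to :func:`riskpref.model.choice_logit_arrays`.
    """

    def __init__(self, prep: TrialArrays, family: str):
        self.family = family
        self.prep = prep
        xs = (prep.xa_best, prep.xa_worst, prep.xb_best, prep.xb_worst)
        self.sgn = [np.sign(x) for x in xs]
        self.lx = [
            np.where(x == 0.0, 0.0, np.log(np.abs(np.where(x == 0.0, 1.0, x))))
            for x in xs
        ]
        self.zero = [x == 0.0 for x in xs]
        p = prep.p_best
        self.interior = (p > 0.0) & (p < 1.0)
        pc = np.clip(p, 1e-12, 1.0 - 1e-12)
        self.lp = np.log(pc)
        self.lq = np.log1p(-pc)
        self.nlp = -self.lp                  # for Prelec
        with np.errstate(divide="ignore"):
            self.log_nlp = np.where(self.interior, np.log(self.nlp), 0.0)

    def weight(self, gamma):
        """(w, dw/dgamma) per trial for the kernel's family."""
        p = self.prep.p_best
        if self.family == "linear":
            return p, np.zeros_like(p)
        if self.family == "kahneman_tversky":
            pg = np.exp(gamma * self.lp)
            qg = np.exp(gamma * self.lq)
            s = pg + qg
            ls = np.log(s)
            w = np.exp(gamma * self.lp - ls / gamma)
            dw = w * (self.lp + ls / gamma**2 - (pg * self.lp + qg * self.lq) / (gamma * s))
        else:
            t = np.exp(gamma * self.log_nlp)  # (-ln p)**gamma in the interior
            w = np.exp(-t)
            dw = -w * t * self.log_nlp
        w = np.where(self.interior, w, p)
        dw = np.where(self.interior, dw, 0.0)
        return w, dw

    def __call__(self, r, gamma, tau):
        """(pointwise ll, dll/dz, dz/dr, dz/dgamma, dz/dtau) per trial."""
        prep = self.prep
        w, dw = self.weight(gamma)
        u, du = [], []
        for sgn, lx, zero in zip(self.sgn, self.lx, self.zero):
            ui = sgn * np.exp(r * lx)
            u.append(np.where(zero, 0.0, ui))
            du.append(np.where(zero, 0.0, ui * lx))
        u1a, u2a, u1b, u2b = u
        du1a, du2a, du1b, du2b = du
        eu_a = w * u1a + (1.0 - w) * u2a
        eu_b = w * u1b + (1.0 - w) * u2b
        if np.any(eu_a == 0.0) or np.any(eu_b == 0.0) or np.any(
            (eu_a > 0) != (eu_b > 0)
        ):
            raise FloatingPointError("degenerate expected-utility ratio")
        big_l = np.log(np.abs(eu_a)) - np.log(np.abs(eu_b))
        dl_dr = (w * du1a + (1.0 - w) * du2a) / eu_a - (
            w * du1b + (1.0 - w) * du2b
        ) / eu_b
        dl_dg = dw * ((u1a - u2a) / eu_a - (u1b - u2b) / eu_b)
        z = prep.sign * tau / r * big_l
        dz_dr = prep.sign * tau * (dl_dr / r - big_l / r**2)
        dz_dg = prep.sign * tau / r * dl_dg
        dz_dt = prep.sign * big_l / r
        signed = np.where(prep.y > 0.5, z, -z)
        ll = -np.logaddexp(0.0, -signed)
        g = prep.y - expit(z)  # dll/dz
        return ll, g, dz_dr, dz_dg, dz_dt


def _pointwise_loglik(r, gamma, tau, prep: TrialArrays, family: str):
    """(pointwise ll, dll/dz_logit, dz/dr, dz/dgamma, dz/dtau) per trial."""
    kernel = getattr(prep, "_kernel_cache", None)
    if kernel is None or kernel.family != family:
        kernel = _LikelihoodKernel(prep, family)
        prep._kernel_cache = kernel
    return kernel(r, gamma, tau)


def _fast_kernel(prep: TrialArrays, family: str):
    """Cached fused-loop kernel for the sampler's hot path."""
    from ._fastkernel import FastKernel

    kernel = getattr(prep, "_fast_cache", None)
    if kernel is None or kernel.family != family:
        kernel = FastKernel(prep, family)
        prep._fast_cache = kernel
    return kernel


class _SpecCache:
    """Per-spec constants for the sampler hot path: vectorized transform
    parameters, prior arrays, and block-row lookups."""

    def __init__(self, spec: "ModelSpec"):
        blocks = spec.blocks
        self.blocks = blocks
        self.exp_rows = np.array([not b.bounds.two_sided for b in blocks])
        self.lower = np.array(
            [b.bounds.lower if b.bounds.two_sided else 0.0 for b in blocks]
        )
        self.width = np.array(
            [b.bounds.width if b.bounds.two_sided else 1.0 for b in blocks]
        )
        self.prior_mean = np.array([b.prior_mean for b in blocks])
        self.prior_sd = np.array([b.prior_sd for b in blocks])
        self.natural = np.array([b.prior_scale == "natural" for b in blocks])
        self.row = {b.name: i for i, b in enumerate(blocks)}

    def prior_mu_logp_grad(self, mu_z: np.ndarray):
        """Group-mean prior at the unconstrained point ``mu_z``.

        Baseline blocks carry their stated normal prior on the natural
        scale (evaluated at the transformed location, with the transform's
        log-Jacobian); shift blocks carry it on the latent scale, where
        the matched standard normal implies a uniform interval prior.
        Normalizing constants are dropped.
        """
        lp = 0.0
        grad = np.zeros_like(mu_z)
        nat = self.natural
        lat = ~nat
        if lat.any():
            d = (mu_z[lat] - self.prior_mean[lat]) / self.prior_sd[lat]
            lp -= 0.5 * float(np.sum(d * d))
            grad[lat] = -d / self.prior_sd[lat]
        if nat.any():
            from scipy.special import ndtr

            z = mu_z[nat]
            exp_rows = self.exp_rows[nat]
            width = self.width[nat]
            lower = self.lower[nat]
            phi = np.exp(-0.5 * z**2 - _LOG_SQRT_2PI)
            loc = np.where(exp_rows, np.exp(z), lower + width * ndtr(z))
            jac = np.where(exp_rows, np.exp(z), width * phi)
            dlogjac = np.where(exp_rows, 1.0, -z)
            d = (loc - self.prior_mean[nat]) / self.prior_sd[nat]
            lp += float(np.sum(-0.5 * d * d + np.log(jac)))
            grad[nat] = -d / self.prior_sd[nat] * jac + dlogjac
        return lp, grad

    def constrain_all(self, z_sub: np.ndarray):
        """theta and d(theta)/dz for the whole (B, S) matrix at once."""
        from scipy.special import ndtr

        phi = np.exp(-0.5 * z_sub**2 - _LOG_SQRT_2PI)
        theta = self.lower[:, None] + self.width[:, None] * ndtr(z_sub)
        jac = self.width[:, None] * phi
        if self.exp_rows.any():
            e = np.exp(z_sub[self.exp_rows])
            theta[self.exp_rows] = e
            jac[self.exp_rows] = e
        return theta, jac

    def dlog_jac(self, z_sub: np.ndarray) -> np.ndarray:
        """d/dz of log T'(z), rowwise (-z for Phi rows, 1 for exp rows)."""
        return np.where(self.exp_rows[:, None], 1.0, -z_sub)

    def trunc_normalizer(self, m: np.ndarray, sigma: np.ndarray):
        """Per-block truncation mass Z = P(theta in bounds | N(m, sigma))
        with d(log Z)/dm and d(log Z)/d(log sigma)."""
        from scipy.special import ndtr

        lo = np.array([b.bounds.lower for b in self.blocks])
        hi = np.array(
            [b.bounds.upper if b.bounds.two_sided else np.inf for b in self.blocks]
        )
        c_lo = (lo - m) / sigma
        with np.errstate(invalid="ignore"):
            c_hi = np.where(np.isinf(hi), np.inf, (hi - m) / sigma)
        phi_lo = np.exp(-0.5 * c_lo**2 - _LOG_SQRT_2PI)
        c_hi_f = np.where(np.isinf(c_hi), 40.0, c_hi)  # finite stand-in
        phi_hi = np.where(
            np.isinf(c_hi), 0.0, np.exp(-0.5 * np.minimum(c_hi_f, 40.0) ** 2 - _LOG_SQRT_2PI)
        )
        z_mass = np.where(np.isinf(c_hi), 1.0 - ndtr(c_lo), ndtr(c_hi_f) - ndtr(c_lo))
        z_mass = np.maximum(z_mass, 1e-300)
        dlogz_dm = (phi_lo - phi_hi) / (sigma * z_mass)
        dlogz_dls = (c_lo * phi_lo - c_hi_f * phi_hi) / z_mass
        return np.log(z_mass), dlogz_dm, dlogz_dls

    def compose_cells(self, theta: np.ndarray, family: str):
        """(S, 3) effective parameters from the (B, S) block matrix."""
        row = self.row
        n_s = theta.shape[1]
        out = []
        for target in ("r", "gamma", "tau"):
            if target == "gamma" and family == "linear":
                out.append(np.ones((n_s, 3)))
                continue
            cells = np.empty((n_s, 3))
            base = theta[row[f"{target}0"]]
            cells[:, 0] = base
            cells[:, 1] = base + theta[row[f"d{target}_right"]] if f"d{target}_right" in row else base
            cells[:, 2] = base + theta[row[f"d{target}_left"]] if f"d{target}_left" in row else base
            out.append(cells)
        return out


_SPEC_CACHES: dict = {}


def _spec_cache(spec: "ModelSpec") -> _SpecCache:
    key = (spec.family,)
    cache = _SPEC_CACHES.get(key)
    if cache is None:
        cache = _SPEC_CACHES[key] = _SpecCache(spec)
    return cache


def _compose_cellwise(theta_map: Mapping[str, np.ndarray], n_s: int, family: str):
    """(n_s, 3) effective parameters per subject-condition cell, condition
    order (sham, right, left)."""
    out = []
    for target in ("r", "gamma", "tau"):
        if target == "gamma" and family == "linear":
            out.append(np.ones((n_s, 3)))
            continue
        base = theta_map[f"{target}0"]
        cells = np.empty((n_s, 3))
        cells[:, 0] = base
        cells[:, 1] = base + theta_map[f"d{target}_right"]
        cells[:, 2] = base + theta_map[f"d{target}_left"]
        out.append(cells)
    return out  # r_cells, gamma_cells, tau_cells


def _gtheta_from_cell_acc(acc, blocks, n_s: int) -> np.ndarray:
    """Map per-cell gradient accumulators back to the parameter blocks."""
    acc_r, acc_g, acc_t = (a.reshape(n_s, 3) for a in acc)
    by_target = {"r": acc_r, "gamma": acc_g, "tau": acc_t}
    g_theta = np.empty((len(blocks), n_s))
    for b, block in enumerate(blocks):
        a = by_target[block.target]
        if block.condition == "baseline":
            g_theta[b] = a.sum(axis=1)
        elif block.condition == "right":
            g_theta[b] = a[:, 1]
        else:
            g_theta[b] = a[:, 2]
    return g_theta


def log_likelihood(
    table: pd.DataFrame,
    params: Mapping[tuple, PreferenceParams],
    family: str = "kahneman_tversky",
    domain: str = "gain",
) -> tuple[float, np.ndarray]:
    """Bernoulli log likelihood of observed choices under fixed parameters.

    ``params`` maps (subject, condition) to the effective
    :class:`PreferenceParams` of that cell.  Returns the total and the
    per-trial pointwise vector (retained for information criteria).
    """
    prep = prepare_trials(table, domain)
    conds = ("sham", "right", "left")
    r = np.empty(prep.n_trials)
    gamma = np.empty(prep.n_trials)
    tau = np.empty(prep.n_trials)
    cond_code = (prep.is_right + 2 * prep.is_left).astype(int)  # 0/1/2
    for i in range(prep.n_trials):
        key = (prep.subjects[prep.subject_idx[i]], conds[cond_code[i]])
        if key not in params:
            raise KeyError(f"no parameters for subject-condition {key}")
        p = params[key]
        r[i], gamma[i], tau[i] = p.r, p.gamma, p.tau
    ll, *_ = _pointwise_loglik(r, gamma, tau, prep, family)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite pointwise log likelihood")
    return float(ll.sum()), ll


# ---------------------------------------------------------------------------
# Joint log density with analytic gradient
# ---------------------------------------------------------------------------

def _unpack(zvec: np.ndarray, n_blocks: int, n_subjects: int):
    mu = zvec[:n_blocks]
    log_sigma = zvec[n_blocks: 2 * n_blocks]
    eta = zvec[2 * n_blocks:].reshape(n_blocks, n_subjects)
    return mu, log_sigma, eta


def _logdensity_and_grad(
    zvec: np.ndarray, prep: TrialArrays, spec: ModelSpec
) -> tuple[float, np.ndarray]:
    cache = _spec_cache(spec)
    blocks = cache.blocks
    n_b, n_s = len(blocks), prep.n_subjects
    mu, log_sigma, u = _unpack(zvec, n_b, n_s)
    sigma = np.exp(log_sigma)

    # ---- group-level priors (baselines on the natural scale, shifts
    # implied-uniform; see _SpecCache.prior_mu_logp_grad)
    prior_lp, g_mu_z = cache.prior_mu_logp_grad(mu)
    lp = float(
        prior_lp
        # LogNormal(0,3) on sigma == N(0,3) on log sigma (exact, incl. Jacobian)
        - 0.5 * np.sum((log_sigma / _SIGMA_LOG_SD) ** 2)
        - n_b * (math.log(_SIGMA_LOG_SD) + _LOG_SQRT_2PI)
    )
    g_log_sigma = -log_sigma / _SIGMA_LOG_SD**2

    # ---- truncated-normal hierarchy on the natural scale
    z_sub = u                                            # (B, S)
    m_loc, jac_mu = cache.constrain_all(mu[:, None])
    m_loc, jac_mu = m_loc[:, 0], jac_mu[:, 0]
    theta, jac = cache.constrain_all(z_sub)
    resid = (theta - m_loc[:, None]) / sigma[:, None]
    log_z_mass, dlogz_dm, dlogz_dls = cache.trunc_normalizer(m_loc, sigma)
    lp += float(
        -0.5 * np.sum(resid**2)
        - n_s * np.sum(log_sigma)
        - n_s * np.sum(log_z_mass)
        + np.sum(np.log(jac))
        - n_b * n_s * _LOG_SQRT_2PI
    )
    g_u = -resid / sigma[:, None] * jac + cache.dlog_jac(z_sub)
    g_mu_z += (resid.sum(axis=1) / sigma - n_s * dlogz_dm) * jac_mu
    g_log_sigma += np.sum(resid**2 - 1.0, axis=1) - n_s * dlogz_dls

    r_c, g_c, t_c = cache.compose_cells(theta, spec.family)
    if min(r_c.min(), g_c.min(), t_c.min()) <= 0.0:
        return -np.inf, np.zeros_like(zvec)

    kern = _fast_kernel(prep, spec.family)
    ok, ll_sum, _, acc = kern(r_c, g_c, t_c)
    if not ok or not np.isfinite(ll_sum):
        return -np.inf, np.zeros_like(zvec)
    lp += ll_sum

    g_theta = _gtheta_from_cell_acc(acc, blocks, n_s)
    g_u += g_theta * jac

    grad = np.concatenate([g_mu_z, g_log_sigma, g_u.ravel()])
    return lp, grad


def log_density(zvec: np.ndarray, data: pd.DataFrame | TrialArrays, spec: ModelSpec) -> float:
    """Joint unnormalized log posterior density at an unconstrained point.

    The vector layout is ``[group means | group log-SDs | subject etas]``
    with one entry (or row of etas) per active parameter block.
    """
    prep = data if isinstance(data, TrialArrays) else prepare_trials(data, spec.domain)
    lp, _ = _logdensity_and_grad(np.asarray(zvec, dtype=float), prep, spec)
    return lp


def log_density_dim(spec: ModelSpec, n_subjects: int) -> int:
    n_b = len(spec.blocks)
    return 2 * n_b + n_b * n_subjects


# ---------------------------------------------------------------------------
# Posterior container, fitting, diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Constrained-scale posterior draws with pointwise log likelihood.

    ``array`` has shape (chains, draws, n_params); group-level locations
    (``mu_*``) are the interval transforms of the group means, ``sigma_*``
    are the latent-scale group SDs, and ``<block>[label]`` are per-subject
    parameters.
    """

    names: list[str]
    array: np.ndarray
    loglik: np.ndarray  # (chains, draws, n_trials)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[1]

    def get(self, name: str, flat: bool = True) -> np.ndarray:
        x = self.array[:, :, self._index[name]]
        return x.reshape(-1) if flat else x

    def group_names(self) -> list[str]:
        return [n for n in self.names if n.startswith(("mu_", "sigma_"))]

    def pooled_loglik(self) -> np.ndarray:
        """Pointwise log likelihood flattened to (total draws, trials)."""
        c, d, t = self.loglik.shape
        return self.loglik.reshape(c * d, t)

    def to_frame(self) -> pd.DataFrame:
        c, d, p = self.array.shape
        chain = np.repeat(np.arange(c), d * p)
        draw = np.tile(np.repeat(np.arange(d), p), c)
        param = np.tile(np.asarray(self.names, dtype=object), c * d)
        return pd.DataFrame(
            {"chain": chain, "draw": draw, "parameter": param,
             "value": self.array.reshape(-1)}
        )

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "draws.csv", index=False)
        c, d, t = self.loglik.shape
        np.savetxt(directory / "pointwise_loglik.txt", self.loglik.reshape(c * d, t))
        with open(directory / "meta.json", "w") as fh:
            json.dump(
                {**self.meta, "chains": c, "draws": d, "n_trials": t,
                 "names": self.names},
                fh, indent=2, default=str,
            )

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        directory = Path(directory)
        with open(directory / "meta.json") as fh:
            meta = json.load(fh)
        names = meta.pop("names")
        c, d, t = meta.pop("chains"), meta.pop("draws"), meta.pop("n_trials")
        frame = pd.read_csv(directory / "draws.csv")
        array = np.empty((c, d, len(names)))
        idx = {n: i for i, n in enumerate(names)}
        array[frame["chain"], frame["draw"],
              frame["parameter"].map(idx)] = frame["value"]
        loglik = np.loadtxt(directory / "pointwise_loglik.txt", ndmin=2)
        return cls(names=names, array=array, loglik=loglik.reshape(c, d, t), meta=meta)


@dataclass
class Diagnostics:
    rhat: dict
    ess: dict

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess(self) -> float:
        return min(self.ess.values())


# ---------------------------------------------------------------------------
# Blocked Gibbs / NUTS hybrid
#
# The hierarchy is conditionally conjugate on the unconstrained scale:
# given the subject values z_bi, each group mean has a closed-form normal
# conditional and each group SD a one-dimensional log-concave conditional.
# Sampling them by Gibbs removes the slow-mixing group coordinates from
# the Hamiltonian dynamics; NUTS then only has to explore the
# subject-level block, which is conditionally independent across subjects.
# ---------------------------------------------------------------------------

def _subject_cond_logp_grad(
    x: np.ndarray,
    sigma: np.ndarray,
    prep: TrialArrays,
    spec: ModelSpec,
    barrier: float = 0.0,
):
    """Conditional log density of (group means, subject values) given the
    group SDs (constants dropped), with its gradient.

    Layout of ``x``: [mu (B) | z_sub (B*S)].  ``barrier`` adds a mild
    log-barrier on the composed per-cell parameters (warm-start use only):
    near the support wall the density stays finite but its gradient
    explodes, and an optimizer parked there produces a useless curvature
    metric.
    """
    cache = _spec_cache(spec)
    blocks = cache.blocks
    n_b, n_s = len(blocks), prep.n_subjects
    mu = x[:n_b]
    z_sub = x[n_b:].reshape(n_b, n_s)
    theta, jac = cache.constrain_all(z_sub)
    r_c, g_c, t_c = cache.compose_cells(theta, spec.family)
    if min(r_c.min(), g_c.min(), t_c.min()) <= 0.0:
        return -np.inf, np.zeros_like(x)
    kern = _fast_kernel(prep, spec.family)
    ok, ll_sum, _, acc = kern(r_c, g_c, t_c)
    if not ok or not np.isfinite(ll_sum):
        return -np.inf, np.zeros_like(x)
    prior_lp, g_mu_z = cache.prior_mu_logp_grad(mu)
    m_loc, jac_mu = cache.constrain_all(mu[:, None])
    m_loc, jac_mu = m_loc[:, 0], jac_mu[:, 0]
    resid = (theta - m_loc[:, None]) / sigma[:, None]
    log_z_mass, dlogz_dm, _ = cache.trunc_normalizer(m_loc, sigma)
    lp = (
        ll_sum + prior_lp
        - 0.5 * float(np.sum(resid**2))
        - n_s * float(np.sum(log_z_mass))
        + float(np.sum(np.log(jac)))
    )

    g_theta = _gtheta_from_cell_acc(acc, blocks, n_s)
    if barrier > 0.0:
        lp += barrier * float(np.sum(np.log(r_c)) + np.sum(np.log(g_c))
                              + np.sum(np.log(t_c)))
        # accumulate d(log composed)/d(theta) through the same cell mapping
        bar = (
            (barrier / r_c).reshape(-1),
            (np.zeros_like(g_c) if spec.family == "linear" else barrier / g_c).reshape(-1),
            (barrier / t_c).reshape(-1),
        )
        g_theta = g_theta + _gtheta_from_cell_acc(bar, blocks, n_s)
    g_mu = g_mu_z + (resid.sum(axis=1) / sigma - n_s * dlogz_dm) * jac_mu
    g_sub = (g_theta - resid / sigma[:, None]) * jac + cache.dlog_jac(z_sub)
    return lp, np.concatenate([g_mu, g_sub.ravel()])


def _slice_log_sigma(
    u0: float, m_nat: float, theta_row: np.ndarray, bounds,
    rng: np.random.Generator, width: float = 1.0, max_steps: int = 50,
) -> float:
    """Slice sample log sigma_b from its 1-D conditional under the
    truncated-normal hierarchy (prior LogNormal(0, 3))."""
    from scipy.special import ndtr

    n = theta_row.size
    ss = float(np.sum((theta_row - m_nat) ** 2))
    lo = bounds.lower
    hi = bounds.upper if bounds.two_sided else math.inf

    def logf(u: float) -> float:
        sigma = math.exp(u)
        z_lo = ndtr((lo - m_nat) / sigma)
        z_hi = 1.0 if math.isinf(hi) else ndtr((hi - m_nat) / sigma)
        z_mass = max(z_hi - z_lo, 1e-300)
        return (
            -u * u / (2.0 * _SIGMA_LOG_SD**2)
            - n * u
            - 0.5 * ss * math.exp(-2.0 * u)
            - n * math.log(z_mass)
        )

    y = logf(u0) + math.log(rng.random())
    left = u0 - width * rng.random()
    right = left + width
    for _ in range(max_steps):
        if logf(left) <= y:
            break
        left -= width
    for _ in range(max_steps):
        if logf(right) <= y:
            break
        right += width
    while True:
        u1 = left + rng.random() * (right - left)
        if logf(u1) >= y:
            return u1
        if u1 < u0:
            left = u1
        else:
            right = u1


def _dense_metric_at(
    x: np.ndarray, sigma: np.ndarray, prep: TrialArrays, spec: ModelSpec
) -> DenseMetric:
    """Dense metric from the conditional Hessian at (x, sigma), by central
    differences of the analytic gradient."""
    h = 1e-4
    dim = x.size
    hess = np.empty((dim, dim))
    for i in range(dim):
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        hess[i] = -(
            _subject_cond_logp_grad(xp, sigma, prep, spec)[1]
            - _subject_cond_logp_grad(xm, sigma, prep, spec)[1]
        ) / (2 * h)
    return DenseMetric(hess)


def _gibbs_nuts_chain(
    prep: TrialArrays,
    spec: ModelSpec,
    z0_full: np.ndarray,
    metric: DenseMetric,
    config: "MCMCConfig",
    rng: np.random.Generator,
):
    """One chain of the blocked sampler; returns draws in the full layout
    [group means | group log-SDs | subject values] plus sampler stats.

    The metric stays fixed (mode curvature); only the step size adapts.
    """
    blocks = spec.blocks
    n_b, n_s = len(blocks), prep.n_subjects
    log_sigma = z0_full[n_b: 2 * n_b].copy()
    # Hamiltonian block: [group means | subject values]
    x = np.concatenate([z0_full[:n_b], z0_full[2 * n_b:]])

    step = config.init_step
    adapter = _DualAveraging(config.init_step, config.target_accept)
    n_warmup, n_draws = config.warmup, config.draws

    draws = np.empty((n_draws, z0_full.size))
    divergences = 0
    alpha_hist = []
    best_lp, best_x, best_sigma = -np.inf, x.copy(), np.exp(log_sigma)
    recent: list[float] = []  # trailing warmup acceptance, for recovery resets

    for it in range(n_warmup + n_draws):
        sigma = np.exp(log_sigma)

        def cond(xv):
            return _subject_cond_logp_grad(xv, sigma, prep, spec)

        lp, grad = cond(x)
        if not np.isfinite(lp):
            raise FloatingPointError("Hamiltonian block left the support")
        if it < n_warmup and lp > best_lp:
            best_lp, best_x, best_sigma = lp, x.copy(), sigma.copy()
        x, _, _, accept_stat, diverged = nuts_transition(
            cond, x, lp, grad, step, metric, rng, config.max_treedepth
        )
        mu = x[:n_b]
        z_sub = x[n_b:].reshape(n_b, n_s)
        cache = _spec_cache(spec)
        theta, _ = cache.constrain_all(z_sub)
        m_loc, _ = cache.constrain_all(mu[:, None])

        for b, block in enumerate(blocks):
            log_sigma[b] = _slice_log_sigma(
                log_sigma[b], float(m_loc[b, 0]), theta[b], block.bounds, rng
            )

        if diverged and it >= n_warmup:
            divergences += 1
        if it < n_warmup:
            step = float(np.clip(adapter.update(accept_stat), 1e-4, 2.0))
            if it == int(0.7 * n_warmup):
                # refresh the curvature metric at the best (highest-density)
                # warmup state — the conditional Hessian moves with the
                # group SDs, and the current state may sit in a divergent
                # excursion
                metric = _dense_metric_at(best_x, best_sigma, prep, spec)
                adapter.restart(float(np.exp(adapter.log_step_bar)))
            if it == n_warmup - 1:
                step = float(np.exp(adapter.log_step_bar))
                if best_lp - lp > 50.0:
                    # the chain ended warmup stranded far below the best
                    # density it visited; sample from there instead
                    x = best_x.copy()
                    log_sigma = np.log(best_sigma)
        else:
            k = it - n_warmup
            draws[k, :n_b] = x[:n_b]
            draws[k, n_b: 2 * n_b] = log_sigma
            draws[k, 2 * n_b:] = x[n_b:]
            alpha_hist.append(accept_stat)

    accept = float(np.mean(alpha_hist)) if alpha_hist else 0.0
    return draws, accept, divergences, step


#: Interior starting values for chain initialization (jittered per chain):
#: mildly concave utility, mildly curved weighting, moderate consistency,
#: zero shifts, modest group spreads.
_INIT_TYPICAL = {"r0": 1.0, "gamma0": 1.5, "tau0": 4.0}


def _init_sigma(block: ParamBlock) -> float:
    """Plausible starting group SD: a fifth of the interval width for
    bounded parameters, a couple of units for the open consistency scale."""
    return block.bounds.width / 5.0 if block.bounds.two_sided else 2.0


def initial_point(
    spec: ModelSpec, n_subjects: int, rng: np.random.Generator, jitter: float = 0.1
) -> np.ndarray:
    """Unconstrained starting point inside the support of the composed model."""
    blocks = spec.blocks
    mu0 = np.array(
        [
            unconstrain(_INIT_TYPICAL[b.name], b.bounds)
            if b.condition == "baseline"
            else 0.0
            for b in blocks
        ]
    )
    u0 = np.repeat(mu0, n_subjects)
    log_sig0 = np.log([_init_sigma(b) for b in blocks])
    z0 = np.concatenate([mu0, log_sig0, u0])
    return z0 + jitter * rng.standard_normal(z0.size)


def _warm_start(prep: TrialArrays, spec: ModelSpec):
    """Deterministic warm start: conditional posterior mode and curvature.

    Optimizes (group means, subject values) with the group log-SDs pinned
    at a moderate value — the joint mode is degenerate (density diverges as
    any sigma -> 0 with zero spread), but the conditional mode is well
    defined and sits inside the typical set.  A short plain-gradient
    descent precedes L-BFGS because the optimizer's first line search can
    overshoot into the unsupported region and stall.  Returns the starting
    point and an inverse-mass vector from the diagonal Hessian there.
    """
    from scipy.optimize import minimize

    blocks = spec.blocks
    n_b, n_s = len(blocks), prep.n_subjects
    sig_slice = slice(n_b, 2 * n_b)
    log_sig0 = np.log([_init_sigma(b) for b in blocks])

    def expand(zfree: np.ndarray) -> np.ndarray:
        z = np.empty(zfree.size + n_b)
        z[:n_b] = zfree[:n_b]
        z[sig_slice] = log_sig0
        z[2 * n_b:] = zfree[n_b:]
        return z

    sigma_pin = np.exp(log_sig0)

    def neg(zfree):
        # conditional objective with a mild interior barrier: the raw
        # density is finite right up to the composed-parameter wall, and
        # an optimizer parked at the cliff edge yields a useless metric
        lp, g = _subject_cond_logp_grad(
            np.asarray(zfree, dtype=float), sigma_pin, prep, spec, barrier=1.0
        )
        return -lp, -g

    z0 = initial_point(spec, n_s, np.random.default_rng(0), jitter=0.0)
    x = np.concatenate([z0[:n_b], z0[2 * n_b:]])
    f, g = neg(x)
    scale = 1e-3
    for _ in range(100):
        # backtracking gradient steps: never leave the support
        x_new = x - scale * g
        f_new, g_new = neg(x_new)
        if np.isfinite(f_new) and f_new <= f:
            x, f, g = x_new, f_new, g_new
            scale *= 1.2
        else:
            scale *= 0.5
    opt = minimize(neg, x, jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "gtol": 1e-6})
    if not np.isfinite(opt.fun):
        opt_x = x  # fall back to the last valid gradient-descent point
    else:
        opt_x = opt.x
    z_map = expand(opt_x)

    # full Hessian (negative) by central differences of the gradient
    h = 1e-4
    dim = z_map.size
    hess = np.empty((dim, dim))
    for i in range(dim):
        zp = z_map.copy(); zp[i] += h
        zm = z_map.copy(); zm[i] -= h
        hess[i] = -(
            _logdensity_and_grad(zp, prep, spec)[1]
            - _logdensity_and_grad(zm, prep, spec)[1]
        ) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    return z_map, hess


def fit(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    config: MCMCConfig = TEST_CONFIG,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the hierarchical posterior for one model specification.

    Deterministic for a fixed (data, spec, config, seed).  Divergence
    counts and low acceptance rates are surfaced in ``meta`` (and warned
    about), never silently dropped.
    """
    spec = spec or ModelSpec()
    prep = prepare_trials(data, spec.domain)
    blocks = spec.blocks
    n_b, n_s = len(blocks), prep.n_subjects
    dim = 2 * n_b + n_b * n_s

    def logp_grad(z):
        return _logdensity_and_grad(z, prep, spec)

    z_map, hess = _warm_start(prep, spec)
    diag_curv = np.clip(np.diag(hess), 0.25, None)
    inv_mass0 = 1.0 / diag_curv
    scale0 = np.sqrt(inv_mass0)
    # dense metric over the [group means | subject values] block
    keep = np.r_[np.arange(n_b), np.arange(2 * n_b, z_map.size)]
    dense_metric = DenseMetric(hess[np.ix_(keep, keep)])

    seed_seq = np.random.SeedSequence(seed)
    chain_seeds = seed_seq.spawn(config.chains)
    chain_draws, accept_rates, divergences = [], [], 0
    for c in range(config.chains):
        rng = np.random.default_rng(chain_seeds[c])
        z0 = z_map + 0.5 * scale0 * rng.standard_normal(z_map.size)
        if not np.isfinite(_logdensity_and_grad(z0, prep, spec)[0]):
            z0 = z_map  # fall back to the mode if the jitter left the support
        if config.algorithm == "gibbs_nuts":
            cd, acc, div, _ = _gibbs_nuts_chain(
                prep, spec, z0, dense_metric, config, rng
            )
            chain_draws.append(cd)
            accept_rates.append(acc)
            divergences += div
            continue
        if config.algorithm == "nuts":
            result = sample_nuts(
                logp_grad, z0, config.warmup, config.draws, rng,
                target_accept=config.target_accept,
                max_treedepth=config.max_treedepth,
                init_step=config.init_step,
                inv_mass0=inv_mass0,
            )
        else:
            result = sample_chain(
                logp_grad, z0, config.warmup, config.draws, rng,
                target_accept=config.target_accept,
                max_leapfrog=config.max_leapfrog,
                init_step=config.init_step,
                inv_mass0=inv_mass0,
            )
        chain_draws.append(result.draws)
        accept_rates.append(result.accept_rate)
        divergences += result.divergences
    zs = np.asarray(chain_draws)  # (chains, draws, dim)

    if divergences:
        import warnings

        warnings.warn(
            f"{divergences} divergent transitions after warmup", RuntimeWarning
        )

    # ---- constrain and name the draws
    names: list[str] = []
    cols: list[np.ndarray] = []
    mu = zs[:, :, :n_b]
    log_sigma = zs[:, :, n_b: 2 * n_b]
    u = zs[:, :, 2 * n_b:].reshape(config.chains, config.draws, n_b, n_s)
    sigma = np.exp(log_sigma)
    z_sub = u
    for b, block in enumerate(blocks):
        names.append(f"mu_{block.name}")
        cols.append(np.asarray(constrain(mu[:, :, b], block.bounds)))
    for b, block in enumerate(blocks):
        names.append(f"sigma_{block.name}")
        cols.append(sigma[:, :, b])
    theta_sub = np.empty_like(z_sub)
    for b, block in enumerate(blocks):
        theta_sub[:, :, b, :] = constrain(z_sub[:, :, b, :], block.bounds)
        for j, label in enumerate(prep.subjects):
            names.append(f"{block.name}[{label}]")
            cols.append(theta_sub[:, :, b, j])
    array = np.stack(cols, axis=-1)

    # ---- pointwise log likelihood of every kept draw
    kern = _fast_kernel(prep, spec.family)
    loglik = np.empty((config.chains, config.draws, prep.n_trials))
    for c in range(config.chains):
        for d in range(config.draws):
            theta_map = {block.name: theta_sub[c, d, b] for b, block in enumerate(blocks)}
            for name in ("dr_right", "dr_left", "dtau_right", "dtau_left",
                         "dgamma_right", "dgamma_left"):
                theta_map.setdefault(name, np.zeros(n_s))
            r_c, g_c, t_c = _compose_cellwise(theta_map, n_s, spec.family)
            ok, _, ll, _ = kern(r_c, g_c, t_c)
            if not ok:
                raise FloatingPointError("degenerate likelihood at a kept draw")
            loglik[c, d] = ll

    meta = {
        "family": spec.family,
        "domain": spec.domain,
        "seed": seed,
        "warmup": config.warmup,
        "chains": config.chains,
        "draws_per_chain": config.draws,
        "subjects": list(prep.subjects),
        "accept_rates": [float(a) for a in accept_rates],
        "divergences": int(divergences),
    }
    return PosteriorDraws(names=names, array=array, loglik=loglik, meta=meta)


def diagnostics(draws: PosteriorDraws, group_only: bool = False) -> Diagnostics:
    """Split-R-hat and effective sample size per parameter (>= 2 chains)."""
    if draws.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    names = draws.group_names() if group_only else draws.names
    rhat, ess = {}, {}
    for name in names:
        x = draws.get(name, flat=False)
        rhat[name] = float(az.rhat(x))
        ess[name] = float(az.ess(x))
    return Diagnostics(rhat=rhat, ess=ess)
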