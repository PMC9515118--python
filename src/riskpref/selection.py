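"""Model comparison: WAIC, PSIS-LOO and posterior predictive accuracy.

Both criteria work from the pointwise log-likelihood matrix (posterior
draws x trials) and are reported on the deviance scale (-2 * elpd), where
lower is better.  The posterior predictive check asks how often the
fitted model's modal choice prediction matches the observed choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .inference import PosteriorDraws, _compose_trialwise, _pointwise_loglik, prepare_trials

__all__ = [
    "waic",
    "psis_loo",
    "ppc_accuracy",
    "select_model",
    "ComparisonReport",
]


def _check_matrix(ll: np.ndarray) -> np.ndarray:
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be draws x trials")
    if ll.shape[0] < 2:
        raise ValueError("need at least 2 draws")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite entries in the log-likelihood matrix")
    return ll


def waic(pointwise_loglik: np.ndarray) -> dict:
    """Widely applicable information criterion.

    lppd_i = log mean_s exp(ll_si); p_i = var_s(ll_si);
    waic = -2 * sum_i (lppd_i - p_i), with its standard error from the
    pointwise scatter.
    """
    ll = _check_matrix(pointwise_loglik)
    n_draws, n_obs = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    se = 2.0 * np.sqrt(n_obs * elpd_i.var(ddof=1)) if n_obs > 1 else 0.0
    return {
        "waic": float(-2.0 * elpd_i.sum()),
        "se": float(se),
        "p_waic": float(p_i.sum()),
        "lppd": float(lppd_i.sum()),
    }


def psis_loo(pointwise_loglik: np.ndarray) -> dict:
    """Pareto-smoothed importance-sampling leave-one-out criterion.

    Raw importance log-weights are -ll; smoothing of the heaviest weights
    follows the standard generalized-Pareto procedure.  Trials with a
    Pareto shape above 0.7 are flagged as unreliable.
    """
    ll = _check_matrix(pointwise_loglik)
    n_draws = ll.shape[0]
    # psislw smooths along the last axis -> (trials, draws)
    lw, pareto_k = az.psislw(-ll.T)
    elpd_i = logsumexp(lw + ll.T, axis=1)
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    n_obs = ll.shape[1]
    se = 2.0 * np.sqrt(n_obs * elpd_i.var(ddof=1)) if n_obs > 1 else 0.0
    return {
        "looic": float(-2.0 * elpd_i.sum()),
        "se": float(se),
        "p_loo": float((lppd_i - elpd_i).sum()),
        "pareto_k": np.asarray(pareto_k, dtype=float),
        "n_bad_k": int(np.sum(np.asarray(pareto_k) > 0.7)),
    }


def _trialwise_params_from_draw(draws: PosteriorDraws, prep, flat_index: int, family: str):
    n_s = prep.n_subjects
    theta = {}
    labels = draws.meta.get("subjects", prep.subjects)
    for base in ("r0", "gamma0", "tau0", "dr_right", "dr_left",
                 "dgamma_right", "dgamma_left", "dtau_right", "dtau_left"):
        name0 = f"{base}[{labels[0]}]"
        if name0 in draws.names:
            theta[base] = np.array(
                [draws.get(f"{base}[{lab}]")[flat_index] for lab in labels]
            )
        else:
            theta[base] = np.zeros(n_s)
    return _compose_trialwise(theta, prep, family)


def ppc_accuracy(
    draws: PosteriorDraws,
    data: pd.DataFrame,
    n_samples: int = 8000,
    rng: np.random.Generator | None = None,
    sampled_predictions: bool = False,
) -> dict:
    """Posterior predictive accuracy: proportion of observed choices that
    the model predicts correctly, over random joint-posterior samples.

    The default prediction is the modal choice (probability > 1/2);
    ``sampled_predictions`` draws stochastic choices instead.  Returns the
    median proportion and an equal-tailed 95% interval.
    """
    rng = rng or np.random.default_rng(0)
    family = draws.meta.get("family", "kahneman_tversky")
    domain = draws.meta.get("domain", "gain")
    prep = prepare_trials(data, domain)
    total = draws.n_chains * draws.n_draws
    if n_samples > total:
        raise ValueError(f"n_samples={n_samples} exceeds total draws {total}")
    idx = rng.choice(total, size=n_samples, replace=False)
    props = np.empty(n_samples)
    for k, flat_index in enumerate(idx):
        r, gamma, tau = _trialwise_params_from_draw(draws, prep, int(flat_index), family)
        ll, g, *_ = _pointwise_loglik(r, gamma, tau, prep, family)
        p_a = prep.y - g  # expit(z) recovered from the gradient identity
        if sampled_predictions:
            pred = (rng.random(prep.n_trials) < p_a).astype(float)
        else:
            pred = (p_a > 0.5).astype(float)
        props[k] = float(np.mean(pred == prep.y))
    lo, hi = np.percentile(props, [2.5, 97.5])
    return {
        "median": float(np.median(props)),
        "ci95": (float(lo), float(hi)),
        "n_samples": int(n_samples),
    }


@dataclass
class ComparisonReport:
    """Per-family information criteria and the selected specification."""

    models: dict = field(default_factory=dict)  # family -> {looic, waic, ...}
    selected: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for family, rep in self.models.items():
            rows.append(
                {
                    "model": family,
                    "looic": rep["looic"],
                    "looic_se": rep["looic_se"],
                    "waic": rep["waic"],
                    "waic_se": rep["waic_se"],
                    "n_bad_pareto_k": rep["n_bad_k"],
                    "selected": family == self.selected,
                }
            )
        return pd.DataFrame(rows)


def select_model(fits: dict) -> ComparisonReport:
    """Rank fitted specifications by LOOIC (ties by WAIC, then simplicity).

    ``fits`` maps family name to a :class:`PosteriorDraws`; all must be
    fitted to the same trials.
    """
    if not fits:
        raise ValueError("no fitted models supplied")
    n_trials = {f: d.loglik.shape[-1] for f, d in fits.items()}
    if len(set(n_trials.values())) > 1:
        raise ValueError(f"models fitted to different trial counts: {n_trials}")
    simplicity = {"linear": 0, "kahneman_tversky": 1, "prelec1": 1}
    report = ComparisonReport()
    for family, draws in fits.items():
        ll = draws.pooled_loglik()
        w = waic(ll)
        loo = psis_loo(ll)
        report.models[family] = {
            "looic": loo["looic"],
            "looic_se": loo["se"],
            "p_loo": loo["p_loo"],
            "n_bad_k": loo["n_bad_k"],
            "waic": w["waic"],
            "waic_se": w["se"],
            "p_waic": w["p_waic"],
        }
    report.selected = min(
        report.models,
        key=lambda f: (
            round(report.models[f]["looic"], 9),
            round(report.models[f]["waic"], 9),
            simplicity.get(f, 99),
        ),
    )
    return report
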