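"""Generative simulator of hierarchical subject populations.

Each subject carries baseline preferences (r0, gamma0, tau0) and
per-condition shifts (dr, dgamma, dtau for right- and left-stimulation
sessions); the effective parameters in a condition are baseline + shift.
Individual parameters follow the same hierarchy the estimator assumes: a
normal distribution on the parameter's own scale around the group
location, truncated to the admissible interval, so the generator and the
fitted model form an exactly matched pair.

Group locations and spreads are specified on the natural scale, e.g.
``mu_r0 = 1.0`` means the group-typical subject is risk neutral and
``sigma_r0 = 0.5`` that subjects spread by about half a unit of the CRRA
coefficient around it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FAMILIES, PreferenceParams, choice_logit_arrays
from .params import BLOCKS, CONDITIONS
from .task import build_session


__all__ = [
    "GroupHyperParams",
    "SubjectParams",
    "TRIAL_COLUMNS",
    "draw_subject_params",
    "condition_params",
    "simulate_dataset",
]

#: Schema (version 1) of the long-format trial table.
TRIAL_COLUMNS = (
    "subject",
    "session",
    "condition",
    "domain",
    "mpl_id",
    "row_index",
    "xA_best",
    "xA_worst",
    "xB_best",
    "xB_worst",
    "p_best",
    "choice",
)

#: Latin square over the six orderings of (sham, right, left); subject i
#: receives row i mod 6, counterbalancing condition against session index.
_CONDITION_ORDERS = (
    ("sham", "right", "left"),
    ("right", "left", "sham"),
    ("left", "sham", "right"),
    ("sham", "left", "right"),
    ("left", "right", "sham"),
    ("right", "sham", "left"),
)


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level locations and between-subject spreads (natural scale).

    Defaults follow the estimated gain-domain group posteriors of the
    motivating study (risk-neutral-ish r, S-shaped weighting, consistent
    choices) with all stimulation shifts at zero.
    """

    mu_r0: float = 1.03
    mu_gamma0: float = 2.5
    mu_tau0: float = 6.68
    mu_dr_right: float = 0.0
    mu_dr_left: float = 0.0
    mu_dgamma_right: float = 0.0
    mu_dgamma_left: float = 0.0
    mu_dtau_right: float = 0.0
    mu_dtau_left: float = 0.0
    sigma_r0: float = 0.5
    sigma_gamma0: float = 0.8
    sigma_tau0: float = 2.5
    sigma_dr_right: float = 0.3
    sigma_dr_left: float = 0.3
    sigma_dgamma_right: float = 0.25
    sigma_dgamma_left: float = 0.25
    sigma_dtau_right: float = 0.8
    sigma_dtau_left: float = 0.8

    def __post_init__(self) -> None:
        for block in BLOCKS:
            mu = getattr(self, f"mu_{block.name}")
            if not block.bounds.lower < mu < block.bounds.upper:
                raise ValueError(
                    f"mu_{block.name}={mu} outside ({block.bounds.lower}, "
                    f"{block.bounds.upper})"
                )
            if getattr(self, f"sigma_{block.name}") <= 0:
                raise ValueError(f"sigma_{block.name} must be positive")

    def location(self, name: str) -> float:
        return getattr(self, f"mu_{name}")

    def spread(self, name: str) -> float:
        return getattr(self, f"sigma_{name}")


@dataclass(frozen=True)
class SubjectParams:
    """Realized baseline and shift parameters of one subject."""

    subject: int
    r0: float
    gamma0: float
    tau0: float
    dr_right: float = 0.0
    dr_left: float = 0.0
    dgamma_right: float = 0.0
    dgamma_left: float = 0.0
    dtau_right: float = 0.0
    dtau_left: float = 0.0


def _composed_margin(values: dict[str, np.ndarray]) -> np.ndarray:
    """Smallest composed (r, gamma, tau) across conditions, per subject."""
    mins = None
    for target in ("r", "gamma", "tau"):
        base = values[f"{target}0"]
        for cond in ("right", "left"):
            composed = base + values[f"d{target}_{cond}"]
            mins = composed if mins is None else np.minimum(mins, composed)
        mins = np.minimum(mins, base)
    return mins


def draw_subject_params(
    hyper: GroupHyperParams,
    n_subjects: int,
    rng: np.random.Generator,
    margin: float = 0.3,
    max_redraws: int = 1000,
) -> list[SubjectParams]:
    """Draw a subject population from the hierarchical generative model.

    Subjects whose composed per-condition parameters would fall within
    ``margin`` of zero are redrawn: the study's empirical posteriors sat
    well inside the admissible intervals, so a realistic population has no
    boundary-riding subjects.  Set ``margin=None`` (or 0) to disable.
    """
    values: dict[str, np.ndarray] = {}

    def _trunc_normal(m: float, sd: float, bounds, n: int) -> np.ndarray:
        out = m + sd * rng.standard_normal(n)
        for _ in range(max_redraws):
            bad = (out <= bounds.lower) | (out >= bounds.upper)
            if not bad.any():
                return out
            out[bad] = m + sd * rng.standard_normal(int(bad.sum()))
        raise RuntimeError("truncated-normal rejection sampling did not converge")

    def _draw(n: int) -> dict[str, np.ndarray]:
        return {
            b.name: _trunc_normal(
                hyper.location(b.name), hyper.spread(b.name), b.bounds, n
            )
            for b in BLOCKS
        }

    values = _draw(n_subjects)
    if margin:
        for _ in range(max_redraws):
            bad = _composed_margin(values) < margin
            if not bad.any():
                break
            fresh = _draw(int(bad.sum()))
            for name in values:
                values[name][bad] = fresh[name]
        else:
            raise RuntimeError(
                "could not draw a population clear of the parameter boundaries; "
                "check hyperparameter locations/spreads against the margin"
            )
    return [
        SubjectParams(subject=i, **{name: float(values[name][i]) for name in values})
        for i in range(n_subjects)
    ]


def condition_params(
    subject: SubjectParams,
    condition: str,
    family: str = "kahneman_tversky",
    truncate: bool = True,
    floor: float = 1e-3,
) -> PreferenceParams:
    """Effective (r, gamma, tau) in a condition: baseline plus the
    condition's shift (sham = baseline).

    Composed values are floored at a small positive value to stay in the
    admissible region; with ``truncate=False`` a non-positive composition
    raises instead.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    out = {}
    for target in ("r", "gamma", "tau"):
        value = getattr(subject, f"{target}0")
        if condition != "sham":
            value += getattr(subject, f"d{target}_{condition}")
        if value <= 0.0:
            if not truncate:
                raise ValueError(
                    f"composed {target} = {value} <= 0 for subject "
                    f"{subject.subject} in condition {condition!r}"
                )
            value = floor
        out[target] = value
    if family == "linear":
        out["gamma"] = 1.0
    return PreferenceParams(**out)


def simulate_dataset(
    hyper: GroupHyperParams,
    n_subjects: int,
    rng: np.random.Generator,
    family: str = "kahneman_tversky",
    outcome_sets=None,
    domains: Sequence[str] = ("gain", "loss"),
    subjects: Sequence[SubjectParams] | None = None,
) -> pd.DataFrame:
    """Simulate the full three-session experiment for a subject cohort.

    Each subject completes one session per condition (Latin-square
    counterbalanced order), each session a freshly shuffled 96-question
    design; choices are Bernoulli draws from the Luce rule.  Returns a
    long-format trial table (one row per subject x session x question),
    optionally restricted to ``domains``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if subjects is None:
        subjects = draw_subject_params(hyper, n_subjects, rng)
    elif len(subjects) != n_subjects:
        raise ValueError("subjects and n_subjects disagree")

    from .task import MPL_OUTCOME_SETS

    outcome_sets = MPL_OUTCOME_SETS if outcome_sets is None else outcome_sets
    frames = []
    for subj in subjects:
        order = _CONDITION_ORDERS[subj.subject % len(_CONDITION_ORDERS)]
        for session, condition in enumerate(order, start=1):
            design = build_session(
                outcome_sets, seed=int(rng.integers(0, 2**31 - 1))
            )
            frame = design.to_frame()
            frame.insert(0, "subject", subj.subject)
            frame.insert(1, "session", session)
            frame.insert(2, "condition", condition)
            keep = frame["domain"].isin(domains)
            frame = frame.loc[keep].reset_index(drop=True)
            params = condition_params(subj, condition, family)
            sign = np.where(frame["domain"].to_numpy() == "gain", 1.0, -1.0)
            z, *_ = choice_logit_arrays(
                frame["xA_best"],
                frame["xA_worst"],
                frame["xB_best"],
                frame["xB_worst"],
                frame["p_best"],
                params.r,
                params.gamma,
                params.tau,
                family,
                sign,
            )
            from scipy.special import expit

            p_a = expit(z)
            frame["choice"] = np.where(rng.random(len(frame)) < p_a, "A", "B")
            frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return table[list(TRIAL_COLUMNS)]
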