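"""Parameter blocks of the hierarchical model.

Each block is one subject-level quantity (a baseline or a stimulation
shift) with its admissible interval and the prior on its group-level mean
(the prior lives on the unconstrained scale).  The linear weighting family
has no curvature parameter, so its gamma blocks are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .transforms import Interval, POSITIVE

__all__ = ["ParamBlock", "BLOCKS", "blocks_for_family", "CONDITIONS"]

CONDITIONS = ("sham", "right", "left")


@dataclass(frozen=True)
class ParamBlock:
    """One subject-level quantity of the hierarchical model.

    ``prior_scale`` says where the group-mean prior lives: "natural" puts
    the stated normal on the parameter's own scale (weakly informative
    relative to its admissible range, as for the baselines), "latent"
    puts it on the unconstrained sampling scale (for the stimulation
    shifts, where the matched standard normal through the scaled-Phi map
    makes the implied prior exactly uniform on the interval — the form
    the Savage-Dickey prior density at zero assumes).
    """

    name: str           # e.g. "r0", "dgamma_left"
    target: str         # which preference parameter it feeds: r / gamma / tau
    condition: str      # "baseline", "right" or "left"
    bounds: Interval
    prior_mean: float
    prior_sd: float
    prior_scale: str = "latent"


BLOCKS: tuple[ParamBlock, ...] = (
    ParamBlock("r0", "r", "baseline", Interval(0.0, 5.0), 0.0, 5.0, "natural"),
    ParamBlock("gamma0", "gamma", "baseline", Interval(0.0, 6.0), 1.0, 3.0, "natural"),
    ParamBlock("tau0", "tau", "baseline", POSITIVE, 0.0, 10.0, "natural"),
    ParamBlock("dr_right", "r", "right", Interval(-2.0, 2.0), 0.0, 1.0),
    ParamBlock("dr_left", "r", "left", Interval(-2.0, 2.0), 0.0, 1.0),
    ParamBlock("dgamma_right", "gamma", "right", Interval(-1.5, 1.5), 0.0, 1.0),
    ParamBlock("dgamma_left", "gamma", "left", Interval(-1.5, 1.5), 0.0, 1.0),
    ParamBlock("dtau_right", "tau", "right", Interval(-5.0, 5.0), 0.0, 1.0),
    ParamBlock("dtau_left", "tau", "left", Interval(-5.0, 5.0), 0.0, 1.0),
)


def blocks_for_family(family: str) -> tuple[ParamBlock, ...]:
    """Blocks active under a weighting family (gamma dropped for linear)."""
    if family == "linear":
        return tuple(b for b in BLOCKS if b.target != "gamma")
    return BLOCKS
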