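"""Multiple-price-list (MPL) lottery task construction.

The task is a random-lottery-pair design: three MPLs per outcome domain,
each a list of 16 binary questions between a *safe* lottery (narrow outcome
spread) and a *risky* lottery (wide spread), ordered by the probability of
the best outcome running from 0 to 1.  Loss-domain questions mirror the
gain-domain ones with the sign of every outcome flipped.  A full session
presents all 96 questions (2 domains x 3 MPLs x 16 rows) in randomized
order, with the risky lottery shown on the left in a random half of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Lottery",
    "LotteryPair",
    "SessionDesign",
    "TABLE1_GRID",
    "MPL_OUTCOME_SETS",
    "expected_value",
    "lottery_sd",
    "mirror",
    "build_mpl",
    "build_session",
    "risk_neutral_choices",
]

#: Probability-of-best-outcome levels of the 16 MPL rows.
TABLE1_GRID: tuple[float, ...] = (
    0.0, 0.01, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40,
    0.50, 0.60, 0.70, 0.80, 0.85, 0.90, 0.95, 1.0,
)

#: Gain-domain outcome quadruples (safe best, safe worst, risky best, risky worst)
#: for the three MPLs.  The first is the published example list; the other two
#: are companion lists in the same 50-500 MU magnitude range, each with the
#: risky option's expected-value range spanning the safe option's.
MPL_OUTCOME_SETS: tuple[tuple[float, float, float, float], ...] = (
    (260.0, 180.0, 350.0, 50.0),
    (240.0, 160.0, 400.0, 40.0),
    (300.0, 220.0, 420.0, 80.0),
)

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class Lottery:
    """A two-outcome gamble: win ``x_best`` with probability ``p_best``,
    else ``x_worst``.  Outcomes are in monetary units and share a sign
    (pure-gain or pure-loss lotteries only)."""

    x_best: float
    x_worst: float
    p_best: float

    def __post_init__(self) -> None:
        if not (-_PROB_TOL <= self.p_best <= 1.0 + _PROB_TOL):
            raise ValueError(f"p_best must lie in [0, 1], got {self.p_best}")
        if self.x_best < self.x_worst:
            raise ValueError(
                f"x_best ({self.x_best}) must be >= x_worst ({self.x_worst})"
            )
        if self.x_best > 0 and self.x_worst < 0:
            raise ValueError("mixed-sign lotteries are not part of the design")

    @property
    def p_worst(self) -> float:
        return 1.0 - self.p_best

    @property
    def spread(self) -> float:
        return abs(self.x_best - self.x_worst)


def expected_value(lottery: Lottery) -> float:
    """Expected monetary value ``p_best*x_best + p_worst*x_worst``."""
    return lottery.p_best * lottery.x_best + lottery.p_worst * lottery.x_worst


def lottery_sd(lottery: Lottery) -> float:
    """Standard deviation of the lottery's monetary outcome.

    Used to label the *riskier* option of a pair (the higher-SD lottery).
    """
    ev = expected_value(lottery)
    var = (
        lottery.p_best * (lottery.x_best - ev) ** 2
        + lottery.p_worst * (lottery.x_worst - ev) ** 2
    )
    return math.sqrt(max(var, 0.0))


def mirror(lottery: Lottery) -> Lottery:
    """Sign-mirrored (loss-domain) version of a gain lottery and vice versa."""
    # probabilities stay on the exact decimal grid (1 - 0.95 -> 0.05)
    return Lottery(
        x_best=-lottery.x_worst,
        x_worst=-lottery.x_best,
        p_best=round(lottery.p_worst, 12),
    )


@dataclass(frozen=True)
class LotteryPair:
    """One binary question: option A vs option B at a shared probability
    of the best outcome.  Exactly one option has the wider outcome spread."""

    option_a: Lottery
    option_b: Lottery
    row_index: int
    mpl_id: str = "mpl1"

    def __post_init__(self) -> None:
        if abs(self.option_a.p_best - self.option_b.p_best) > _PROB_TOL:
            raise ValueError("options of a pair must share outcome probabilities")
        if math.isclose(self.option_a.spread, self.option_b.spread):
            raise ValueError("exactly one option must have the larger spread")
        if not 1 <= self.row_index <= 16:
            raise ValueError("row_index must lie in 1..16")

    @property
    def p_best(self) -> float:
        return self.option_a.p_best

    @property
    def riskier(self) -> str:
        return "A" if self.option_a.spread > self.option_b.spread else "B"

    def swapped(self) -> "LotteryPair":
        return replace(self, option_a=self.option_b, option_b=self.option_a)


def _domain_of(x_vals: Iterable[float]) -> str:
    xs = list(x_vals)
    if all(x >= 0 for x in xs):
        return "gain"
    if all(x <= 0 for x in xs):
        return "loss"
    raise ValueError("outcomes must share a sign within one MPL")


def build_mpl(
    x_a_best: float,
    x_a_worst: float,
    x_b_best: float,
    x_b_worst: float,
    grid: Sequence[float] = TABLE1_GRID,
    mpl_id: str = "mpl1",
) -> list[LotteryPair]:
    """Build one MPL: a pair per grid level, rows ordered by ``p_best``.

    The grid must be strictly increasing within [0, 1]; the four outcomes
    must share a sign (no mixed lotteries).
    """
    _domain_of([x_a_best, x_a_worst, x_b_best, x_b_worst])
    grid = list(grid)
    if any(not 0.0 <= p <= 1.0 for p in grid):
        raise ValueError("grid probabilities must lie in [0, 1]")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    pairs = []
    for i, p in enumerate(grid, start=1):
        pairs.append(
            LotteryPair(
                option_a=Lottery(x_a_best, x_a_worst, p),
                option_b=Lottery(x_b_best, x_b_worst, p),
                row_index=i,
                mpl_id=mpl_id,
            )
        )
    return pairs


def risk_neutral_choices(mpl: Sequence[LotteryPair]) -> list[str]:
    """Choices of a risk-neutral agent: the higher-EV option per row,
    ties broken toward option A (indifference is not an allowed response)."""
    return [
        "A" if expected_value(p.option_a) >= expected_value(p.option_b) else "B"
        for p in mpl
    ]


@dataclass
class SessionDesign:
    """An ordered 96-question session: 48 gain + 48 loss questions drawn
    from 3 MPLs per domain, shuffled, with the riskier option's screen
    position (A/B) randomized in half of the questions."""

    pairs: list[LotteryPair]
    domains: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.domains):
            raise ValueError("pairs and domains must align")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, domain in zip(self.pairs, self.domains):
            rows.append(
                {
                    "mpl_id": pair.mpl_id,
                    "row_index": pair.row_index,
                    "domain": domain,
                    "xA_best": pair.option_a.x_best,
                    "xA_worst": pair.option_a.x_worst,
                    "xB_best": pair.option_b.x_best,
                    "xB_worst": pair.option_b.x_worst,
                    "p_best": pair.p_best,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int | None = None) -> "SessionDesign":
        pairs, domains = [], []
        for _, row in frame.iterrows():
            pairs.append(
                LotteryPair(
                    option_a=Lottery(row["xA_best"], row["xA_worst"], row["p_best"]),
                    option_b=Lottery(row["xB_best"], row["xB_worst"], row["p_best"]),
                    row_index=int(row["row_index"]),
                    mpl_id=str(row["mpl_id"]),
                )
            )
            domains.append(str(row["domain"]))
        return cls(pairs=pairs, domains=domains, seed=seed)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SessionDesign":
        return cls.from_frame(pd.read_csv(path))


def build_session(
    outcome_sets: Sequence[tuple[float, float, float, float]] = MPL_OUTCOME_SETS,
    seed: int | None = 0,
    grid: Sequence[float] = TABLE1_GRID,
) -> SessionDesign:
    """Assemble a randomized 96-question session from 3 gain outcome sets.

    Loss questions are the sign mirrors of the gain questions.  The
    presentation order and the A/B position of the riskier option are
    randomized by ``seed`` (riskier option appears as option A in exactly
    half of the questions).
    """
    if len(outcome_sets) != 3:
        raise ValueError(f"exactly 3 gain outcome sets required, got {len(outcome_sets)}")
    rng = np.random.default_rng(seed)
    pairs: list[LotteryPair] = []
    domains: list[str] = []
    for m, (sa_best, sa_worst, sb_best, sb_worst) in enumerate(outcome_sets, start=1):
        if _domain_of([sa_best, sa_worst, sb_best, sb_worst]) != "gain":
            raise ValueError("outcome sets must be gain-domain; losses are mirrored")
        gain_mpl = build_mpl(sa_best, sa_worst, sb_best, sb_worst, grid, f"mpl{m}")
        for pair in gain_mpl:
            pairs.append(pair)
            domains.append("gain")
            loss_pair = LotteryPair(
                option_a=mirror(pair.option_a),
                option_b=mirror(pair.option_b),
                row_index=pair.row_index,
                mpl_id=f"{pair.mpl_id}_loss",
            )
            pairs.append(loss_pair)
            domains.append("loss")
    n = len(pairs)
    # riskier lottery on the A side in exactly half of the questions
    swap_mask = np.zeros(n, dtype=bool)
    swap_mask[rng.permutation(n)[: n // 2]] = True
    arranged = []
    for pair, swap in zip(pairs, swap_mask):
        want_risky_a = not swap
        if (pair.riskier == "A") != want_risky_a:
            pair = pair.swapped()
        arranged.append(pair)
    order = rng.permutation(n)
    return SessionDesign(
        pairs=[arranged[i] for i in order],
        domains=[domains[i] for i in order],
        seed=seed,
    )
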