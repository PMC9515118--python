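"""Fit the three weighting-function specifications to the cohort.

Fits the linear, Kahneman-Tversky and one-parameter Prelec models to the
gain-domain trials of the simulated cohort (run 02 first) at the reduced
sampling scale, and writes posterior draws, group-level summaries, and
convergence diagnostics per family under results/fits/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from riskpref.inference import MCMCConfig, ModelSpec, diagnostics, fit
from riskpref.pipeline import read_trials

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
CONFIG = MCMCConfig(chains=2, warmup=300, draws=600)
FAMILIES = ("linear", "kahneman_tversky", "prelec1")


def main() -> None:
    trials = read_trials(SCRATCH / "cohort" / "trials.csv")
    out = ROOT / "fits"
    out.mkdir(parents=True, exist_ok=True)

    for family in FAMILIES:
        draws = fit(trials, ModelSpec(family=family), CONFIG, seed=7)
        d = diagnostics(draws, group_only=True)
        draws.save(SCRATCH / "fits" / family)  # bulky, regenerable
        rows = []
        for name in draws.group_names():
            x = draws.get(name)
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "ci95_lo": lo,
                    "ci95_hi": hi,
                    "rhat": d.rhat[name],
                    "ess": d.ess[name],
                }
            )
        summary = pd.DataFrame(rows)
        (out / family).mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / family / "group_summary.csv", index=False)
        print(f"\n=== {family} ===")
        print(f"divergences: {draws.meta['divergences']}, "
              f"max group R-hat: {d.max_rhat:.3f}")
        print(summary.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
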