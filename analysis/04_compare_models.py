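"""Model comparison and posterior predictive accuracy.

Computes WAIC and PSIS-LOO for the three fitted specifications (run 03
first), selects the best by LOOIC, and runs the posterior predictive
check on the selected model: the proportion of observed choices matched
by the model's modal prediction, over random joint-posterior samples.

Writes results/comparison/{comparison.csv,ppc.csv}.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from riskpref.inference import PosteriorDraws
from riskpref.pipeline import read_trials
from riskpref.selection import ppc_accuracy, select_model

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
FAMILIES = ("linear", "kahneman_tversky", "prelec1")


def main() -> None:
    trials = read_trials(SCRATCH / "cohort" / "trials.csv")
    fits = {f: PosteriorDraws.load(SCRATCH / "fits" / f) for f in FAMILIES}
    out = ROOT / "comparison"
    out.mkdir(parents=True, exist_ok=True)

    report = select_model(fits)
    frame = report.to_frame().sort_values("looic")
    frame.to_csv(out / "comparison.csv", index=False)
    print(frame.round(2).to_string(index=False))
    print(f"\nselected specification: {report.selected}")

    best = fits[report.selected]
    n = min(2000, best.n_chains * best.n_draws)
    ppc = ppc_accuracy(best, trials, n_samples=n, rng=np.random.default_rng(3))
    pd.DataFrame([ppc]).to_csv(out / "ppc.csv", index=False)
    print(f"posterior predictive accuracy: median {ppc['median']:.3f}, "
          f"95% interval [{ppc['ci95'][0]:.3f}, {ppc['ci95'][1]:.3f}]")


if __name__ == "__main__":
    main()
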