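"""Stimulation-effect summaries with Savage-Dickey Bayes factors.

For the selected (Kahneman-Tversky) fit, summarizes the six group-level
stimulation shifts: posterior mean, 89% and 95% equal-tailed credible
intervals, the Savage-Dickey BF10 at zero, and its evidence label.

Writes results/effects/effects.csv.
"""

from pathlib import Path

from riskpref.effects import effect_table, effects_frame
from riskpref.inference import PosteriorDraws

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    draws = PosteriorDraws.load(SCRATCH / "fits" / "kahneman_tversky")
    out = ROOT / "effects"
    out.mkdir(parents=True, exist_ok=True)

    frame = effects_frame(effect_table(draws))
    frame.to_csv(out / "effects.csv", index=False)
    print(frame.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
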