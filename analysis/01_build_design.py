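"""Construct the lottery task and check its design arithmetic.

Builds the published 16-row multiple price list (safe 260/180 vs risky
350/50) plus the two companion lists, assembles a randomized 96-question
session (48 gain + 48 loss), and verifies the design-level facts: row-6
and row-9 expected values, the number of rows favoring the safe option,
and the risk-neutral choice pattern (A on rows 1-9, B on rows 10-16).

Writes results/design/{design.csv,design_checks.csv}.
"""

from pathlib import Path

import pandas as pd

from riskpref.task import (
    build_mpl,
    build_session,
    expected_value,
    lottery_sd,
    risk_neutral_choices,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "design"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    mpl = build_mpl(260, 180, 350, 50)
    ev_a = [expected_value(p.option_a) for p in mpl]
    ev_b = [expected_value(p.option_b) for p in mpl]
    pattern = risk_neutral_choices(mpl)
    checks = pd.DataFrame(
        {
            "check": [
                "EV(safe) at p=0.20",
                "EV(risky) at p=0.50",
                "rows with EV(safe) > EV(risky)",
                "risk-neutral A-choices",
                "risk-neutral pattern",
            ],
            "value": [
                ev_a[5],
                ev_b[8],
                sum(a > b for a, b in zip(ev_a, ev_b)),
                pattern.count("A"),
                "".join(pattern),
            ],
        }
    )
    checks.to_csv(OUT / "design_checks.csv", index=False)

    session = build_session(seed=0)
    session.to_csv(OUT / "design.csv")

    frame = session.to_frame()
    print(f"session: {len(frame)} questions "
          f"({(frame.domain == 'gain').sum()} gain / {(frame.domain == 'loss').sum()} loss)")
    print(checks.to_string(index=False))
    sd_a = lottery_sd(mpl[8].option_a)
    sd_b = lottery_sd(mpl[8].option_b)
    print(f"row 9 outcome SDs: safe {sd_a:.1f} vs risky {sd_b:.1f}")


if __name__ == "__main__":
    main()
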