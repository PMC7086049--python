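#!/usr/bin/env python
"""Cost of not knowing dominance: best/intermediate/worst scenario sweep.

All three scenarios share the same SS and RR mortality envelopes and differ
only in the heterozygote: dominance constant at 0 (best case for management),
the idealized concentration-dependent transition, or constant at 1 (worst
case). Times to 50% resistance are simulated at every concentration and
p0 = 1e-4, and the pointwise spread between scenarios is tabulated.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from resistwin import synth, windows  # noqa: E402

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    axis = np.logspace(-4, 2, 25)
    p0 = 1e-4
    table = {"concentration": axis}
    gens = {}
    for kind in ("best", "intermediate", "worst"):
        prof = windows.resistance_time_profile(
            synth.scenario_curves(kind, axis), p0_list=(p0,)
        )
        gens[kind] = np.where(prof.censored[p0], np.inf, prof.generations[p0])
        table[f"generations_{kind}"] = [
            ">500" if not np.isfinite(g) else int(g) for g in gens[kind]
        ]
    pd.DataFrame(table).to_csv(RESULTS / "dominance_scenarios.csv", index=False)

    finite_worst = np.isfinite(gens["worst"])
    gap = gens["best"][finite_worst] - gens["worst"][finite_worst]
    big = int(np.sum(gap > 100))
    print(f"Scenario sweep at p0={p0:g}, x=0.3 (censored shown as >500):")
    print(
        f"  fastest fixation: worst {np.min(gens['worst']):.0f}, "
        f"intermediate {np.min(gens['intermediate']):.0f} generations; "
        "best case never reaches 50% within 500 generations at this p0."
    )
    print(
        f"  at {big}/{int(finite_worst.sum())} concentrations where the worst case "
        "fixes, the best-case prediction lags by more than 100 generations — "
        "uncertainty in dominance alone can swing predicted times to resistance "
        "by hundreds of generations."
    )


if __name__ == "__main__":
    main()
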