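#!/usr/bin/env python
"""Selective advantage and time to resistance along the idealized axis.

At 30% exposure and starting resistance frequencies of 1% and 0.01%, computes
the per-generation selective advantage z and the generations needed to reach
50% resistance allele frequency at every concentration, each point simulated
independently with its mortalities held fixed.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from resistwin import io as rio  # noqa: E402
from resistwin import synth, windows  # noqa: E402

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    axis = np.logspace(-4, 2, 25)
    curve = synth.scenario_curves("intermediate", axis)
    zprof = windows.selection_profile(curve)
    tprof = windows.resistance_time_profile(curve)
    rio.write_report(zprof, RESULTS / "idealized_advantage_profile.txt")
    rio.write_report(tprof, RESULTS / "idealized_time_profile.txt")

    print("Idealized profiles at x=0.3 (exposure), threshold 50%, cap 500 generations:")
    for p0 in (0.01, 1e-4):
        i = int(np.nanargmax(zprof.z[p0]))
        gens = np.where(tprof.censored[p0], np.inf, tprof.generations[p0])
        j = int(np.argmin(gens))
        n_cens = int(tprof.censored[p0].sum())
        print(
            f"  p0={p0:g}: z peaks at {zprof.z[p0][i]:.3f} "
            f"(concentration {axis[i]:.4g}, dominance {zprof.dominance[i]:.2f}); "
            f"fastest fixation {gens[j]:.0f} generations at {axis[j]:.4g}; "
            f"{n_cens}/25 points censored at >500."
        )
    print(
        "  Selection is greatest inside the window of dominance; outside the "
        "window of selection the allele frequency never reaches 50%."
    )


if __name__ == "__main__":
    main()
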