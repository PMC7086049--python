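"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from resistwin import synth
from resistwin.popgen import FitnessSet


def six_mass_oracle(p: float, x: float, w: FitnessSet) -> float:
    """Brute-force one-generation update, independent of the recursion.

    Enumerates the six population masses (exposed/unexposed x three
    genotypes) at Hardy-Weinberg proportions, applies survival to the exposed
    masses, and counts R alleles among survivors.
    """
    q = 1.0 - p
    hw = {"RR": p * p, "SR": 2 * p * q, "SS": q * q}
    surv = {"RR": w.w_rr, "SR": w.w_sr, "SS": w.w_ss}
    r_per_genotype = {"RR": 2, "SR": 1, "SS": 0}
    total = 0.0
    r_alleles = 0.0
    for genotype, mass in hw.items():
        for exposed, fraction in ((True, x), (False, 1.0 - x)):
            survivors = mass * fraction * (surv[genotype] if exposed else 1.0)
            total += survivors
            r_alleles += survivors * r_per_genotype[genotype]
    return r_alleles / (2.0 * total)


def dense_grid_window_oracle(diff_fn, lo: float, hi: float, delta: float, n: int = 1000):
    """Window boundaries by brute-force scan of the generating functions.

    Evaluates ``diff_fn`` (susceptible-minus-resistant mortality, as a
    function of concentration) on an n-point log-spaced dense grid and
    returns the (low, high) concentrations bracketing the open region, or
    None when no grid point is open.
    """
    grid = np.logspace(np.log10(lo), np.log10(hi), n)
    open_mask = diff_fn(grid) > delta
    if not open_mask.any():
        return None
    idx = np.flatnonzero(open_mask)
    return grid[idx[0]], grid[idx[-1]]


@pytest.fixture
def idealized_axis() -> np.ndarray:
    """25-point log-spaced concentration grid spanning the idealized curves."""
    return np.logspace(-4, 2, 25)


@pytest.fixture
def idealized_curve(idealized_axis):
    return synth.scenario_curves("intermediate", idealized_axis)
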