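"""Synthetic bioassay data with the structure the window analysis assumes.

Real inputs to this analysis are cone/larval bioassay mortality series for
resistant and susceptible strains (or SS/SR/RR genotypes) along a declining
concentration — or time-after-deployment — axis. This module emulates them:

* per-arm sigmoidal dose-response, modelled as a log-logistic (Hill) curve on
  log10 concentration, the standard bioassay mortality model;
* first-order exponential decay mapping time since deployment to residual
  concentration, the conventional residual-insecticide model;
* binomial sampling of dead/exposed counts per replicate;
* the idealized/best/intermediate/worst dominance scenario curves used to
  bracket how unknown dominance changes predicted times to resistance.

The decay law and dose-response form are generator conventions, not fitted
claims about any particular insecticide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .windows import MortalityCurve

__all__ = [
    "ArmDoseResponse",
    "DecayParams",
    "BioassayObservation",
    "loglogistic_mortality",
    "fit_loglogistic",
    "generate_genotype_curves",
    "generate_strain_curves",
    "concentration_decay",
    "sample_bioassay",
    "scenario_curves",
    "IDEALIZED_PARAMS",
]

#: Values this close to the floor/ceiling are snapped to the exact bound in
#: the idealized scenarios, so the curves attain 0/100% at the axis extremes
#: (a mortality within 0.001% of the bound is far below bioassay resolution).
_SNAP_TOL = 1e-5


@dataclass(frozen=True)
class ArmDoseResponse:
    """Log-logistic dose-response parameters for one assay arm.

    lc50
        Concentration (assay units, > 0) killing half the exposed insects
        (midway between floor and ceiling).
    slope
        Hill steepness on the log10-concentration scale (> 0).
    floor, ceiling
        Minimum and maximum mortality; defaults span the full [0, 1] range.
    """

    lc50: float
    slope: float
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if self.lc50 <= 0:
            raise ValueError(f"lc50 must be > 0, got {self.lc50!r}")
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope!r}")
        if not (0.0 <= self.floor < self.ceiling <= 1.0):
            raise ValueError(
                f"need 0 <= floor < ceiling <= 1, got {self.floor!r}, {self.ceiling!r}"
            )


@dataclass(frozen=True)
class DecayParams:
    """First-order decay of deployed insecticide: c(t) = c0 * 2^(-t / half_life)."""

    c0: float
    half_life: float

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.half_life <= 0:
            raise ValueError("c0 and half_life must both be > 0")


@dataclass(frozen=True)
class BioassayObservation:
    """One bioassay replicate: dead out of exposed."""

    dead: int
    exposed: int

    @property
    def mortality(self) -> float:
        return self.dead / self.exposed


def loglogistic_mortality(c, params: ArmDoseResponse):
    """Mortality at concentration ``c`` (scalar or array).

    floor + (ceiling - floor) / (1 + (lc50 / c)^slope); strictly increasing
    in c, equal to the floor/ceiling midpoint at c = lc50.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be > 0")
    value = params.floor + (params.ceiling - params.floor) / (
        1.0 + (params.lc50 / c) ** params.slope
    )
    return value if value.ndim else float(value)


def concentration_decay(t, params: DecayParams):
    """Residual concentration at time ``t`` after deployment (t >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    value = params.c0 * 2.0 ** (-t / params.half_life)
    return value if value.ndim else float(value)


def sample_bioassay(
    true_mortality: float, n_exposed: int, seed: int
) -> BioassayObservation:
    """Binomially sampled replicate; same seed gives identical counts."""
    if n_exposed < 1:
        raise ValueError("n_exposed must be >= 1")
    if not (0.0 <= true_mortality <= 1.0):
        raise ValueError("true_mortality must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dead = int(rng.binomial(n_exposed, true_mortality))
    return BioassayObservation(dead=dead, exposed=n_exposed)


def _curve_from_params(
    params: dict[str, ArmDoseResponse],
    axis: np.ndarray,
    axis_kind: str = "concentration",
    snap: bool = False,
) -> MortalityCurve:
    arms = {}
    for name, arm in params.items():
        series = np.asarray(loglogistic_mortality(axis, arm), dtype=float)
        if snap:
            series = np.where(series - arm.floor < _SNAP_TOL, arm.floor, series)
            series = np.where(arm.ceiling - series < _SNAP_TOL, arm.ceiling, series)
        arms[name] = series
    return MortalityCurve(axis_kind=axis_kind, axis=np.asarray(axis, float), arms=arms)


def generate_genotype_curves(
    params: dict[str, ArmDoseResponse],
    axis: np.ndarray,
    snap: bool = False,
) -> MortalityCurve:
    """Noise-free SS/SR/RR mortality curves on a concentration grid.

    Requires the resistance ordering lc50_RR > lc50_SR > lc50_SS. With equal
    slopes this geometry makes dominance rise from ~0 at high concentration
    (SR dies like SS) toward 1 at low concentration (SR survives like RR).
    """
    missing = {"SS", "SR", "RR"} - params.keys()
    if missing:
        raise ValueError(f"missing genotype arms: {sorted(missing)}")
    if not (params["RR"].lc50 > params["SR"].lc50 > params["SS"].lc50):
        raise ValueError("resistance ordering requires lc50 RR > SR > SS")
    return _curve_from_params(params, axis, snap=snap)


def generate_strain_curves(
    params: dict[str, ArmDoseResponse],
    axis: np.ndarray,
    axis_kind: str = "concentration",
) -> MortalityCurve:
    """Noise-free resistant/susceptible strain curves (arms 'R' and 'S')."""
    missing = {"R", "S"} - params.keys()
    if missing:
        raise ValueError(f"missing strain arms: {sorted(missing)}")
    if not params["R"].lc50 > params["S"].lc50:
        raise ValueError("resistant strain must have the larger lc50")
    return _curve_from_params(params, axis, axis_kind=axis_kind)


#: Idealized three-genotype scenario: LC50s a decade apart, shared slope,
#: full floor-to-ceiling range. Chosen to give a selection window spanning
#: roughly two decades of concentration with the dominance window inside it.
IDEALIZED_PARAMS: dict[str, ArmDoseResponse] = {
    "SS": ArmDoseResponse(lc50=0.01, slope=3.0),
    "SR": ArmDoseResponse(lc50=0.1, slope=3.0),
    "RR": ArmDoseResponse(lc50=1.0, slope=3.0),
}


def scenario_curves(kind: str, axis: np.ndarray) -> MortalityCurve:
    """Best/intermediate/worst dominance scenarios over a shared envelope.

    All three share the idealized SS and RR curves; they differ only in the
    heterozygote. ``best``: dominance constant 0 (SR dies like SS, no window
    of dominance). ``worst``: dominance constant 1 (SR survives like RR, the
    dominance window spans the whole selection window). ``intermediate``: the
    idealized SR curve, dominance rising from 0 to 1 as concentration falls.
    """
    if kind not in {"best", "intermediate", "worst"}:
        raise ValueError(f"unknown scenario kind {kind!r}")
    curve = generate_genotype_curves(IDEALIZED_PARAMS, axis, snap=True)
    if kind == "best":
        arms = dict(curve.arms, SR=curve.arms["SS"].copy())
        curve = replace(curve, arms=arms)
    elif kind == "worst":
        arms = dict(curve.arms, SR=curve.arms["RR"].copy())
        curve = replace(curve, arms=arms)
    return curve


def _loglogistic_unit(c, log10_lc50, slope):
    return 1.0 / (1.0 + (10.0**log10_lc50 / c) ** slope)


def fit_loglogistic(
    concentrations: np.ndarray,
    dead: np.ndarray,
    exposed: np.ndarray,
) -> ArmDoseResponse:
    """Least-squares log-logistic fit (floor 0, ceiling 1) to count data.

    Pools replicates per concentration into observed proportions and fits
    lc50 (on a log10 scale, for a well-conditioned search) and slope.
    """
    concentrations = np.asarray(concentrations, float)
    dead = np.asarray(dead, float)
    exposed = np.asarray(exposed, float)
    pooled = (
        pd.DataFrame({"c": concentrations, "dead": dead, "exposed": exposed})
        .groupby("c", sort=True)
        .sum()
    )
    c = pooled.index.to_numpy()
    prop = (pooled["dead"] / pooled["exposed"]).to_numpy()
    popt, _ = curve_fit(
        _loglogistic_unit,
        c,
        prop,
        p0=[np.mean(np.log10(c)), 2.0],
        bounds=([np.log10(c.min()) - 3, 0.05], [np.log10(c.max()) + 3, 50.0]),
        maxfev=10000,
    )
    return ArmDoseResponse(lc50=10.0 ** popt[0], slope=popt[1])
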