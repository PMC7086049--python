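"""Windows of selection and dominance on mortality-versus-concentration curves.

A *window of selection* is the range of insecticide concentrations (or time
since deployment, concentration's operational surrogate) over which resistant
insects suffer lower mortality than susceptible ones, so resistance is
selected. When per-genotype mortalities are available, the *window of
dominance* is the sub-region where heterozygote mortality falls below that of
susceptible homozygotes (dominance h > 0); selection is strongest there.

This module detects and measures both windows on observed or synthetic
mortality curves, and computes per-point dominance, selective-advantage and
time-to-resistance profiles along the axis. Concentration axes are handled on
a log10 scale for smoothing and boundary interpolation; time axes are linear.
Windows are reported in deployment order: concentrations decline after
deployment, so a concentration window opens at its high boundary and closes
at its low one, while a time window opens early and closes late.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import popgen
from .popgen import (
    GenotypeMortalities,
    SelectionContext,
    UndefinedDominanceError,
    fitness_from_mortality,
    selective_advantage,
)

__all__ = [
    "MortalityCurve",
    "WindowReport",
    "WindowMeasure",
    "ProfileResult",
    "CompletionRule",
    "smooth_mortality",
    "complete_curve",
    "detect_selection_window",
    "detect_dominance_window",
    "dominance_profile",
    "selection_profile",
    "resistance_time_profile",
    "window_metrics",
]

DEFAULT_EXPOSURE = 0.3
DEFAULT_P0 = (0.01, 1e-4)
DEFAULT_THRESHOLD = 0.5
DEFAULT_MAX_GENERATIONS = 500
DEFAULT_SPAN = 0.75


@dataclass(frozen=True)
class MortalityCurve:
    """Per-arm mortality series along a concentration or time axis.

    ``arms`` maps an arm label (strain "R"/"S", or genotype "SS"/"SR"/"RS"/
    "RR") to mortality proportions aligned with ``axis``; NaN marks a missing
    observation. ``counts``, when present, carries (dead, exposed) per point.
    The axis is stored ascending; descending input is reversed on construction
    so that presentation order (high-to-low concentration) is a display
    concern only.
    """

    axis_kind: str
    axis: np.ndarray
    arms: dict[str, np.ndarray]
    counts: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis_kind not in {"concentration", "time"}:
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        axis = np.asarray(self.axis, dtype=float)
        if axis.ndim != 1 or len(axis) < 2:
            raise ValueError("axis must be a 1-d array with >= 2 points")
        diffs = np.diff(axis)
        if np.all(diffs < 0):  # canonicalize to ascending
            object.__setattr__(self, "axis", axis[::-1].copy())
            object.__setattr__(
                self, "arms", {k: np.asarray(v, float)[::-1].copy() for k, v in self.arms.items()}
            )
            if self.counts is not None:
                object.__setattr__(
                    self,
                    "counts",
                    {
                        k: (np.asarray(d, float)[::-1].copy(), np.asarray(e, float)[::-1].copy())
                        for k, (d, e) in self.counts.items()
                    },
                )
            axis = self.axis
            diffs = np.diff(axis)
        else:
            object.__setattr__(self, "axis", axis)
            object.__setattr__(
                self, "arms", {k: np.asarray(v, dtype=float) for k, v in self.arms.items()}
            )
        if not np.all(diffs > 0):
            raise ValueError("axis must be strictly monotone")
        if self.axis_kind == "concentration" and np.any(axis <= 0):
            raise ValueError("concentrations must be > 0")
        for name, series in self.arms.items():
            if series.shape != axis.shape:
                raise ValueError(f"arm {name!r} length does not match axis")
            observed = series[~np.isnan(series)]
            if np.any((observed < 0) | (observed > 1)):
                raise ValueError(f"arm {name!r} has mortality outside [0, 1]")
        if self.counts is not None:
            for name, (dead, exposed) in self.counts.items():
                dead, exposed = np.asarray(dead, float), np.asarray(exposed, float)
                ok = ~np.isnan(dead)
                if np.any(dead[ok] < 0) or np.any(dead[ok] > exposed[ok]):
                    raise ValueError(f"arm {name!r} has dead > exposed or negative counts")

    @property
    def transformed_axis(self) -> np.ndarray:
        """log10(axis) for concentration, identity for time."""
        return np.log10(self.axis) if self.axis_kind == "concentration" else self.axis

    def require_arms(self, *names: str) -> None:
        missing = [n for n in names if n not in self.arms]
        if missing:
            raise ValueError(f"curve is missing required arm(s): {missing}")

    def heterozygote_series(self) -> np.ndarray:
        """SR series, averaged pointwise with RS when both are present."""
        if "SR" in self.arms and "RS" in self.arms:
            stacked = np.vstack([self.arms["SR"], self.arms["RS"]])
            with np.errstate(invalid="ignore"):
                return np.nanmean(stacked, axis=0)
        if "SR" in self.arms:
            return self.arms["SR"]
        if "RS" in self.arms:
            return self.arms["RS"]
        raise ValueError("curve is missing required arm(s): ['SR' or 'RS']")


@dataclass(frozen=True)
class WindowMeasure:
    """Size of a window: x-fold concentration range, or duration in axis units."""

    kind: str  # "fold_range" | "duration" | "no_window"
    value: float | None
    open_ended: bool = False


@dataclass(frozen=True)
class WindowReport:
    """Detected window with boundaries in deployment order.

    ``open_at``/``close_at`` are axis-unit positions (interpolated between
    grid points); for a concentration axis deployment runs high-to-low, so
    ``open_at >= close_at``. ``open_unbounded``/``close_unbounded`` flag
    windows already open at the first observed point or not yet closed at the
    last. ``open_flags`` aligns with the curve's ascending canonical axis.
    ``fragmented`` marks noisy curves whose open points form more than one
    contiguous run; the report then spans the outermost run edges.
    """

    window_kind: str  # "selection" | "dominance"
    axis_kind: str
    axis: np.ndarray
    open_flags: np.ndarray
    open_at: float | None
    close_at: float | None
    open_unbounded: bool = False
    close_unbounded: bool = False
    fragmented: bool = False

    @property
    def is_empty(self) -> bool:
        return not bool(np.any(self.open_flags))


@dataclass(frozen=True)
class ProfileResult:
    """Per-point dominance, selective advantage and/or time to resistance.

    ``z`` and ``generations`` map each starting allele frequency to a series
    aligned with ``axis``; in ``generations`` NaN marks a simulation censored
    at ``max_generations`` (the paired boolean mask in ``censored`` is the
    authoritative marker). ``dominance`` is NaN where undefined
    (m_ss <= m_rr).
    """

    axis_kind: str
    axis: np.ndarray
    dominance: np.ndarray
    z: dict[float, np.ndarray] | None = None
    generations: dict[float, np.ndarray] | None = None
    censored: dict[float, np.ndarray] | None = None
    max_generations: int = DEFAULT_MAX_GENERATIONS


@dataclass(frozen=True)
class CompletionRule:
    """Impose a constant mortality on an arm where data are absent.

    ``lo``/``hi`` bound the axis region (inclusive; None = unbounded) and
    ``value`` must be 0 or 1 — the convention of extrapolating missing
    mortalities to 0% or 100% outside the assayed range.
    """

    arm: str
    value: float
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.value not in (0.0, 1.0):
            raise ValueError("completion value must be 0 or 1")


def smooth_mortality(
    curve: MortalityCurve, span: float = DEFAULT_SPAN
) -> MortalityCurve:
    """Locally weighted (loess) smoothing of every arm, clipped to [0, 1].

    Tricube-weighted local linear regression on the transformed axis
    (log10 concentration / linear time), evaluated at the original axis
    points. Arms with fewer than 4 observed points pass through unchanged and
    the curve is flagged in ``metadata['smoothing_warnings']``.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must lie in (0, 1], got {span!r}")
    taxis = curve.transformed_axis
    smoothed: dict[str, np.ndarray] = {}
    warnings: list[str] = []
    for name, series in curve.arms.items():
        observed = ~np.isnan(series)
        if observed.sum() < 4:
            smoothed[name] = series.copy()
            warnings.append(name)
            continue
        fitted = lowess(
            series[observed],
            taxis[observed],
            frac=span,
            it=0,
            xvals=taxis[observed],
        )
        out = np.full_like(series, np.nan)
        out[observed] = np.clip(fitted, 0.0, 1.0)
        smoothed[name] = out
    metadata = dict(curve.metadata)
    if warnings:
        metadata["smoothing_warnings"] = warnings
    return replace(curve, arms=smoothed, metadata=metadata)


def complete_curve(
    curve: MortalityCurve, rules: list[CompletionRule]
) -> MortalityCurve:
    """Fill missing (NaN) points with 0/1 per the stated extrapolation rules.

    Observed points are never overwritten: a rule whose region contains an
    observed point is an error, since that would silently replace data.
    """
    arms = {k: v.copy() for k, v in curve.arms.items()}
    for rule in rules:
        if rule.arm not in arms:
            raise ValueError(f"completion rule names unknown arm {rule.arm!r}")
        series = arms[rule.arm]
        region = np.ones_like(curve.axis, dtype=bool)
        if rule.lo is not None:
            region &= curve.axis >= rule.lo
        if rule.hi is not None:
            region &= curve.axis <= rule.hi
        clash = region & ~np.isnan(series)
        if np.any(clash):
            where = curve.axis[clash]
            raise ValueError(
                f"completion rule for arm {rule.arm!r} overlaps observed data "
                f"at axis value(s) {where.tolist()}"
            )
        series[region] = rule.value
    return replace(curve, arms=arms)


def _interp_boundary(
    taxis: np.ndarray, diff: np.ndarray, i_out: int, i_in: int, delta: float
) -> float:
    """Axis position (transformed scale) where diff crosses delta between
    a closed grid point and its open neighbour."""
    d0, d1 = diff[i_out], diff[i_in]
    if d1 == d0:
        return taxis[i_in]
    frac = (delta - d0) / (d1 - d0)
    return taxis[i_out] + frac * (taxis[i_in] - taxis[i_out])


def _detect_window(
    curve: MortalityCurve, diff: np.ndarray, window_kind: str, delta: float
) -> WindowReport:
    """Shared boundary-finding: open where diff > delta (strict), boundaries
    linearly interpolated on the transformed axis, deployment-order output."""
    taxis = curve.transformed_axis
    valid = ~np.isnan(diff)
    flags = np.zeros(len(taxis), dtype=bool)
    flags[valid] = diff[valid] > delta
    if not np.any(flags):
        return WindowReport(
            window_kind=window_kind,
            axis_kind=curve.axis_kind,
            axis=curve.axis,
            open_flags=flags,
            open_at=None,
            close_at=None,
        )
    open_idx = np.flatnonzero(flags)
    first, last = open_idx[0], open_idx[-1]
    fragmented = bool(np.any(~flags[first : last + 1]))

    def _untransform(t: float) -> float:
        return float(10.0**t if curve.axis_kind == "concentration" else t)

    # Lower (ascending-axis) edge
    if first == 0 or not valid[first - 1]:
        lower, lower_unbounded = float(curve.axis[first]), first == 0
        if first != 0:  # adjacent point missing: boundary at the open point
            lower_unbounded = False
    else:
        lower = _untransform(_interp_boundary(taxis, diff, first - 1, first, delta))
        lower_unbounded = False
    # Upper (ascending-axis) edge
    if last == len(taxis) - 1 or not valid[last + 1]:
        upper, upper_unbounded = float(curve.axis[last]), last == len(taxis) - 1
        if last != len(taxis) - 1:
            upper_unbounded = False
    else:
        upper = _untransform(_interp_boundary(taxis, diff, last + 1, last, delta))
        upper_unbounded = False

    if curve.axis_kind == "concentration":
        open_at, close_at = upper, lower
        open_unbounded, close_unbounded = upper_unbounded, lower_unbounded
    else:
        open_at, close_at = lower, upper
        open_unbounded, close_unbounded = lower_unbounded, upper_unbounded
    return WindowReport(
        window_kind=window_kind,
        axis_kind=curve.axis_kind,
        axis=curve.axis,
        open_flags=flags,
        open_at=open_at,
        close_at=close_at,
        open_unbounded=open_unbounded,
        close_unbounded=close_unbounded,
        fragmented=fragmented,
    )


def _strain_pair(curve: MortalityCurve) -> tuple[np.ndarray, np.ndarray]:
    """(susceptible, resistant) series: strain arms if present, else SS/RR."""
    if "R" in curve.arms and "S" in curve.arms:
        return curve.arms["S"], curve.arms["R"]
    curve.require_arms("SS", "RR")
    return curve.arms["SS"], curve.arms["RR"]


def detect_selection_window(
    curve: MortalityCurve,
    delta: float = 0.0,
    smoothed: bool = True,
    span: float = DEFAULT_SPAN,
) -> WindowReport:
    """Window of selection: where susceptible mortality exceeds resistant.

    Uses strain arms R/S when present, otherwise the SS/RR genotype arms.
    With ``smoothed`` (default) the comparison runs on loess-smoothed series,
    matching how windows are judged against fitted mortality lines; raw-series
    detection is available for noise-free or pre-smoothed curves.
    """
    if ("R" in curve.arms) != ("S" in curve.arms) and not (
        "SS" in curve.arms and "RR" in curve.arms
    ):
        raise ValueError("selection window needs both strain arms (R and S)")
    work = smooth_mortality(curve, span) if smoothed else curve
    mort_s, mort_r = _strain_pair(work)
    return _detect_window(work, mort_s - mort_r, "selection", delta)


def dominance_profile(curve: MortalityCurve) -> np.ndarray:
    """Per-point dominance h of resistance; NaN where undefined.

    Requires SS, RR and at least one heterozygote arm (reciprocal
    heterozygotes are averaged first). Points where SS mortality does not
    exceed RR mortality — the window of selection shut, or the fitness-cost
    regime — carry NaN rather than a number.
    """
    curve.require_arms("SS", "RR")
    het = curve.heterozygote_series()
    out = np.full(len(curve.axis), np.nan)
    for i in range(len(out)):
        m_ss, m_rr, m_sr = curve.arms["SS"][i], curve.arms["RR"][i], het[i]
        if np.isnan(m_ss) or np.isnan(m_rr) or np.isnan(m_sr):
            continue
        try:
            inputs = popgen.model_inputs_from_mortalities(
                GenotypeMortalities(m_ss=m_ss, m_sr=m_sr, m_rr=m_rr), x=0.0
            )
        except UndefinedDominanceError:
            continue
        out[i] = inputs.dominance
    return out


def detect_dominance_window(
    curve: MortalityCurve,
    delta: float = 0.0,
    smoothed: bool = True,
    span: float = DEFAULT_SPAN,
) -> WindowReport:
    """Window of dominance: h > 0 inside an open window of selection.

    Open where heterozygote mortality sits below SS mortality by more than
    ``delta`` AND the SS-vs-RR selection window is open at the same point; by
    construction the dominance window is a subset of the selection window.
    """
    curve.require_arms("SS", "RR")
    work = smooth_mortality(curve, span) if smoothed else curve
    het = work.heterozygote_series()
    m_ss, m_rr = work.arms["SS"], work.arms["RR"]
    dom_diff = m_ss - het
    sel_diff = m_ss - m_rr
    # Combined criterion: the binding (smaller) margin must still exceed delta.
    combined = np.fmin(dom_diff, sel_diff)
    combined = np.where(np.isnan(dom_diff) | np.isnan(sel_diff), np.nan, combined)
    return _detect_window(work, combined, "dominance", delta)


def _profile_mortalities(curve: MortalityCurve) -> list[GenotypeMortalities | None]:
    curve.require_arms("SS", "RR")
    het = curve.heterozygote_series()
    rows: list[GenotypeMortalities | None] = []
    for m_ss, m_sr, m_rr in zip(curve.arms["SS"], het, curve.arms["RR"]):
        if np.isnan(m_ss) or np.isnan(m_sr) or np.isnan(m_rr):
            rows.append(None)
        else:
            rows.append(GenotypeMortalities(m_ss=m_ss, m_sr=m_sr, m_rr=m_rr))
    return rows


def selection_profile(
    curve: MortalityCurve,
    x: float = DEFAULT_EXPOSURE,
    p0_list: tuple[float, ...] = DEFAULT_P0,
) -> ProfileResult:
    """Selective advantage z at each axis point, per starting frequency.

    z needs only the three fitnesses, so points where dominance is undefined
    still yield a value; missing mortalities yield NaN.
    """
    rows = _profile_mortalities(curve)
    z = {p0: np.full(len(rows), np.nan) for p0 in p0_list}
    for i, m in enumerate(rows):
        if m is None:
            continue
        w = fitness_from_mortality(m)
        for p0 in p0_list:
            z[p0][i] = selective_advantage(SelectionContext(p=p0, x=x), w)
    return ProfileResult(
        axis_kind=curve.axis_kind,
        axis=curve.axis,
        dominance=dominance_profile(curve),
        z=z,
    )


def resistance_time_profile(
    curve: MortalityCurve,
    x: float = DEFAULT_EXPOSURE,
    p0_list: tuple[float, ...] = DEFAULT_P0,
    threshold: float = DEFAULT_THRESHOLD,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> ProfileResult:
    """Generations to the threshold frequency at each point, per p0.

    Each point is an independent simulation with its mortalities held
    constant. Censored runs (threshold not reached within the cap) are NaN in
    ``generations`` with the paired ``censored`` mask set.
    """
    rows = _profile_mortalities(curve)
    generations = {p0: np.full(len(rows), np.nan) for p0 in p0_list}
    censored = {p0: np.zeros(len(rows), dtype=bool) for p0 in p0_list}
    for i, m in enumerate(rows):
        if m is None:
            continue
        w = fitness_from_mortality(m)
        for p0 in p0_list:
            result = popgen.simulate_trajectory(
                w, x, p0, threshold=threshold, max_generations=max_generations
            )
            if result.censored:
                censored[p0][i] = True
            else:
                generations[p0][i] = result.generations_to_threshold
    return ProfileResult(
        axis_kind=curve.axis_kind,
        axis=curve.axis,
        dominance=dominance_profile(curve),
        generations=generations,
        censored=censored,
        max_generations=max_generations,
    )


def window_metrics(report: WindowReport) -> WindowMeasure:
    """Fold-range (concentration axis) or duration (time axis) of a window.

    Fold-range is the larger boundary concentration divided by the smaller,
    hence always >= 1. Open-ended windows report the observed span with the
    ``open_ended`` flag set. An empty window is a defined "no window" result.
    """
    if report.is_empty:
        return WindowMeasure(kind="no_window", value=None)
    open_ended = report.open_unbounded or report.close_unbounded
    if report.axis_kind == "concentration":
        hi = max(report.open_at, report.close_at)
        lo = min(report.open_at, report.close_at)
        return WindowMeasure(kind="fold_range", value=hi / lo, open_ended=open_ended)
    return WindowMeasure(
        kind="duration", value=report.close_at - report.open_at, open_ended=open_ended
    )
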