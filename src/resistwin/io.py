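"""Delimited-text tables, structured report files and run configuration.

The single input dialect is a UTF-8 comma-separated bioassay table with a
mandatory header. Each row carries one arm at one axis point::

    axis_kind,axis_value,arm,dead,exposed
    concentration,0.8,R,12,50

or, when only summary mortalities are available::

    axis_kind,axis_value,arm,mortality_pct
    concentration,0.8,R,24.0

Percentages are accepted on input (matching how bioassay mortality is
reported) but proportions are used internally. Concentration units are opaque
and carried through unchanged — published windows mix % papers, ppm and
multiples of the discriminating dose, and no conversion is attempted.

Reports (windows, profiles, simulations) are written as self-describing
``key: value`` headers followed by a per-point CSV table; censored
simulations carry an explicit ``>500``-style marker, never a bare number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .popgen import SimulationResult
from .windows import (
    DEFAULT_EXPOSURE,
    DEFAULT_MAX_GENERATIONS,
    DEFAULT_P0,
    DEFAULT_SPAN,
    DEFAULT_THRESHOLD,
    MortalityCurve,
    ProfileResult,
    WindowReport,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_bioassay_table",
    "write_bioassay_table",
    "write_report",
    "read_report",
]

_AXIS_KINDS = {"concentration", "time"}


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; defaults are the study's standard settings.

    30% of the population exposed each generation; starting resistance allele
    frequencies of 1% and 0.01%; resistance declared at 50% allele frequency;
    simulations censored at 500 generations.
    """

    x: float = DEFAULT_EXPOSURE
    p0_list: tuple[float, ...] = DEFAULT_P0
    threshold: float = DEFAULT_THRESHOLD
    max_generations: int = DEFAULT_MAX_GENERATIONS
    span: float = DEFAULT_SPAN
    delta: float = 0.0
    seed: int = 0


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    known = RunConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "p0_list" in raw:
        raw["p0_list"] = tuple(float(v) for v in raw["p0_list"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    data = {
        "x": config.x,
        "p0_list": list(config.p0_list),
        "threshold": config.threshold,
        "max_generations": config.max_generations,
        "span": config.span,
        "delta": config.delta,
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_bioassay_table(path) -> MortalityCurve:
    """Read a bioassay CSV into a :class:`MortalityCurve`.

    Row order does not matter (points are sorted by axis value); counts are
    converted to proportions. Schema violations name the offending row and
    column; mixing concentration and time rows in one file is an error.
    """
    df = pd.read_csv(path)
    required = {"axis_kind", "axis_value", "arm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    has_counts = {"dead", "exposed"} <= set(df.columns)
    has_pct = "mortality_pct" in df.columns
    if not has_counts and not has_pct:
        raise ValueError("need either dead+exposed columns or mortality_pct")
    kinds = set(df["axis_kind"].unique())
    if len(kinds) > 1:
        raise ValueError(f"mixed axis kinds in one file: {sorted(kinds)}")
    axis_kind = kinds.pop()
    if axis_kind not in _AXIS_KINDS:
        raise ValueError(f"unknown axis_kind {axis_kind!r}")

    mort = np.empty(len(df))
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based, after the header line
        if has_counts and not (has_pct and pd.notna(row.get("mortality_pct"))):
            dead, exposed = row["dead"], row["exposed"]
            if pd.isna(dead) or pd.isna(exposed):
                raise ValueError(f"row {rowno}: missing value in column 'dead'/'exposed'")
            if exposed < 1 or dead < 0 or dead > exposed:
                raise ValueError(
                    f"row {rowno}: invalid counts dead={dead}, exposed={exposed} "
                    "(need 0 <= dead <= exposed, exposed >= 1)"
                )
            mort[i] = dead / exposed
        else:
            pct = row["mortality_pct"]
            if pd.isna(pct):
                raise ValueError(f"row {rowno}: missing value in column 'mortality_pct'")
            if not (0.0 <= pct <= 100.0):
                raise ValueError(
                    f"row {rowno}: column 'mortality_pct' outside [0, 100]: {pct}"
                )
            mort[i] = pct / 100.0
    df = df.assign(_mortality=mort)

    # Replicates (repeated axis_value/arm rows) are pooled: counts are summed
    # into one proportion; summary percentages are averaged with equal weight.
    axis = np.sort(df["axis_value"].unique().astype(float))
    arms: dict[str, np.ndarray] = {}
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for arm, sub in df.groupby("arm", sort=True):
        series = np.full(len(axis), np.nan)
        arm_counts = has_counts and sub["dead"].notna().all()
        dead = np.full(len(axis), np.nan)
        exposed = np.full(len(axis), np.nan)
        for value, point in sub.groupby("axis_value"):
            i = int(np.searchsorted(axis, float(value)))
            if arm_counts:
                dead[i] = point["dead"].sum()
                exposed[i] = point["exposed"].sum()
                series[i] = dead[i] / exposed[i]
            else:
                series[i] = point["_mortality"].mean()
        arms[str(arm)] = series
        if arm_counts:
            counts[str(arm)] = (dead, exposed)
    return MortalityCurve(
        axis_kind=axis_kind, axis=axis, arms=arms, counts=counts or None
    )


def write_bioassay_table(curve: MortalityCurve, path) -> None:
    """Write a curve back to the bioassay CSV dialect (full float precision)."""
    rows = []
    for arm, series in sorted(curve.arms.items()):
        for value, m in zip(curve.axis, series):
            if np.isnan(m):
                continue
            row = {
                "axis_kind": curve.axis_kind,
                "axis_value": repr(float(value)),
                "arm": arm,
                "mortality_pct": repr(float(m) * 100.0),
            }
            if curve.counts and arm in curve.counts:
                i = int(np.searchsorted(curve.axis, value))
                dead, exposed = curve.counts[arm]
                if not np.isnan(dead[i]):
                    row["dead"] = int(dead[i])
                    row["exposed"] = int(exposed[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _fmt(value) -> str:
    if value is None:
        return "none"
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def _parse_scalar(text: str):
    if text == "none":
        return None
    if text in {"true", "false"}:
        return text == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def write_report(report, path) -> None:
    """Write a window report, profile or simulation to a structured text file.

    The format is a ``key: value`` header block, a blank line, then a CSV
    table of per-point values. Censored generation counts appear as an
    explicit ``>N`` marker; an empty window writes a ``no window`` record.
    Output is byte-stable for identical inputs.
    """
    if isinstance(report, WindowReport):
        _write_window_report(report, path)
    elif isinstance(report, ProfileResult):
        _write_profile(report, path)
    elif isinstance(report, SimulationResult):
        _write_simulation(report, path)
    else:
        raise TypeError(f"cannot serialise report of type {type(report).__name__}")


def _write_window_report(report: WindowReport, path) -> None:
    from .windows import window_metrics

    measure = window_metrics(report)
    lines = [
        "report: window",
        f"window_kind: {report.window_kind}",
        f"axis_kind: {report.axis_kind}",
        f"status: {'no window' if report.is_empty else 'open'}",
        f"open_at: {_fmt(report.open_at)}",
        f"close_at: {_fmt(report.close_at)}",
        f"open_unbounded: {_fmt(report.open_unbounded)}",
        f"close_unbounded: {_fmt(report.close_unbounded)}",
        f"fragmented: {_fmt(report.fragmented)}",
        f"measure_kind: {measure.kind}",
        f"measure_value: {_fmt(measure.value)}",
        f"measure_open_ended: {_fmt(measure.open_ended)}",
        "",
        "axis,open",
    ]
    for value, flag in zip(report.axis, report.open_flags):
        lines.append(f"{_fmt(float(value))},{_fmt(bool(flag))}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_profile(profile: ProfileResult, path) -> None:
    p0s: list[float] = []
    if profile.z:
        p0s = sorted(profile.z)
    elif profile.generations:
        p0s = sorted(profile.generations)
    lines = [
        "report: profile",
        f"axis_kind: {profile.axis_kind}",
        f"p0_list: {','.join(repr(p) for p in p0s)}",
        f"has_z: {_fmt(profile.z is not None)}",
        f"has_generations: {_fmt(profile.generations is not None)}",
        f"max_generations: {profile.max_generations}",
        "",
    ]
    header = ["axis", "dominance"]
    if profile.z is not None:
        header += [f"z@{repr(p)}" for p in p0s]
    if profile.generations is not None:
        header += [f"generations@{repr(p)}" for p in p0s]
    lines.append(",".join(header))
    for i, value in enumerate(profile.axis):
        row = [_fmt(float(value))]
        h = profile.dominance[i]
        row.append("undefined" if np.isnan(h) else _fmt(float(h)))
        if profile.z is not None:
            for p in p0s:
                zval = profile.z[p][i]
                row.append("missing" if np.isnan(zval) else _fmt(float(zval)))
        if profile.generations is not None:
            for p in p0s:
                if profile.censored is not None and profile.censored[p][i]:
                    row.append(f">{profile.max_generations}")
                else:
                    gen = profile.generations[p][i]
                    row.append("missing" if np.isnan(gen) else str(int(gen)))
        lines.append(",".join(row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_simulation(result: SimulationResult, path) -> None:
    lines = [
        "report: simulation",
        f"threshold: {_fmt(result.threshold)}",
        f"max_generations: {result.max_generations}",
        f"generations_to_threshold: {result.display_generations()}",
        f"censored: {_fmt(result.censored)}",
        "",
        "generation,p",
    ]
    for gen, p in enumerate(result.trajectory):
        lines.append(f"{gen},{_fmt(float(p))}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_report(path):
    """Parse a file written by :func:`write_report` back into its object."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    head, _, tail = text.partition("\n\n")
    header: dict[str, str] = {}
    for line in head.splitlines():
        key, _, value = line.partition(": ")
        header[key] = value
    table_lines = [ln for ln in tail.splitlines() if ln]
    columns = table_lines[0].split(",")
    rows = [ln.split(",") for ln in table_lines[1:]]
    kind = header["report"]
    if kind == "window":
        return WindowReport(
            window_kind=header["window_kind"],
            axis_kind=header["axis_kind"],
            axis=np.array([float(r[0]) for r in rows]),
            open_flags=np.array([r[1] == "true" for r in rows]),
            open_at=_parse_scalar(header["open_at"]),
            close_at=_parse_scalar(header["close_at"]),
            open_unbounded=header["open_unbounded"] == "true",
            close_unbounded=header["close_unbounded"] == "true",
            fragmented=header["fragmented"] == "true",
        )
    if kind == "profile":
        p0s = [float(v) for v in header["p0_list"].split(",") if v]
        axis = np.array([float(r[0]) for r in rows])
        dominance = np.array(
            [np.nan if r[1] == "undefined" else float(r[1]) for r in rows]
        )
        max_gen = int(header["max_generations"])
        col = 2
        z = None
        if header["has_z"] == "true":
            z = {}
            for p in p0s:
                z[p] = np.array(
                    [np.nan if r[col] == "missing" else float(r[col]) for r in rows]
                )
                col += 1
        generations = censored = None
        if header["has_generations"] == "true":
            generations = {}
            censored = {}
            for p in p0s:
                gen_col = [r[col] for r in rows]
                generations[p] = np.array(
                    [
                        np.nan if v.startswith(">") or v == "missing" else float(v)
                        for v in gen_col
                    ]
                )
                censored[p] = np.array([v.startswith(">") for v in gen_col])
                col += 1
        return ProfileResult(
            axis_kind=header["axis_kind"],
            axis=axis,
            dominance=dominance,
            z=z,
            generations=generations,
            censored=censored,
            max_generations=max_gen,
        )
    if kind == "simulation":
        gens = header["generations_to_threshold"]
        return SimulationResult(
            trajectory=np.array([float(r[1]) for r in rows]),
            threshold=float(header["threshold"]),
            max_generations=int(header["max_generations"]),
            generations_to_threshold=None if gens.startswith(">") else int(gens),
        )
    raise ValueError(f"unknown report kind {kind!r}")
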