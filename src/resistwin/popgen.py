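"""Single-locus diploid selection under partial insecticide exposure.

The model: a randomly mating population carries a resistance allele R at
frequency ``p`` (susceptible allele S at ``q = 1 - p``). Each generation a
fraction ``x`` of the population contacts the insecticide; exposed genotypes
survive with probability ``w_g = 1 - mortality_g`` while unexposed individuals
are untouched (no fitness costs of resistance). Genotypes start each
generation at Hardy-Weinberg proportions ``p^2, 2pq, q^2``. The recursion

    p' = [x (p^2 w_rr + 2pq * 0.5 * w_sr) + (1 - x)(p^2 + 2pq * 0.5)] / Wbar

with ``Wbar`` the sum of the p' and q' numerators, gives the allele frequency
after one round of exposure and reproduction. The per-generation selective
advantage of resistance is ``z = p'/p - 1``.

Bioassay mortalities map onto three interpretable model inputs:
*effectiveness* (SS mortality on exposure), *resistance restoration* (the
proportion of SS mortality prevented in the RR genotype) and *dominance* ``h``
(position of SR mortality between the SS and RR homozygotes; 0 = fully
recessive resistance, 1 = fully dominant). Iterating the recursion with fixed
mortalities yields a "time to resistance": the number of generations for
``p`` to reach a threshold frequency (conventionally 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMortalities",
    "FitnessSet",
    "SelectionContext",
    "ModelInputs",
    "SimulationResult",
    "DegeneratePopulationError",
    "UndefinedDominanceError",
    "fitness_from_mortality",
    "next_generation_frequency",
    "selective_advantage",
    "model_inputs_from_mortalities",
    "mortalities_from_model_inputs",
    "simulate_trajectory",
    "time_to_resistance",
]


class DegeneratePopulationError(ValueError):
    """Every genotype was killed: mean fitness is zero, p' undefined."""


class UndefinedDominanceError(ValueError):
    """Dominance has no meaning when SS mortality does not exceed RR mortality.

    Covers both the no-kill regime (window of selection shut) and the
    fitness-cost regime where resistant mortality exceeds susceptible.
    """


def _check_proportion(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class GenotypeMortalities:
    """Mortality proportions of the three genotypes under one exposure condition.

    ``m_rs`` is the reciprocal heterozygote (R mother x S father cross, or
    vice versa); when both heterozygote classes were assayed their mortalities
    are averaged with equal weight.
    """

    m_ss: float
    m_sr: float
    m_rr: float
    m_rs: float | None = None

    def __post_init__(self) -> None:
        _check_proportion(self.m_ss, "m_ss")
        _check_proportion(self.m_sr, "m_sr")
        _check_proportion(self.m_rr, "m_rr")
        if self.m_rs is not None:
            _check_proportion(self.m_rs, "m_rs")

    @property
    def heterozygote_mortality(self) -> float:
        """SR mortality, averaging reciprocal crosses when both are present."""
        if self.m_rs is None:
            return self.m_sr
        return 0.5 * (self.m_sr + self.m_rs)


@dataclass(frozen=True)
class FitnessSet:
    """Survival proportions of SS, SR and RR on exposure (w = 1 - mortality)."""

    w_ss: float
    w_sr: float
    w_rr: float

    def __post_init__(self) -> None:
        _check_proportion(self.w_ss, "w_ss")
        _check_proportion(self.w_sr, "w_sr")
        _check_proportion(self.w_rr, "w_rr")


@dataclass(frozen=True)
class SelectionContext:
    """Resistance allele frequency ``p`` and exposed fraction ``x``."""

    p: float
    x: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in (0, 1), got {self.p!r}")
        _check_proportion(self.x, "x")

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class ModelInputs:
    """Interpretable parameterization of one exposure condition.

    effectiveness
        SS mortality on exposure.
    restoration
        Proportion of SS mortality prevented in the RR genotype
        (1 means RR survives perfectly; 0 means resistance restores nothing).
    dominance
        h, position of SR mortality between SS (h=0) and RR (h=1).
    exposure
        x, fraction of the population contacting the insecticide per
        generation.
    clamped
        True when the observed SR mortality fell outside the [m_rr, m_ss]
        envelope (bioassay noise) and h was clamped into [0, 1].
    """

    effectiveness: float
    restoration: float
    dominance: float
    exposure: float
    clamped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        _check_proportion(self.effectiveness, "effectiveness")
        _check_proportion(self.restoration, "restoration")
        _check_proportion(self.dominance, "dominance")
        _check_proportion(self.exposure, "exposure")

    def fitnesses(self) -> FitnessSet:
        m = mortalities_from_model_inputs(self)
        return fitness_from_mortality(m)


@dataclass(frozen=True)
class SimulationResult:
    """Allele-frequency trajectory and generations to the threshold.

    ``generations_to_threshold`` is the first generation index at which the
    trajectory reaches ``threshold`` (trajectory[0] is the starting frequency,
    generation 0), or ``None`` when censored at ``max_generations``.
    """

    trajectory: np.ndarray
    threshold: float
    max_generations: int
    generations_to_threshold: int | None

    @property
    def censored(self) -> bool:
        return self.generations_to_threshold is None

    def display_generations(self) -> str:
        """``'17'`` or an explicit ``'>500'`` style censored marker."""
        if self.censored:
            return f">{self.max_generations}"
        return str(self.generations_to_threshold)


def fitness_from_mortality(m: GenotypeMortalities) -> FitnessSet:
    """Convert genotype mortalities to survival fitnesses.

    Fitness is the proportion of the genotype surviving exposure. Reciprocal
    heterozygotes, when both present, contribute the unweighted mean of their
    mortalities.
    """
    return FitnessSet(
        w_ss=1.0 - m.m_ss,
        w_sr=1.0 - m.heterozygote_mortality,
        w_rr=1.0 - m.m_rr,
    )


def next_generation_frequency(ctx: SelectionContext, w: FitnessSet) -> float:
    """One generation of the recursion; returns the updated R frequency p'.

    Raises :class:`DegeneratePopulationError` when the whole population dies
    (x = 1 with zero fitness for every genotype).
    """
    p, q, x = ctx.p, ctx.q, ctx.x
    num_p = x * (p * p * w.w_rr + 2 * p * q * 0.5 * w.w_sr) + (1 - x) * (
        p * p + 2 * p * q * 0.5
    )
    num_q = x * (2 * p * q * 0.5 * w.w_sr + q * q * w.w_ss) + (1 - x) * (
        2 * p * q * 0.5 + q * q
    )
    wbar = num_p + num_q
    if wbar == 0.0:
        raise DegeneratePopulationError(
            "mean fitness is zero: every genotype killed at full exposure"
        )
    return num_p / wbar


def _next_p_array(p: np.ndarray, x: np.ndarray, w_ss, w_sr, w_rr) -> np.ndarray:
    """Vectorised recursion used by property checks and profiles."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    num_p = x * (p * p * w_rr + p * q * w_sr) + (1 - x) * (p * p + p * q)
    num_q = x * (p * q * w_sr + q * q * w_ss) + (1 - x) * (p * q + q * q)
    return num_p / (num_p + num_q)


def selective_advantage(ctx: SelectionContext, w: FitnessSet) -> float:
    """Per-generation selective advantage of resistance, z = p'/p - 1.

    z is zero exactly when exposure or fitness differences are absent; it
    depends on p because p sets the relative abundance of the three genotypes
    and hence how much heterozygote fitness matters.
    """
    return next_generation_frequency(ctx, w) / ctx.p - 1.0


def model_inputs_from_mortalities(
    m: GenotypeMortalities, x: float
) -> ModelInputs:
    """Convert genotype mortalities to (effectiveness, restoration, dominance).

    Requires m_ss > m_rr strictly; otherwise dominance is undefined and an
    :class:`UndefinedDominanceError` carrying the offending mortalities is
    raised. SR mortality outside the [m_rr, m_ss] envelope (bioassay noise)
    clamps h into [0, 1] and sets the ``clamped`` flag rather than failing.
    """
    m_sr = m.heterozygote_mortality
    if m.m_ss <= m.m_rr:
        raise UndefinedDominanceError(
            f"dominance undefined: m_ss={m.m_ss} <= m_rr={m.m_rr} "
            "(window of selection shut or fitness-cost regime)"
        )
    effectiveness = m.m_ss
    restoration = (m.m_ss - m.m_rr) / m.m_ss if m.m_ss > 0 else 0.0
    h_raw = (m.m_ss - m_sr) / (m.m_ss - m.m_rr)
    h = min(1.0, max(0.0, h_raw))
    return ModelInputs(
        effectiveness=effectiveness,
        restoration=restoration,
        dominance=h,
        exposure=x,
        clamped=h != h_raw,
    )


def mortalities_from_model_inputs(inputs: ModelInputs) -> GenotypeMortalities:
    """Inverse map: (effectiveness, restoration, dominance) -> mortalities.

    Round-trips with :func:`model_inputs_from_mortalities` to better than
    1e-12 whenever m_ss > m_rr and the SR mortality lay inside the envelope.
    """
    m_ss = inputs.effectiveness
    m_rr = m_ss * (1.0 - inputs.restoration)
    m_sr = m_ss - inputs.dominance * (m_ss - m_rr)
    return GenotypeMortalities(m_ss=m_ss, m_sr=m_sr, m_rr=m_rr)


def simulate_trajectory(
    w: FitnessSet,
    x: float,
    p0: float,
    threshold: float = 0.5,
    max_generations: int = 500,
) -> SimulationResult:
    """Iterate the recursion with constant fitnesses until ``p >= threshold``.

    Returns the trajectory (generation 0 = p0) and the first generation index
    at or above the threshold, or a censored result after ``max_generations``.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must lie in (0, 1), got {p0!r}")
    if not (p0 < threshold < 1.0):
        raise ValueError(
            f"threshold must lie in (p0, 1), got {threshold!r} with p0={p0!r}"
        )
    traj = [p0]
    p = p0
    generations = None
    for gen in range(1, max_generations + 1):
        p = next_generation_frequency(SelectionContext(p=p, x=x), w)
        traj.append(p)
        if p >= threshold:
            generations = gen
            break
    return SimulationResult(
        trajectory=np.asarray(traj),
        threshold=threshold,
        max_generations=max_generations,
        generations_to_threshold=generations,
    )


def time_to_resistance(
    inputs: ModelInputs,
    p0: float,
    threshold: float = 0.5,
    max_generations: int = 500,
) -> SimulationResult:
    """Generations for the R allele to reach ``threshold``, from frequency p0.

    Mortalities (hence fitnesses) are held constant across generations: each
    exposure condition is simulated independently.
    """
    return simulate_trajectory(
        inputs.fitnesses(),
        inputs.exposure,
        p0,
        threshold=threshold,
        max_generations=max_generations,
    )
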