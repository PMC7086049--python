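# Methods

## Selection model

A single autosomal locus with alleles R (resistant) and S (susceptible) in a
large, randomly mating, discrete-generation population. Each generation a
fraction `x` of individuals contacts the insecticide; exposed individuals of
genotype g survive with probability `W_g = 1 − m_g`, where `m_g` is the
bioassay mortality of that genotype at the current concentration. Unexposed
individuals survive regardless of genotype (no fitness costs of resistance),
and random mating restores Hardy–Weinberg proportions every generation.
Sexes are not distinguished: one exposure probability applies to everyone.
The allele-frequency update is

    p′ = [x(p²W_rr + pqW_sr) + (1−x)(p² + pq)] / W̄,

with `W̄` the total surviving mass, and the selective advantage per
generation is `z = p′/p − 1` (z rather than a selection coefficient s, to
avoid collision with the S allele label). z depends on p because p sets how
much of the R allele sits in heterozygotes: at p = 10⁻⁴ essentially all of
it does, so z is dominated by heterozygote survival, which is what makes the
window of dominance decisive for rare alleles.

Mortalities convert to three interpretable inputs: effectiveness
(`m_ss`), restoration (`(m_ss − m_rr)/m_ss`, defined as 0 when `m_ss = 0` so
the no-kill regime has nothing to restore) and dominance
(`h = (m_ss − m_sr)/(m_ss − m_rr)`). When `m_ss ≤ m_rr` dominance has no
meaning — either no selection or selection against resistance — and the
conversion raises a typed error that profile code converts to an "undefined"
marker. An SR mortality outside the `[m_rr, m_ss]` envelope (routine in
noisy bioassays) clamps h into `[0, 1]` and sets a flag rather than failing.
When both reciprocal heterozygote crosses were assayed their mortalities are
averaged with equal weight before any calculation.

Time to resistance iterates the update with mortalities held constant — each
exposure condition is an independent scenario, not a trajectory through
decaying concentration — and reports the first generation at which
`p ≥ 0.5`, censored at 500 generations. Censoring is carried explicitly
(`>500` in report files, a boolean mask in profile objects), never as a
sentinel number.

Defaults throughout: `x = 0.3`, starting frequencies `p₀ ∈ {0.01, 10⁻⁴}`,
threshold 0.5, cap 500. All are overridable per call, via the YAML run
configuration, or on the command line.

## Window detection

A selection window is open where susceptible mortality exceeds resistant
mortality (strain arms R/S, or SS vs RR when genotype data are available) by
more than `delta`; a dominance window where, in addition, SS mortality
exceeds heterozygote mortality by more than `delta`. The default
`delta = 0` with strict inequality; noisy data can use a positive minimum
difference. Taking the pointwise minimum of the two margins for the
dominance criterion makes the dominance window a subset of the selection
window by construction, at any `delta`.

Concentration axes are processed on a log10 scale (windows span orders of
magnitude); time axes are linear. Boundaries are located by linear
interpolation of the margin between the last closed and first open grid
points on the transformed axis. Windows already open at the first observed
point, or not closed by the last, carry open-ended flags and report the
observed span. Reports present boundaries in deployment order — high→low
concentration, early→late time — while curves are stored ascending
internally, which makes profiles invariant to the row order of the input
table. If noise fragments the open region, the report spans the outermost
open points and sets a `fragmented` flag rather than choosing among
fragments.

Detection defaults to loess-smoothed series (tricube local linear
regression, span 0.75, no robustifying iterations, delegated to statsmodels'
`lowess`), since windows are judged against fitted mortality lines; a raw
mode exists for noise-free or pre-smoothed curves, and arms with fewer than
four observed points pass through unsmoothed with a warning flag. Fold-range
is always the larger boundary concentration over the smaller, hence ≥ 1
regardless of which boundary is labelled "opening". Missing mortalities can
be imposed as exact 0 or 1 over stated axis regions (the standard
extrapolation when an arm was not assayed where its outcome is certain);
rules never overwrite observed points — overlap is an error.

## Synthetic bioassays

The generator emulates the data this analysis consumes. Per-arm mortality
follows a log-logistic (Hill) curve on log10 concentration,
`floor + (ceiling − floor)/(1 + (LC50/c)^slope)` — the standard dose-response
model; probit curves are not implemented. Counts are binomial per replicate
with a per-call seed. Time axes are built by first-order decay
`c(t) = c₀·2^(−t/half_life)`, the conventional residual-insecticide model;
the decay is scenario plumbing, not a fitted claim. Fitting uses pooled
per-concentration proportions and `scipy.optimize.curve_fit` on
(log10 LC50, slope) with floor 0 and ceiling 1 fixed.

The idealized three-genotype scenario uses LC50s 0.01 / 0.1 / 1.0 (assay
units) with shared slope 3 and full 0–1 range, on a 25-point grid spanning
10⁻⁴–10²: a selection window of several decades with the dominance window
inside it, dominance rising from ≈0 at high concentration to ≈1 at low.
Scenario mortalities within 10⁻⁵ of the floor/ceiling are snapped to the
exact bound so the idealized curves genuinely attain 0% and 100% at the axis
extremes — 0.001% mortality is far below bioassay resolution, and without
the snap the asymptotic tails would keep the window technically open
everywhere. The best/intermediate/worst dominance scenarios share the SS and
RR envelopes and set the heterozygote to the SS curve (h ≡ 0), the idealized
SR curve, or the RR curve (h ≡ 1).

What the generator does not emulate: substrate chemistry, control-mortality
correction (Abbott), colony-health drift, overdispersion beyond binomial,
and any dependence between replicates. Tests passing on these fixtures
therefore demonstrate correctness of the machinery under the stated
statistical model, not robustness to every failure mode of real assay data.

## Numerical choices

- The recursion raises a typed degenerate-population error only in the exact
  total-kill case (`x = 1` and all fitnesses 0); elsewhere `W̄ > 0`.
- Agreement between the recursion and a brute-force six-mass allele-counting
  oracle is required to 10⁻¹², and `p′ + q′ = 1` to the same tolerance.
- Dominance-window/selection-window boundary checks against a 1000-point
  dense scan of the generating functions use `delta = 0.05`: noise-free
  log-logistic arms with ordered LC50s differ strictly everywhere, so a zero
  threshold would leave the window open across the whole axis and the
  comparison vacuous.
- Synthetic validation sizes: 25–30 point observation grids, 50 seeded
  curve geometries for boundary checks, 200 noisy draws for the subset
  invariant, 200 datasets (10 concentrations × 20 replicates × n = 100) for
  parameter recovery. These sizes give stable pass/fail behaviour across
  seeds while keeping the full suite under a few seconds.
- Report files are plain text, written with `repr` floats so identical
  inputs produce byte-identical output.

## Known limitations

Single-locus biallelic resistance only (polygenic architectures, multiple
resistance loci, and linkage are out of scope); no fitness costs of
resistance, so the model cannot represent reversion at sub-window
concentrations; no demography, density dependence, dispersal, or
disease-transmission consequences; no confidence intervals on window
boundaries — detection is deterministic given the (smoothed) series; and
concentration units are opaque labels, never converted.
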