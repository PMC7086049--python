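# resistwin

Quantitative analysis of **windows of selection and dominance** in the
evolution of insecticide resistance in disease vectors such as *Anopheles*
mosquitoes.

Persistent insecticides — sprayed on house walls or embedded in bednets —
start at concentrations high enough to kill every insect, then decay over
months or years. As the concentration falls, resistant insects begin to
survive while susceptible ones are still killed: the **window of selection**,
the concentration (or time-after-deployment) range over which resistance is
actively selected. Because insects are diploid, a rare resistance allele is
carried almost exclusively in heterozygotes, so selection at low allele
frequency is governed by the **window of dominance** — the sub-region of the
selection window where heterozygote mortality drops below that of susceptible
homozygotes. This package is for vector-biology and resistance-management
researchers who want to turn bioassay mortality data into measurements of
those windows and into predicted rates of resistance evolution.

## The model

Let `W_ss`, `W_sr`, `W_rr` be the probabilities that each genotype survives
exposure (fitness = 1 − mortality), `p` the resistance allele frequency
(`q = 1 − p`), and `x` the fraction of the population exposed each
generation. With Hardy–Weinberg genotype frequencies and no selection on the
unexposed,

    p′ = [ x(p²·W_rr + 2pq·½·W_sr) + (1−x)(p² + 2pq·½) ] / W̄

where `W̄` is the sum of the `p′` and `q′` numerators. The per-generation
**selective advantage** of resistance is `z = p′/p − 1`. Bioassay
mortalities map onto three interpretable inputs: *effectiveness* (SS
mortality), *resistance restoration* (fraction of SS mortality prevented in
RR) and *dominance* `h = (m_ss − m_sr)/(m_ss − m_rr)`. Iterating the
recursion with mortalities held fixed gives a **time to resistance**: the
number of generations for `p` to reach 50%, censored at 500.

On a mortality curve, the selection window is open wherever susceptible
mortality exceeds resistant mortality; the dominance window wherever, in
addition, heterozygote mortality falls below SS mortality. Windows are
measured as an x-fold concentration range or a duration in time units.

## Layout

- `src/resistwin/` — the library: `popgen` (recursion, z, time to
  resistance), `windows` (loess smoothing, curve completion, window
  detection, dominance/advantage/time profiles), `synth` (log-logistic
  dose-response, exponential concentration decay, binomial bioassay
  sampling, dominance scenarios), `io` (bioassay CSV tables, structured
  report files, run configuration) and `cli`.
- `analysis/` — numbered narrative drivers that run each stage and write
  tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers end to end.

## Worked example

```python
import numpy as np
from resistwin import synth, windows

axis = np.logspace(-4, 2, 25)                      # assay concentration grid
curve = synth.scenario_curves("intermediate", axis)  # idealized SS/SR/RR curves

sel = windows.detect_selection_window(curve, smoothed=False)
dom = windows.detect_dominance_window(curve, smoothed=False)
print(windows.window_metrics(sel).value)  # 316227.77 — fold-range of the selection window
print(windows.window_metrics(dom).value)  # 31622.78  — fold-range of the dominance window

prof = windows.resistance_time_profile(curve, x=0.3, p0_list=(1e-4,))
gens = np.where(prof.censored[1e-4], np.inf, prof.generations[1e-4])
print(int(gens.min()))                    # 31 — fastest time to 50% resistance
print(prof.dominance[int(np.argmin(gens))])  # 0.968 — dominance at that point
```

The fastest resistance evolution (31 generations from a starting frequency of
10⁻⁴) occurs where dominance is high — inside the window of dominance —
while every grid point outside the selection window is censored at >500
generations. Running `python analysis/02_selection_profiles.py` prints the
same numbers with the full profile written to `results/`.

The same machinery applies to real data: read a bioassay CSV with
`resistwin.io.read_bioassay_table` (columns `axis_kind, axis_value, arm` plus
either `dead, exposed` counts or `mortality_pct`), or use the `resistwin`
command line (`advantage`, `simulate`, `windows`, `profile`, `synth`).

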