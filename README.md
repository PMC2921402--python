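# dielcycle

Cell-cycle kinetics of light/dark-synchronized picocyanobacteria from flow
cytometry: DNA-histogram deconvolution, diel phase-timing and duration
estimation, cell-cycle-based growth rates, and comparative-CT expression
quantification — with a population simulator so every stage is testable
against known ground truth.

## The problem

Marine cyanobacteria such as *Prochlorococcus marinus* entrained to a
12 h/12 h modulated light/dark cycle divide in tight synchrony, following
the slow-growth case of the Cooper–Helmstetter model: at most one
chromosome replication round per day.  Each cell moves through a discrete
G1 phase (one chromosome copy), an S phase (replication), and a G2 phase
(two copies, not yet divided).  Sampling the culture hourly and staining
DNA (SYBR Green) yields one fluorescence histogram per timepoint; the
fractions of cells in each phase over the day carry the population's entire
division kinetics — including how stressors such as UV radiation shift the
timing of chromosome replication into the dark period.

## What the package computes

* **Phase fractions.** Each histogram is deconvolved with a constrained
  mixture (`PhaseMixtureModel`, a scikit-learn-style estimator): Gaussian G1
  and G2 peaks with the G2 position fixed at twice the G1 position, plus a
  Dean–Jett–Fox-style S component (a rectangle of DNA content between the
  peaks, broadened by the measurement CV), fitted by Poisson deviance.

* **Phase timing and durations.** With peaks of the diel `f_S` and `f_G2`
  curves at clock times `t_Smax` and `t_G2max` (circular arithmetic, mod
  24 h), the summed duration is `T_S + T_G2 = 2 (t_G2max − t_Smax)`; the
  split between `T_S` and `T_G2` follows the areas under the two curves,
  and `T_G1 = 24 ln2 / μ_cc − (T_S + T_G2)` from the generation-time
  identity.

* **Growth rates.** The cell-cycle estimator of Carpenter & Chang,

      μ_cc = (24 / (n (T_S + T_G2))) · Σᵢ ln(1 + f_S(tᵢ) + f_G2(tᵢ)),

  from `n` samples at fixed intervals over one diel cycle, and the
  count-based estimator `μ_nb = ln(N₂/N₁) · 24/Δt` over a no-division
  window, plus their percent bias.

* **Relative expression.** ΔΔCT quantification of diel qPCR panels
  (*rnpB*-normalized, HL 06:00 calibrator), `RQ = 2^−ΔΔCT`, with a strict
  `|log₂ FC| > 1` differential-expression call.

* **Synthetic populations.** `simulate_population` generates entrained
  populations (per-cell S-entry times drawn around a mean clock hour,
  per-traversal phase durations, division, optional arrest and continuous
  dilution) and a measurement model turns snapshots into fluorescence
  events.  Default scenarios encode the canonical phenomenology: under HL
  the S-cell peak falls exactly at the light-to-dark transition (18:00);
  under HL+UV the replication wave is shifted 2 h into the dark period.

## Worked example

```python
import dielcycle as dc
from dielcycle import growth, histfit, timing

scenario = dc.default_scenarios()["HL"]
result, samples = dc.simulate_scenario(scenario, n_days=2, n_events=100_000, seed=1)

series = histfit.fractions_series(samples)          # 48 histogram fits
peaks = timing.find_phase_peaks(series)
t_sum = 2.0 * peaks.delta_t                         # T_S + T_G2 = 2 * delta_t
cc = growth.mu_cc(series, t_sum)
durations = timing.estimate_phase_durations(peaks, series, cc.mean)
_, nb_mean, _ = growth.mu_nb_from_counts(result.counts)
```

prints, via the obvious format strings:

```
S peak 17.96 h, G2 peak 21.52 h, delta_t 3.56 h
T_S+T_G2 = 7.11 h -> T_S 3.47 h, T_G2 3.64 h, T_G1 16.4 h
mu_cc 0.707 +/- 0.028 d-1, mu_nb 0.665 d-1, bias 6.3%
```

The fitted S-phase peak lands at the light-to-dark transition (18:00) as
built into the scenario; `μ_cc ≈ 0.71 d⁻¹` corresponds to slightly less
than one division per cell per day (5% of cells arrest), and the
cell-cycle estimate runs a few percent above the count-based one, the known
direction of its bias.

The same pipeline is available from the shell:

```sh
dielcycle run-scenario --seed 1 --out out/
# -> "S-phase lag (HL+UV relative to HL): 2.02 h"
```

## Layout

```
src/dielcycle/
  schedule.py   half-sine diel PAR/UV irradiance programs
  simulate.py   entrained-population simulator + measurement model
  histfit.py    constrained-mixture histogram deconvolution
  timing.py     peak timing, durations, synchrony index, condition lag
  growth.py     mu_cc / mu_nb estimators and their comparison
  qpcr.py       comparative-CT relative quantification
  reference.py  published growth-parameter tables (consistency checks)
  io.py, cli.py TSV/YAML I/O and the `dielcycle` command-line tool
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
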