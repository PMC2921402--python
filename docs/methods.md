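# Methods

## Population model

The simulator implements an entrainment model of the prokaryotic
slow-growth cell cycle.  Each day, every non-arrested cell draws an S-entry
time from `Normal(s_onset_clock, sigma_sync)` and S/G2 durations from
`Normal(t_s, jitter_s)` / `Normal(t_g2, jitter_g2)` (floored at 0.05 h);
division at `entry + T_S + T_G2` replaces the cell by two G1 daughters, who
join the next day's wave.  A cell performs at most one traversal per 24 h.
`frac_arrested` is the per-day probability of skipping the traversal
entirely (remaining G1), which sets the realized division rate to
`ln(2(1−f)+f)` per day.  Continuous mode assigns every cell an exponential
washout clock at rate `dilution_rate/24 h⁻¹`; a culture diluted faster than
it divides goes extinct, which raises an explicit error.

Entry into S is gated by *clock time*, not by irradiance dose: diel
experiments show the replication wave locked to the light/dark cycle, but
no quantitative dose–response is available to justify a photophysiological
mechanism, so the light schedule (half-sine PAR/UV between dawn and dusk)
is carried as scenario metadata only.

`s_onset_clock` is the **mean** S-entry time.  Because the entry
distribution is symmetric and S duration is (nearly) fixed per cell, the
S-fraction curve peaks at `s_onset_clock + T_S/2`; the first cells of the
wave appear about `2·sigma_sync` before the mean.  The default HL scenario
(onset 16:00, `T_S = T_G2 = 4 h`, `sigma_sync = 1 h`, dusk 18:00) therefore
puts the first S cells near 14:00, the S peak at the light-to-dark
transition and the G2 peak 4 h later; the default HL+UV scenario is the
same population shifted 2 h later (onset 18:00, S peak 20:00), the
canonical UV response.  The LL scenario uses onset 15:00, durations
4.1/3.9 h and 46% arrest (division rate ≈ 0.43 d⁻¹).  Defaults
`frac_arrested = 0.05` (≈ 0.67 d⁻¹), `n0 = 10⁴` cells.  An optional
two-component onset mixture was considered for the small pre-dusk S
shoulder seen in some continuous cultures and rejected: one component
reproduces everything the downstream estimators consume.

The measurement model draws cells uniformly (with replacement by default)
and reports `gain · DNA · (1 + ε)`, `ε ~ Normal(0, cv)`, with DNA = 1 in
G1, 2 in G2, linear in S.  Defaults `gain = 200 a.u.`, `cv = 0.03`
(a tight SYBR-stained picocyanobacterial peak); optional exponential
debris below the G1 peak, off by default (axenic cultures).

### What the generator does not emulate

No photodamage or mortality kinetics beyond arrest; no aggregates/doublets;
no multi-ploidy (>2C); no drift of instrument gain within a run.  Passing
tests therefore demonstrate correctness of the *estimators* under the
stated statistical model, not robustness to every artifact of real
cytometry.

## Histogram deconvolution

Model per histogram (linear binning, out-of-range events counted and
reported): `f_G1·N(m, cv·m) + f_G2·N(r·m, cv·r·m) + f_S·S(m, r·m)` with the
S component a single rectangle of DNA content spanning `(m, r·m)`,
discretized into `n_s_segments = 8` equal-width uniform segments, each
convolved analytically with the Gaussian measurement kernel at its own
midpoint CV (uniform⊗normal CDF, not a Gaussian comb — avoids ripple
artifacts).  `r` is fixed at exactly 2.0 by default (a G2 cell carries two
chromosome copies); a flag frees it within [1.9, 2.1].

Estimation: the fractions enter linearly, so an inner EM computes the
multinomial weight MLE for fixed shape parameters, and an outer Nelder-Mead
minimizes the Poisson deviance over `(log m, log cv)` (chi-square with
variance `max(count, 1)` available for parity with legacy software).
Initialization takes the two largest local maxima whose position ratio is
near 2 (else the single largest) for `m`; `cv` starts at 0.05, bounded in
[1e-4, 0.3].  A stalled optimizer returns `converged = False` rather than
raising; a histogram with all mass in one bin is rejected as degenerate.
Goodness of fit is the reduced deviance.  The fit is invariant to global
rescaling of the fluorescence axis.

**Series fitting** (`fractions_series`) is two-pass by default: free fits
per timepoint, then a refit with `m` pinned at the median fitted G1
position.  The G1 position is an instrument property and must not drift
between timepoints; pinning it stabilizes the timepoints where a tightly
synchronized S cohort crowds one end of the G1–G2 interval.

**Limitation.** The equal-weight rectangle assumes S-cell DNA content is
uniform over (1C, 2C).  In a *strongly* synchronized population at the
edges of the wave, S cells concentrate near one end and per-timepoint
fractions are biased (the wave's *shape* and peak time remain accurate,
and between-condition lags cancel the bias entirely).  Recovery accuracy
(±0.02 at 10⁵ events, cv 0.03) is asserted against samples whose S cells
are uniform in DNA content, which is the model's own operating assumption.

## Timing and durations

Curves are folded onto the 24 h clock (mean across days), optionally
smoothed with a centered circular moving average (default 3 points; use 1
for noiseless truth series).  Peaks are the argmax refined by a quadratic
through the three surrounding points, ties breaking toward the earlier
time; a curve whose maximum does not exceed its minimum by twice the
median point-to-point step is declared flat ("no replication wave").

`T_S + T_G2 = 2·Δt` with `Δt = (t_G2max − t_Smax) mod 24`.  The split of
the sum between `T_S` and `T_G2` is proportional to the baseline-subtracted
areas under the folded `f_S` and `f_G2` curves — a deterministic,
documented convention; the peak-delay rule itself only fixes the sum.
`T_G1 = 24 ln2/μ_cc − (T_S+T_G2)`: in balanced exponential growth the
generation time is `24 ln2/μ_cc` hours, and this reconstruction reproduces
the published batch-culture `T_G1` values to ≈ 0.1 h at μ ≈ 0.7 d⁻¹ (the
printed two-decimal rounding of μ propagates as `24 ln2 · 0.005/μ²`, up to
±0.4 h for the slowest columns, which sets the regression tolerance).

**Synchronization index.** The S-entry distribution is reconstructed as
the positive part of the circular derivative of the folded `f_S` curve
(entries raise `f_S`; exits lower it), and summarized by its circular
angular deviation `sqrt(2(1−R))` expressed as a percentage of the cycle:
`S_r = 100·sqrt(2(1−R))/2π`, 0 for a delta-function wave, ≈ 22.5 for
uniform entry, monotone in the entry spread.  Published synchronization
indices from proprietary software use an unknown formula and are **not**
numerically comparable; this metric is pluggable and labeled in output.

**Condition lag.** `estimate_delay` mean-subtracts the folded curves,
computes the circular cross-correlation at grid lags, refines the maximum
quadratically and reports hours in (−12, 12], positive when the second
series is later.  It is antisymmetric and exact for pure grid shifts.

## Growth rates

`μ_cc` requires samples at fixed intervals covering each full cycle
(irregular grids are rejected unless circular linear resampling is
requested); multi-day series yield per-day estimates, reported as
mean ± mean absolute deviation — the convention used for duplicate
cultures — rather than pooling days.  `μ_nb` pairs counts at a fixed
early-morning clock hour (default 06:00, when essentially all cells are in
G1) on consecutive days, averaging replicate cultures before the ratio.
The percent bias `100(μ_cc/μ_nb − 1)` is reported as observed; no
correction model is applied.

## ΔΔCT quantification

Amplification efficiency is fixed at 2.0 (the comparative-CT assumption;
no efficiency calibration data).  Technical duplicates are averaged on the
CT scale before differencing — where biological averaging happened in
published panels is unstated, so the CT-scale choice is implemented and
labeled.  Duplicate spread (mean absolute deviation) propagates to an RQ
interval by interval arithmetic.  The differential-expression call is the
strict `|log₂FC| > 1`.  The shipped primer table is metadata for input
validation only.

## Problem sizes and determinism

Default analysis scale — 10⁴ cells, 10⁵ events per timepoint, hourly
sampling over two diel cycles — resolves phase fractions to well under a
percentage point per timepoint while a full two-condition pipeline run
completes in tens of seconds on one CPU; the test suite uses smaller
populations where the property under test permits.  Every stochastic stage
takes an explicit seed; population and measurement streams are split via
`SeedSequence` spawning so that changing the event count does not perturb
the population.  Identical seeds and parameters give bit-identical output.
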