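# Methods

## Rate calculation

Each trial is segmented from t = 0 into (measure, flush) cycles — default
6 min sealed + 4 min flush — with half-open windows `[start, end)` on a
seconds time base; a trailing partial cycle is dropped. Within each
measurement window the O2 depletion slope is the negated least-squares
slope of concentration against time (per minute), with an optional
`trim_s` discarding mixing transients at the window start (default 0:
the full phase is used). Windows with fewer than three samples after
trimming are flagged invalid and excluded. The mass-specific rate is

    MO2 = (s_fish · (V − M) − s_bg · V) / M,

the whole bracketed difference divided by mass, which is the reading that
yields mg O2 kg⁻¹ min⁻¹; the fish displaces its own volume of water at
density 1 (V − M term, kg read as litres). Background respiration is
measured by the same slope estimator on empty-chamber traces before and
after the trial block and interpolated linearly in time by default
(constant mode available); negative evaluated backgrounds are clamped to
zero, since microbial respiration cannot add oxygen. An r² floor on
windows exists but defaults to disabled — all windows are kept.

## Traits

- SMR: mean of the lowest `max(1, round(0.2·N))` of all N per-cycle rates,
  with half-up rounding; the rule is applied over the whole trial
  including the post-chase period (for overnight trials the lowest subset
  falls after recovery anyway), and the temperature reported for SMR is
  the mean over the same entries.
- MMR: maximum per-cycle rate; its timestamp is the recovery clock's t=0.
  Note the per-cycle value is a 6-min average, so the reported MMR sits
  slightly below the instantaneous post-chase peak.
- RMR: post-recovery entries binned by mean window temperature into 1 °C
  bins centred on integers (width configurable); bins with fewer than 3
  measurements per fish are dropped.
- Q10 = (R2/R1)^(10/(T2−T1)). For group-level reporting the rates are
  watershed means at the lowest ambient temperature and the warmest
  treatment.
- Mass scaling: OLS of ln(whole-animal rate) on ln(mass); "no mass
  correction needed" when the 95% CI of the slope contains 1 — the
  isometry point of a mass-specific formulation. The criterion is a
  package choice; the t-based CI is degenerate for exact fits, so the
  containment test carries a 1e-9 numerical guard.

## Recovery kinetics

A cubic smoothing spline is fitted to the per-cycle rates with the
roughness penalty chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`), overridable for
reproducibility studies; the smoother choice is recorded in the output.
Crossing times are located on a 1-s evaluation grid with bisection
refinement between the bracketing points; only the first downward
crossing counts (later noise re-crossings are ignored). Time[MMR50] uses
threshold 0.5·MMR; EPOC end uses 1.2·SMR ("20% above SMR"). A curve
already below a threshold at t=0 gives 0; a curve that never crosses is
flagged. When the thresholds overlap (0.5·MMR ≤ 1.2·SMR) the half-MMR
criterion is capped at the EPOC-end time, so a fish that never left the
recovered band reports both times as 0.

## Thermal risk

TSM = CTmax − MWMT per fish; the group TSM is the mean of per-fish TSMs,
which equals mean CTmax minus the single site MWMT. T_pejus is fitted per
watershed by pooling per-fish (mean test temperature, FAS) points across
treatments — each fish experiences one treatment, so a per-fish fit is
not possible — and inverting FAS = a + b·T at the threshold (default
FAS = 3, configurable for other species/life stages). The inversion is
undefined when b ≥ 0, and also when b < 0 but not significantly below
zero (one-sided t, α = 0.05, disable-able via `slope_alpha=None`): with a
genuinely flat FAS response plus sampling noise, the raw b ≥ 0 rule
returns an arbitrary far extrapolation (~100 °C in cohort simulations)
roughly half the time, which is scientifically meaningless; the
significance gate reproduces the "stable FAS ⇒ no T_pejus" outcome
robustly. Crossings outside the observed temperature range carry an
extrapolation flag. WT = T_pejus − MWMT, with undefined propagating.
Treatment temperatures and MWMT values in the packaged site table are
data, not derived values (the Climate − Max offset is 3 °C at the coastal
sites but 5 °C at the Willamette-basin sites as run).

## Group statistics

Kruskal–Wallis is computed on midranks with the standard tie-correction
divisor; the all-constant degenerate case (correction factor 0) adopts
H = 0, p = 1. Dunn's z uses the tie-corrected pooled-rank variance with
two-sided normal p-values; the default multiplicity adjustment is none
(Bonferroni and Holm offered). One-way ANOVA uses the classical
between/within decomposition; zero within-group variance gives F = 0 for
equal means and an infinite F otherwise. The RMR model
ln(RMR) = slope·T + intercept[watershed] is ordinary least squares with
watershed dummies — a fixed-effects approximation in which treatment and
fish random intercepts are absorbed into the residual; simulation tests
show the slope is recovered within ±10% at cohort scale under per-fish
intercept noise of 0.1 on the log scale. α = 0.05 throughout.

## Synthetic data generator

The generator emulates the stream-side study design: four watersheds
(two warm coastal, two cool interior), three treatments per watershed
(Ambient = diurnal sinusoid around the stream mean with half-amplitude
1.5 °C peaking at 16:45, trials starting at 09:30; Max and Climate =
constant heated temperatures from the site table), 8 fish per treatment,
one overnight trial per fish with duration drawn as a whole number of
cycles between 18 and 24 h (108–144 measurement phases). Instantaneous
consumption is SMR_ref·Q10^((T−T_ref)/10) plus a post-chase excess
E0·epoc_q10^((T−T_ref)/10)·e^(−kt). Chamber O2 declines during sealed
phases at the implied rate plus background and relaxes exponentially to a
fixed 9.0 mg/L saturation ceiling during flushes (time constant 1 min, so
flushing is effectively complete); i.i.d. Gaussian probe noise is added
per sample. Background slope is set so that its ratio to the fish-only
depletion slope equals the configured fraction, drawn per trial from
0.15–2.1%. Body sizes are drawn as fork length ~ N(130, 12) mm and
condition factor ~ N(1.00, 0.03), giving masses near 23 g and ≥95% of K
in [0.93, 1.13]. Ambient fish additionally receive a CTmax trial:
loss-of-equilibrium temperature ~ N(mean, sd) truncated below at the ramp
start, time implied by the 0.3 °C/min ramp.

Per-watershed truth parameters are fixed in `default_scenario` from the
study regimes: SMR Q10 of 3.25 / 2.02 / 1.17 / 2.01 (Alsea, Siletz,
McKenzie, N. Santiam), CTmax means of 29.78 / 30.38 / 27.25 / 27.29 °C
(the McKenzie with a large 2.3 °C spread), and excess magnitudes chosen so
ambient FAS is highest (~12) in the coldest site and recovery to half-MMR
takes 10–25 min. `epoc_q10` controls how burst capacity scales with
temperature: set equal to the SMR Q10 for the McKenzie it yields a flat
FAS (no definable T_pejus); below the SMR Q10 (Alsea, 0.7) it produces a
declining FAS and a slight MMR drop at the warmest treatment.

Randomness: one root seed; each fish gets an independent stream seeded
deterministically from (root seed, fish_id bytes), so cohorts are
reproducible fish-by-fish and byte-identical across runs.

What the generator does *not* emulate: probe drift and calibration error,
incomplete chamber mixing, spontaneous activity bursts (the post-recovery
rate is exactly the temperature-scaled SMR plus noise, so simulated
RMR ≈ SMR), digestion effects, multi-fish interactions, or
temperature-dependent oxygen solubility. Passing round-trip tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every field artefact; the activity-free
assumption in particular makes simulated FAS declines steeper than field
values (~55% vs ~48% for the N. Santiam) since nothing inflates SMR
estimates at cold temperatures.

## Problem sizes and numerical choices

Trial simulation defaults to 1 Hz sampling (the probe frequency is an
assumption); cohort-scale runs in the pipeline and tests use 5-s sampling
(72 samples per 6-min window), which leaves slope standard errors far
below the signal while keeping a full 96-fish cohort simulation and
analysis around 15 s. Empty-chamber background runs are simulated as
12-cycle (2 h) traces and averaged across windows because the microbial
signal (~5×10⁻⁴ mg L⁻¹ min⁻¹) is smaller than the single-window slope
error at realistic probe noise. Euler integration with the per-sample
step is exact for the piecewise-constant-slope noiseless cases used as
oracles. Monte-Carlo calibration tests use 200–5000 replicates depending
on the tolerance being checked.
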