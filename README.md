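# streamresp

Stream-side intermittent-flow respirometry analysis for field-acclimatized
fish: from raw dissolved-oxygen traces to per-fish metabolic traits and
population-level thermal-risk metrics.

The package is aimed at ecophysiologists running portable respirometry
systems on wild salmonids (or similar ectotherms): a fish is exhausted by a
standardized chase, sealed in a small chamber, and its oxygen uptake is
recorded overnight through alternating sealed *measurement* phases and
*flush* phases. From one such trace the package derives the fish's
metabolic phenotype; from a cohort of trials across temperature treatments
and watersheds it derives how close each population lives to its thermal
limits.

## What it computes

Per measurement phase, the mass-specific oxygen consumption rate
(mg O2 kg⁻¹ min⁻¹) with background (microbial) correction:

    ṀO2 = [Δ[O2]_fish · (V_chamber − M) − Δ[O2]_background · V_chamber] / M

where Δ[O2] are least-squares O2 depletion slopes (mg O2 L⁻¹ min⁻¹),
V_chamber the respirometer volume (L) and M the fish mass (kg).

Per fish:

- **SMR** — standard metabolic rate, the mean of the lowest 20% of all
  recorded ṀO2 values (with the mean temperature of that subset);
- **MMR** — maximum metabolic rate, the highest recorded ṀO2 (elicited
  immediately after a 3-min chase + 30-s air exposure);
- **AAS = MMR − SMR** and **FAS = MMR/SMR** — absolute and factorial
  aerobic scope;
- **Time[MMR50]** and **time to EPOC end** — minutes to fall to 0.5·MMR
  and hours to return to 1.2·SMR, read off a generalized-cross-validated
  smoothing spline through the ṀO2 series;
- **RMR** — routine metabolic rate per 1 °C temperature bin after recovery
  (bins with <3 measurements dropped), and **Q10 = (R2/R1)^(10/(T2−T1))**;
- **Fulton's K = 100000·M/L³** and an allometric mass-scaling check
  (ln rate vs ln mass regression).

Per population (watershed), against the maximum weekly maximum stream
temperature (MWMT, baseline and 2080 projection):

- **TSM = CTmax − MWMT** — thermal safety margin before lethality, with
  CTmax the loss-of-equilibrium temperature under a 0.3 °C/min ramp;
- **T_pejus** — the temperature where a linear FAS-vs-temperature fit
  crosses FAS = 3 (undefined when FAS is stable or rising);
- **WT = T_pejus − MWMT** — functional warming tolerance before
  performance impairment.

Group comparisons (Kruskal–Wallis with Dunn's post hoc, one-way ANOVA,
log-linear RMR model with per-watershed intercepts) are implemented from
first principles and cross-checked against independent oracles in the test
suite.

A synthetic-data module generates complete trials, CTmax ramps and
multi-watershed cohorts from known ground truth (temperature-scaled SMR +
exponentially decaying post-chase excess, diurnal ambient profiles, probe
noise, background respiration at 0.15–2.1% of fish respiration), so every
stage of the pipeline is testable without field data.

## Worked example

```python
from streamresp import (SimFishTruth, TrialDesign, simulate_trial,
                        constant_profile, CyclePlan, BackgroundModel,
                        build_mo2_series, estimate_smr, estimate_mmr,
                        aerobic_scope, recovery_metrics, thermal_safety_margin)

truth = SimFishTruth(fish_id="demo", mass_g=22.8, fork_length_mm=130.2,
                     smr_ref=2.0, t_ref_c=18.0, q10_true=2.0,
                     epoc_magnitude=8.0, epoc_rate_k=0.1,
                     ctmax_true_mean=30.4, ctmax_true_sd=0.2)
design = TrialDesign(duration_h=18.0, sample_interval_s=5.0, noise_sd=0.01,
                     background_fraction=0.01, seed=42)
trace, gt = simulate_trial(truth, design, constant_profile(18.0))

bg = BackgroundModel(pre_slope=gt.background_slope, post_slope=gt.background_slope)
series = build_mo2_series(trace, CyclePlan(), bg, mass_kg=truth.mass_g / 1000)
smr, smr_temp, smr_n = estimate_smr(series)
mmr, mmr_time, _ = estimate_mmr(series)
aas, fas = aerobic_scope(smr, mmr)
rec = recovery_metrics(series, smr, mmr, mmr_time)
```

Output:

```
cycles analysed : 108
SMR             : 1.937 mg O2/kg/min (lowest 22 of 108 cycles)
MMR             : 8.042 mg O2/kg/min
AAS, FAS        : 6.105, 4.15
Time[MMR50]     : 10.6 min
EPOC end        : 0.52 h
TSM (CTmax 30.4, MWMT 18.87): 11.53 C
```

The 18-h trial contains 108 ten-minute cycles. The estimated SMR (1.937)
sits just under the generating value of 2.0 because the lowest-20% rule
selects downward noise excursions; MMR (8.04) is the cycle-averaged peak of
the post-chase excess; the fish is back to half its maximum rate in ~11 min
and fully recovered (within 20% of SMR) in ~31 min. A CTmax of 30.4 °C
against an 18.87 °C MWMT leaves an 11.5 °C safety margin.

## Command line

```sh
streamresp all --seed 1 --outdir run1          # simulate + full analysis
streamresp simulate --seed 1 --outdir sim1     # write traces + truth tables
streamresp process --metadata meta.csv --outdir out   # analyse recorded traces
```

`all` writes `traits.csv`, `recovery.csv`, `rmr.csv`, `risk.csv`,
`stats.csv`, `pairwise.csv`, `failures.csv` and a `manifest.json`
recording the seed and a hash of every tunable; identical configs
reproduce identical outputs byte for byte. A YAML config file
(`--config`) supplies any `RunConfig` field; flags override it.

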