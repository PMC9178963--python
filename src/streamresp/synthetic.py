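"""Synthetic stream-side respirometry trials with known ground truth.

Every downstream stage (trace processing, trait estimation, recovery
kinetics, thermal risk, group statistics) is testable without field
data: this module generates whole oxygen traces from a parametric fish
model and an intermittent-flow trial design, plus critical-thermal-
maximum trials and full multi-watershed cohorts.

The fish model: instantaneous oxygen consumption is

    MO2(t, T) = SMR_ref * q10**((T - T_ref)/10)
              + E0 * epoc_q10**((T - T_ref)/10) * exp(-k * t)

i.e. a temperature-scaled standard metabolic rate plus an exponentially
decaying excess post-exercise component (the fish enters the chamber
immediately after an exhaustive chase, so MO2 starts near its maximum
and relaxes toward routine levels). Chamber oxygen declines during
sealed measurement phases at the rate implied by this consumption (the
fish displaces its own volume of water), background microbial
respiration adds a small constant depletion, and flush phases relax the
chamber back toward air saturation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .thermal import CTmaxRecord, ThermalContext, DEFAULT_SITES
from .traces import O2Trace

__all__ = [
    "SimFishTruth",
    "TrialDesign",
    "TrialGroundTruth",
    "diurnal_profile",
    "constant_profile",
    "simulate_trial",
    "simulate_background_trial",
    "simulate_ctmax",
    "WatershedScenario",
    "CohortScenario",
    "CohortDataset",
    "default_scenario",
    "simulate_cohort",
]

TREATMENTS = ("Ambient", "Max", "Climate")


def _fish_rng(root_seed: int, fish_id: str) -> np.random.Generator:
    """Deterministic per-fish stream derived from (root seed, fish_id)."""
    return np.random.default_rng((int(root_seed), *fish_id.encode("utf-8")))


@dataclass
class SimFishTruth:
    """Generative parameters for one simulated fish.

    ``smr_ref`` is the standard metabolic rate (mg O2 kg^-1 min^-1) at
    reference temperature ``t_ref_c``; ``q10_true`` scales it to other
    temperatures. ``epoc_magnitude`` is the post-chase excess above SMR
    at t=0 (at ``t_ref_c``) decaying at ``epoc_rate_k`` per minute;
    ``epoc_q10`` optionally temperature-scales the excess (1 = burst
    capacity independent of temperature).
    """

    fish_id: str
    mass_g: float
    fork_length_mm: float
    smr_ref: float
    t_ref_c: float
    q10_true: float
    epoc_magnitude: float
    epoc_rate_k: float
    ctmax_true_mean: float
    ctmax_true_sd: float
    epoc_q10: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass must be positive")
        if self.smr_ref <= 0:
            raise ValueError("reference SMR must be positive")
        if self.q10_true < 1:
            raise ValueError("Q10 below 1 not supported by the generator")
        if self.epoc_magnitude < 0:
            raise ValueError("EPOC magnitude cannot be negative")
        if self.epoc_rate_k <= 0:
            raise ValueError("EPOC decay constant must be positive")

    def smr_at(self, temp_c) -> np.ndarray | float:
        return self.smr_ref * self.q10_true ** ((np.asarray(temp_c) - self.t_ref_c) / 10.0)

    def mo2_true(self, t_min, temp_c) -> np.ndarray | float:
        """Instantaneous oxygen consumption (mg O2 kg^-1 min^-1)."""
        t_min = np.asarray(t_min, dtype=float)
        excess = (
            self.epoc_magnitude
            * self.epoc_q10 ** ((np.asarray(temp_c) - self.t_ref_c) / 10.0)
            * np.exp(-self.epoc_rate_k * t_min)
        )
        return self.smr_at(temp_c) + excess


@dataclass(frozen=True)
class TrialDesign:
    """Intermittent-flow trial layout and instrument model.

    Defaults follow the stream-side protocol: 2-L chambers, 6-min
    sealed measurement + 4-min flush cycles over an 18-24 h overnight
    trial, oxygen sampled at 1 Hz. ``background_fraction`` expresses
    microbial (empty-chamber) respiration as a fraction of the fish's
    trial-mean respiration. Flush is exponential relaxation toward air
    saturation with time constant ``flush_tau_s``.
    """

    duration_h: float = 24.0
    measure_min: float = 6.0
    flush_min: float = 4.0
    sample_interval_s: float = 1.0
    chamber_volume_l: float = 2.0
    noise_sd: float = 0.02
    background_fraction: float = 0.01
    diurnal_amplitude_c: float = 1.5
    diurnal_phase: float = 16.75
    seed: int = 0
    o2_saturation_mg_per_l: float = 9.0
    flush_tau_s: float = 60.0

    def __post_init__(self) -> None:
        if self.chamber_volume_l <= 0:
            raise ValueError("chamber volume must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd cannot be negative")
        if self.sample_interval_s <= 0:
            raise ValueError("sample interval must be positive")

    @property
    def cycle_s(self) -> float:
        return (self.measure_min + self.flush_min) * 60.0

    @property
    def n_cycles(self) -> int:
        return int(round(self.duration_h * 3600.0 / self.cycle_s))


@dataclass
class TrialGroundTruth:
    """Realized generative quantities for one simulated trial."""

    fish_id: str
    smr_ref: float
    t_ref_c: float
    q10_true: float
    epoc_magnitude: float
    epoc_rate_k: float
    mean_mo2_true: float
    background_slope: float
    background_fraction: float
    mass_kg: float


def diurnal_profile(
    mean_c: float,
    amplitude_c: float = 1.5,
    peak_hour: float = 16.75,
    start_hour: float = 9.5,
) -> Callable[[np.ndarray], np.ndarray]:
    """Sinusoidal ambient stream temperature as a function of trial time.

    ``amplitude_c`` is the half-range of the diurnal cycle; the peak
    occurs at ``peak_hour`` clock time (streams here peak between 15:30
    and 18:00) and the trial starts at ``start_hour`` (fish are chased
    and chambered mid-morning).
    """

    def profile(t_s):
        clock_h = start_hour + np.asarray(t_s, dtype=float) / 3600.0
        return mean_c + amplitude_c * np.cos(2 * np.pi * (clock_h - peak_hour) / 24.0)

    return profile


def constant_profile(temp_c: float) -> Callable[[np.ndarray], np.ndarray]:
    """Constant-temperature profile (heated Max/Climate treatments)."""

    def profile(t_s):
        return np.full_like(np.asarray(t_s, dtype=float), temp_c)

    return profile


def _check_design(design: TrialDesign) -> None:
    n = design.duration_h * 3600.0 / design.cycle_s
    if abs(n - round(n)) > 1e-9 or round(n) < 1:
        raise ValueError(
            f"trial duration ({design.duration_h} h) is not a whole number of "
            f"{design.measure_min}+{design.flush_min} min cycles"
        )


def simulate_trial(
    truth: SimFishTruth,
    design: TrialDesign,
    temp_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[O2Trace, TrialGroundTruth]:
    """Generate one intermittent-flow trial trace.

    The trace alternates measurement and flush phases starting with a
    measurement phase (the post-chase fish is sealed in immediately).
    During measurement, chamber O2 declines at the rate implied by the
    fish's instantaneous MO2 plus background respiration; during flush
    it relaxes exponentially toward air saturation. Gaussian probe
    noise is added to every sample. Identical seeds give identical
    traces.
    """
    _check_design(design)
    if temp_profile is None:
        temp_profile = diurnal_profile(truth.t_ref_c, design.diurnal_amplitude_c,
                                       design.diurnal_phase)
    if rng is None:
        rng = np.random.default_rng(design.seed)

    dt = design.sample_interval_s
    duration_s = design.duration_h * 3600.0
    n = int(round(duration_s / dt))
    times = np.arange(n) * dt
    temps = np.asarray(temp_profile(times), dtype=float)
    if temps.shape != times.shape or not np.all(np.isfinite(temps)):
        raise ValueError("temperature profile must be finite over the whole trial")

    mass_kg = truth.mass_g / 1000.0
    vol = design.chamber_volume_l
    if not 0 < mass_kg < vol:
        raise ValueError("fish mass (kg) must be below chamber volume (L)")
    water_l = vol - mass_kg

    mo2 = np.asarray(truth.mo2_true(times / 60.0, temps), dtype=float)
    mean_mo2 = float(np.mean(mo2))
    # background depletion slope chosen so that (background slope /
    # fish-only depletion slope) equals the configured fraction
    bg_slope = design.background_fraction * mean_mo2 * mass_kg / water_l
    # total chamber depletion during sealed phases, mg O2 L^-1 min^-1
    fish_slope = (mo2 * mass_kg + bg_slope * vol) / water_l

    measure_s = design.measure_min * 60.0
    cycle_s = design.cycle_s
    in_measure = (times % cycle_s) < measure_s - 1e-9

    o2 = np.empty(n)
    sat = design.o2_saturation_mg_per_l
    tau = design.flush_tau_s
    level = sat  # chamber O2 at segment start
    for c in range(design.n_cycles):
        m_sel = (times >= c * cycle_s) & (times < c * cycle_s + measure_s - 1e-9)
        idx = np.nonzero(m_sel)[0]
        if idx.size:
            dep = np.concatenate(([0.0], np.cumsum(fish_slope[idx[:-1]] * dt / 60.0)))
            o2[idx] = level - dep
            level = o2[idx[-1]] - fish_slope[idx[-1]] * dt / 60.0
        f_sel = (times >= c * cycle_s + measure_s - 1e-9) & (times < (c + 1) * cycle_s)
        idx = np.nonzero(f_sel)[0]
        if idx.size:
            t_rel = times[idx] - (c * cycle_s + measure_s)
            o2[idx] = sat + (level - sat) * np.exp(-t_rel / tau)
            t_end = cycle_s - measure_s
            level = sat + (level - sat) * math.exp(-t_end / tau)
        elif design.flush_min > 0:
            t_end = cycle_s - measure_s
            level = sat + (level - sat) * math.exp(-t_end / tau)

    if design.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, design.noise_sd, size=n)
    o2 = np.clip(o2, 0.0, None)

    trace = O2Trace(
        time_s=times,
        o2_mg_per_l=o2,
        temp_c=temps,
        chamber_volume_l=vol,
        fish_id=truth.fish_id,
        phase=np.where(in_measure, "M", "F"),
    )
    gt = TrialGroundTruth(
        fish_id=truth.fish_id,
        smr_ref=truth.smr_ref,
        t_ref_c=truth.t_ref_c,
        q10_true=truth.q10_true,
        epoc_magnitude=truth.epoc_magnitude,
        epoc_rate_k=truth.epoc_rate_k,
        mean_mo2_true=mean_mo2,
        background_slope=bg_slope,
        background_fraction=design.background_fraction,
        mass_kg=mass_kg,
    )
    return trace, gt


def simulate_background_trial(
    bg_slope: float,
    design: TrialDesign,
    temp_c: float,
    n_cycles: int = 12,
    rng: np.random.Generator | None = None,
) -> O2Trace:
    """Empty-chamber trace whose sealed-phase depletion slope is ``bg_slope``."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    short = replace(design, duration_h=n_cycles * design.cycle_s / 3600.0,
                    background_fraction=0.0)
    # an "empty fish": zero displacement, consumption producing bg_slope
    dt = short.sample_interval_s
    n = int(round(short.duration_h * 3600.0 / dt))
    times = np.arange(n) * dt
    measure_s = short.measure_min * 60.0
    cycle_s = short.cycle_s
    in_measure = (times % cycle_s) < measure_s - 1e-9
    o2 = np.empty(n)
    sat = short.o2_saturation_mg_per_l
    level = sat
    for c in range(n_cycles):
        m_sel = (times >= c * cycle_s) & (times < c * cycle_s + measure_s - 1e-9)
        idx = np.nonzero(m_sel)[0]
        if idx.size:
            o2[idx] = level - bg_slope * (times[idx] - c * cycle_s) / 60.0
            level = float(o2[idx[-1]] - bg_slope * dt / 60.0)
        f_sel = (times >= c * cycle_s + measure_s - 1e-9) & (times < (c + 1) * cycle_s)
        idx = np.nonzero(f_sel)[0]
        if idx.size:
            t_rel = times[idx] - (c * cycle_s + measure_s)
            o2[idx] = sat + (level - sat) * np.exp(-t_rel / short.flush_tau_s)
            level = sat + (level - sat) * math.exp(
                -(cycle_s - measure_s) / short.flush_tau_s
            )
    if short.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, short.noise_sd, size=n)
    return O2Trace(
        time_s=times,
        o2_mg_per_l=np.clip(o2, 0.0, None),
        temp_c=np.full(n, temp_c),
        chamber_volume_l=short.chamber_volume_l,
        fish_id="",
        phase=np.where(in_measure, "M", "F"),
    )


def simulate_ctmax(
    truth: SimFishTruth,
    start_temp_c: float,
    ramp_rate_c_per_min: float = 0.3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CTmaxRecord:
    """Simulate a critical-thermal-maximum heating ramp.

    The loss-of-equilibrium temperature is drawn from
    Normal(ctmax_true_mean, ctmax_true_sd), truncated below at the ramp
    start; the loss-of-equilibrium time follows from the ramp rate.
    """
    if ramp_rate_c_per_min <= 0:
        raise ValueError("ramp rate must be positive")
    if start_temp_c >= truth.ctmax_true_mean:
        raise ValueError("ramp must start below the true mean CTmax")
    if rng is None:
        rng = np.random.default_rng(seed)
    if truth.ctmax_true_sd == 0:
        loe = truth.ctmax_true_mean
    else:
        loe = start_temp_c - 1.0
        while loe < start_temp_c:  # truncation below at ramp start
            loe = rng.normal(truth.ctmax_true_mean, truth.ctmax_true_sd)
    loe_time = (loe - start_temp_c) / ramp_rate_c_per_min
    return CTmaxRecord(
        fish_id=truth.fish_id,
        loe_temp_c=float(loe),
        start_temp_c=start_temp_c,
        ramp_rate_c_per_min=ramp_rate_c_per_min,
        loe_time_min=float(loe_time),
        realized_rate_c_per_3min=3.0 * ramp_rate_c_per_min,
    )


@dataclass
class WatershedScenario:
    """Ground-truth physiology distribution for one watershed's fish.

    Mean parameters describe the typical fish; per-fish values are
    drawn with lognormal multiplicative variation (``cv`` fields).
    ``epoc_q10`` controls how burst (post-chase excess) capacity scales
    with temperature relative to SMR: values below ``q10`` make
    factorial aerobic scope decline with warming, equal values keep it
    flat.
    """

    context: ThermalContext
    smr_ref: float
    q10: float
    epoc_magnitude: float
    epoc_rate_k: float = 0.06
    epoc_q10: float = 1.0
    ctmax_mean: float = 29.0
    ctmax_sd: float = 0.5
    smr_cv: float = 0.10
    epoc_cv: float = 0.10
    k_cv: float = 0.15
    t_ref_c: float | None = None  # defaults to ambient mean

    @property
    def t_ref(self) -> float:
        return self.context.ambient_mean_c if self.t_ref_c is None else self.t_ref_c


@dataclass
class CohortScenario:
    """Full study design: watersheds x treatments x fish per treatment."""

    watersheds: dict[str, WatershedScenario]
    n_per_treatment: int = 8
    treatments: tuple[str, ...] = TREATMENTS
    design: TrialDesign = field(default_factory=TrialDesign)
    seed: int = 0
    # trial lengths are drawn per fish as whole cycles in this range (hours)
    duration_range_h: tuple[float, float] = (18.0, 24.0)
    mean_fork_length_mm: float = 130.0
    sd_fork_length_mm: float = 12.0
    mean_condition_k: float = 1.00
    sd_condition_k: float = 0.03
    ctmax_ramp_rate: float = 0.3
    background_fraction_range: tuple[float, float] = (0.0015, 0.021)


def default_scenario(
    seed: int = 0,
    design: TrialDesign | None = None,
    n_per_treatment: int = 8,
) -> CohortScenario:
    """The packaged four-watershed scenario.

    Physiology truths per watershed reflect the study regimes: warm
    coastal sites (Alsea, Siletz) with high thermal tolerance; cool
    Willamette-basin sites (McKenzie, N. Santiam) with lower CTmax, the
    McKenzie temperature-insensitive in factorial scope (its excess
    scales with SMR) and the N. Santiam showing the steepest factorial
    scope decline from a cold ambient baseline.
    """
    sites = DEFAULT_SITES
    watersheds = {
        "Alsea": WatershedScenario(
            context=sites["Alsea"], smr_ref=2.2, q10=3.25,
            epoc_magnitude=14.0, epoc_q10=0.7,
            ctmax_mean=29.78, ctmax_sd=0.30,
        ),
        "Siletz": WatershedScenario(
            context=sites["Siletz"], smr_ref=2.0, q10=2.02,
            epoc_magnitude=9.0, epoc_q10=1.15,
            ctmax_mean=30.38, ctmax_sd=0.17,
        ),
        "McKenzie": WatershedScenario(
            context=sites["McKenzie"], smr_ref=1.5, q10=1.17,
            epoc_magnitude=10.0, epoc_q10=1.17,  # = q10: flat FAS
            ctmax_mean=27.25, ctmax_sd=2.3,
        ),
        "N. Santiam": WatershedScenario(
            context=sites["N. Santiam"], smr_ref=1.0, q10=2.01,
            epoc_magnitude=11.0, epoc_q10=1.0,
            ctmax_mean=27.29, ctmax_sd=0.5,
        ),
    }
    if design is None:
        design = TrialDesign()
    return CohortScenario(
        watersheds=watersheds,
        n_per_treatment=n_per_treatment,
        design=design,
        seed=seed,
    )


_WS_CODE = {"Alsea": "ALS", "Siletz": "SIL", "McKenzie": "MCK", "N. Santiam": "SAN"}


@dataclass
class CohortDataset:
    """Complete simulated study: traces, CTmax records, metadata, truth."""

    metadata: pd.DataFrame
    truth: pd.DataFrame
    trials: dict[str, tuple[O2Trace, TrialGroundTruth]]
    background_pre: dict[str, O2Trace]
    background_post: dict[str, O2Trace]
    ctmax_records: list[CTmaxRecord]
    scenario: CohortScenario

    def write(self, outdir) -> None:
        """Write the dataset as delimited text under ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        (out / "traces").mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(out / "metadata.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        pd.DataFrame([vars(r) for r in self.ctmax_records]).to_csv(
            out / "ctmax.csv", index=False
        )
        for fid, (trace, _) in self.trials.items():
            safe = fid.replace("/", "_")
            trace.to_frame().to_csv(out / "traces" / f"{safe}.csv", index=False)
            self.background_pre[fid].to_frame().to_csv(
                out / "traces" / f"{safe}_bg_pre.csv", index=False
            )
            self.background_post[fid].to_frame().to_csv(
                out / "traces" / f"{safe}_bg_post.csv", index=False
            )


def simulate_cohort(scenario: CohortScenario | None = None) -> CohortDataset:
    """Simulate the full study: 8 fish x 3 treatments x N watersheds.

    Body sizes are drawn so Fulton's condition factor centres near 1.00.
    Each fish gets one overnight trial at its treatment temperature
    (Ambient fish on the diurnal stream profile, Max/Climate at constant
    heated temperatures) with per-fish pre/post empty-chamber background
    traces; Ambient fish additionally get a CTmax trial. All randomness
    derives from the scenario seed via per-fish streams keyed on
    fish_id.
    """
    if scenario is None:
        scenario = default_scenario()
    meta_rows = []
    truth_rows = []
    trials: dict[str, tuple[O2Trace, TrialGroundTruth]] = {}
    bg_pre: dict[str, O2Trace] = {}
    bg_post: dict[str, O2Trace] = {}
    ctmax_records: list[CTmaxRecord] = []
    base = scenario.design
    cyc_h = base.cycle_s / 3600.0
    lo_cycles = int(np.ceil(scenario.duration_range_h[0] / cyc_h - 1e-9))
    hi_cycles = int(np.floor(scenario.duration_range_h[1] / cyc_h + 1e-9))

    for ws_name, ws in scenario.watersheds.items():
        if ws.context is None:
            raise ValueError(f"watershed {ws_name!r} is missing treatment temperatures")
        code = _WS_CODE.get(ws_name, ws_name[:3].upper())
        for treatment in scenario.treatments:
            treat_temp = ws.context.treatment_temp(treatment)
            for i in range(scenario.n_per_treatment):
                fish_id = f"{code}-{treatment[0]}{i + 1}"
                rng = _fish_rng(scenario.seed, fish_id)
                # body size: fork length and condition factor -> mass
                fl = rng.normal(scenario.mean_fork_length_mm, scenario.sd_fork_length_mm)
                fl = float(np.clip(fl, 95.0, 185.0))
                k = float(rng.normal(scenario.mean_condition_k, scenario.sd_condition_k))
                mass_g = k * fl**3 / 1e5
                truth = SimFishTruth(
                    fish_id=fish_id,
                    mass_g=mass_g,
                    fork_length_mm=fl,
                    smr_ref=ws.smr_ref * float(rng.lognormal(0.0, ws.smr_cv)),
                    t_ref_c=ws.t_ref,
                    q10_true=ws.q10,
                    epoc_magnitude=ws.epoc_magnitude * float(rng.lognormal(0.0, ws.epoc_cv)),
                    epoc_rate_k=ws.epoc_rate_k * float(rng.lognormal(0.0, ws.k_cv)),
                    ctmax_true_mean=ws.ctmax_mean,
                    ctmax_true_sd=ws.ctmax_sd,
                    epoc_q10=ws.epoc_q10,
                )
                n_cycles = int(rng.integers(lo_cycles, hi_cycles + 1))
                bg_frac = float(rng.uniform(*scenario.background_fraction_range))
                design = replace(
                    base,
                    duration_h=n_cycles * cyc_h,
                    background_fraction=bg_frac,
                )
                if treatment == "Ambient":
                    profile = diurnal_profile(
                        ws.context.ambient_mean_c,
                        base.diurnal_amplitude_c,
                        base.diurnal_phase,
                    )
                else:
                    profile = constant_profile(treat_temp)
                trace, gt = simulate_trial(truth, design, profile, rng=rng)
                trials[fish_id] = (trace, gt)
                bg_pre[fish_id] = simulate_background_trial(
                    gt.background_slope, design, treat_temp, rng=rng
                )
                bg_post[fish_id] = simulate_background_trial(
                    gt.background_slope, design, treat_temp, rng=rng
                )
                if treatment == "Ambient":
                    start = min(treat_temp, truth.ctmax_true_mean - 5.0)
                    ctmax_records.append(
                        simulate_ctmax(
                            truth, start_temp_c=start,
                            ramp_rate_c_per_min=scenario.ctmax_ramp_rate,
                            rng=rng,
                        )
                    )
                meta_rows.append(
                    {
                        "fish_id": fish_id,
                        "watershed": ws_name,
                        "treatment": treatment,
                        "treatment_temp_c": treat_temp,
                        "mass_g": mass_g,
                        "fork_length_mm": fl,
                        "chamber_volume_l": design.chamber_volume_l,
                        "duration_h": design.duration_h,
                    }
                )
                truth_rows.append(
                    {
                        "fish_id": fish_id,
                        "watershed": ws_name,
                        "treatment": treatment,
                        **{k_: v for k_, v in vars(truth).items() if k_ != "fish_id"},
                        "background_slope": gt.background_slope,
                        "background_fraction": bg_frac,
                        "mean_mo2_true": gt.mean_mo2_true,
                    }
                )
    return CohortDataset(
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
        trials=trials,
        background_pre=bg_pre,
        background_post=bg_post,
        ctmax_records=ctmax_records,
        scenario=scenario,
    )
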