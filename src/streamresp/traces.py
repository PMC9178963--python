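"""Intermittent-flow respirometry trace processing.

A trial alternates sealed *measurement* phases, during which dissolved
oxygen in the chamber declines as the fish respires, with *flush* phases
in which the chamber water is replaced. This module segments a raw
oxygen trace into measurement windows, estimates the O2 depletion slope
in each window by least squares, corrects for background (microbial)
respiration measured in an empty chamber, and converts each corrected
slope into a mass-specific oxygen consumption rate

    MO2 = (slope_fish * (V_chamber - Mass) - slope_background * V_chamber) / Mass

in mg O2 kg^-1 min^-1, yielding one MO2 value per measurement phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "O2Trace",
    "CyclePlan",
    "MeasurementWindow",
    "BackgroundModel",
    "MO2Series",
    "segment_cycles",
    "estimate_slope",
    "evaluate_background",
    "compute_mo2",
    "build_mo2_series",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass
class O2Trace:
    """Timestamped dissolved-oxygen and temperature samples for one chamber.

    Parameters
    ----------
    time_s, o2_mg_per_l, temp_c
        Equal-length 1-D arrays. Time is seconds from trial start,
        strictly increasing. Dissolved oxygen is mg O2 per litre.
    chamber_volume_l
        Respirometer volume in litres.
    fish_id
        Identifier of the occupant, or ``""`` for an empty (background)
        chamber.
    phase
        Optional per-sample tag, ``"M"`` (measure) or ``"F"`` (flush).
    """

    time_s: np.ndarray
    o2_mg_per_l: np.ndarray
    temp_c: np.ndarray
    chamber_volume_l: float = 2.0
    fish_id: str = ""
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_mg_per_l = np.asarray(self.o2_mg_per_l, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if not (len(self.time_s) == len(self.o2_mg_per_l) == len(self.temp_c)):
            raise ValueError("time, O2 and temperature arrays must have equal length")
        if len(self.time_s) and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.o2_mg_per_l < 0):
            raise ValueError("dissolved oxygen cannot be negative")
        if not np.all(np.isfinite(self.temp_c)):
            raise ValueError("temperature samples must be finite")
        if self.chamber_volume_l <= 0:
            raise ValueError("chamber volume must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        """Trace span including the final sampling interval."""
        if self.n_samples == 0:
            return 0.0
        if self.n_samples == 1:
            return 0.0
        dt = float(np.median(np.diff(self.time_s)))
        return float(self.time_s[-1] - self.time_s[0] + dt)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.time_s,
                "o2_mg_per_l": self.o2_mg_per_l,
                "temp_c": self.temp_c,
            }
        )
        if self.phase is not None:
            df["phase"] = self.phase
        return df


@dataclass(frozen=True)
class CyclePlan:
    """Measurement/flush cycle layout.

    ``trim_s`` seconds are discarded at the start of every measurement
    phase before slope fitting (mixing transients); the default keeps
    the full phase.
    """

    measure_min: float = 6.0
    flush_min: float = 4.0
    trim_s: float = 0.0

    def __post_init__(self) -> None:
        if self.measure_min <= 0:
            raise ValueError("measurement phase must be positive")
        if self.flush_min < 0:
            raise ValueError("flush phase cannot be negative")
        if self.trim_s >= self.measure_min * 60:
            raise ValueError("trim cannot consume the whole measurement phase")

    @property
    def cycle_s(self) -> float:
        return (self.measure_min + self.flush_min) * 60.0


@dataclass
class MeasurementWindow:
    """Least-squares O2 depletion fit for one measurement phase.

    ``slope_mg_per_l_min`` is the rate of *decrease* of chamber O2
    (positive = depletion).
    """

    cycle_index: int
    start_s: float
    end_s: float
    slope_mg_per_l_min: float = float("nan")
    r_squared: float = float("nan")
    mean_temp_c: float = float("nan")
    n_samples: int = 0
    valid: bool = True

    @property
    def mid_time_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class BackgroundModel:
    """Background (microbial) respiration measured in an empty chamber.

    Slopes are mg O2 L^-1 min^-1 from `estimate_slope` applied to
    empty-chamber traces before (``pre``) and after (``post``) the
    trial block. Evaluation clamps at zero: probe noise can produce a
    slightly negative measured slope, but respiration cannot add oxygen.
    """

    pre_slope: float | None = None
    post_slope: float | None = None
    interpolation: Literal["constant", "linear"] = "linear"

    def __post_init__(self) -> None:
        if self.pre_slope is None and self.post_slope is None:
            raise ValueError("background model needs at least one of pre/post slope")
        for s in (self.pre_slope, self.post_slope):
            if s is not None and not np.isfinite(s):
                raise ValueError("background slopes must be finite")


def evaluate_background(
    model: BackgroundModel, t_s: float, trial_duration_s: float
) -> float:
    """Background depletion slope (mg O2 L^-1 min^-1) at time ``t_s``.

    Constant mode returns the mean of the available endpoint slopes;
    linear mode interpolates pre -> post across the trial. Negative
    evaluations are clamped to zero.
    """
    pre = model.pre_slope
    post = model.post_slope
    if pre is None:
        pre = post
    if post is None:
        post = pre
    assert pre is not None and post is not None
    if model.interpolation == "constant":
        value = 0.5 * (pre + post)
    elif model.interpolation == "linear":
        if trial_duration_s <= 0:
            value = 0.5 * (pre + post)
        else:
            frac = min(max(t_s / trial_duration_s, 0.0), 1.0)
            value = pre + (post - pre) * frac
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown interpolation mode {model.interpolation!r}")
    return max(value, 0.0)


def segment_cycles(trace: O2Trace, plan: CyclePlan) -> list[tuple[int, float, float]]:
    """Tile the trace into measurement-window bounds.

    Windows start at t=0 in (measure, flush) order; a trailing partial
    cycle is dropped. Returns ``(cycle_index, start_s, end_s)`` tuples
    with half-open window semantics ``[start, end)``.
    """
    if trace.n_samples == 0:
        raise ValueError("cannot segment an empty trace")
    duration = trace.duration_s
    n_cycles = int(np.floor(duration / plan.cycle_s + 1e-9))
    t0 = float(trace.time_s[0])
    out = []
    for i in range(n_cycles):
        start = t0 + i * plan.cycle_s
        end = start + plan.measure_min * 60.0
        out.append((i, start, end))
    return out


def estimate_slope(
    trace: O2Trace,
    bounds: tuple[int, float, float],
    trim_s: float = 0.0,
) -> MeasurementWindow:
    """Fit the O2 depletion slope for one measurement window.

    The slope is the negated least-squares slope of O2 against time over
    the trimmed window, expressed per minute. Windows with fewer than 3
    samples after trimming are flagged invalid (``valid=False``) and
    carry NaN estimates.
    """
    cycle_index, start_s, end_s = bounds
    win = MeasurementWindow(cycle_index=cycle_index, start_s=start_s, end_s=end_s)
    sel = (trace.time_s >= start_s + trim_s) & (trace.time_s < end_s)
    t = trace.time_s[sel]
    o2 = trace.o2_mg_per_l[sel]
    win.n_samples = int(t.size)
    if t.size < 3:
        win.valid = False
        return win
    res = stats.linregress(t / 60.0, o2)
    win.slope_mg_per_l_min = -float(res.slope)
    win.r_squared = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    win.mean_temp_c = float(np.mean(trace.temp_c[sel]))
    return win


def compute_mo2(
    slope_fish: float,
    slope_background: float,
    chamber_volume_l: float,
    mass_kg: float,
) -> float:
    """Mass-specific oxygen consumption rate (mg O2 kg^-1 min^-1).

    ``slope_fish`` and ``slope_background`` are chamber O2 depletion
    rates in mg O2 L^-1 min^-1; the fish displaces its own volume of
    water (density 1), hence the ``V - Mass`` term. Negative results
    (background exceeding the fish signal) are returned as-is for the
    caller to flag.
    """
    if not 0 < mass_kg < chamber_volume_l:
        raise ValueError("fish mass must be positive and below chamber volume (kg vs L)")
    return (
        slope_fish * (chamber_volume_l - mass_kg)
        - slope_background * chamber_volume_l
    ) / mass_kg


@dataclass
class MO2Series:
    """Per-cycle oxygen consumption rates for one fish.

    ``entries`` has one row per accepted measurement phase with columns
    ``cycle_index, mid_time_s, mo2, mean_temp_c`` (mo2 in
    mg O2 kg^-1 min^-1).
    """

    fish_id: str
    entries: pd.DataFrame
    chamber_volume_l: float
    mass_kg: float
    background_fraction: float = float("nan")
    n_invalid_windows: int = 0
    trial_duration_s: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 < self.mass_kg < self.chamber_volume_l:
            raise ValueError("fish mass must be positive and below chamber volume")

    @property
    def mo2(self) -> np.ndarray:
        return self.entries["mo2"].to_numpy()

    @property
    def mid_time_s(self) -> np.ndarray:
        return self.entries["mid_time_s"].to_numpy()

    @property
    def temp_c(self) -> np.ndarray:
        return self.entries["mean_temp_c"].to_numpy()

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        df = self.entries.copy()
        df.insert(0, "fish_id", self.fish_id)
        return df


def build_mo2_series(
    trace: O2Trace,
    plan: CyclePlan,
    background: BackgroundModel,
    mass_kg: float,
    r_squared_floor: float = 0.0,
) -> MO2Series:
    """Full trace -> MO2 pipeline for one fish.

    Segments the trace, fits depletion slopes, evaluates the background
    model at each window midpoint and applies the mass-specific rate
    formula, producing one MO2 value per accepted measurement phase.
    The reported ``background_fraction`` is the mean evaluated
    background slope divided by the mean fitted fish slope.
    """
    if mass_kg <= 0:
        raise ValueError("fish mass must be positive")
    bounds = segment_cycles(trace, plan)
    duration = trace.duration_s
    rows = []
    n_invalid = 0
    bg_slopes = []
    fish_slopes = []
    for b in bounds:
        win = estimate_slope(trace, b, trim_s=plan.trim_s)
        if not win.valid:
            n_invalid += 1
            continue
        if r_squared_floor > 0.0 and win.r_squared < r_squared_floor:
            n_invalid += 1
            continue
        bg = evaluate_background(background, win.mid_time_s, duration)
        mo2 = compute_mo2(
            win.slope_mg_per_l_min, bg, trace.chamber_volume_l, mass_kg
        )
        bg_slopes.append(bg)
        fish_slopes.append(win.slope_mg_per_l_min)
        rows.append(
            {
                "cycle_index": win.cycle_index,
                "mid_time_s": win.mid_time_s,
                "mo2": mo2,
                "mean_temp_c": win.mean_temp_c,
            }
        )
    if not rows:
        raise ValueError("no valid measurement windows in trace")
    entries = pd.DataFrame(rows).sort_values("cycle_index").reset_index(drop=True)
    mean_fish = float(np.mean(fish_slopes))
    frac = float(np.mean(bg_slopes) / mean_fish) if mean_fish > 0 else float("nan")
    return MO2Series(
        fish_id=trace.fish_id,
        entries=entries,
        chamber_volume_l=trace.chamber_volume_l,
        mass_kg=mass_kg,
        background_fraction=frac,
        n_invalid_windows=n_invalid,
        trial_duration_s=duration,
    )


_DEFAULT_COLUMNS = {
    "time_s": "time_s",
    "o2_mg_per_l": "o2_mg_per_l",
    "temp_c": "temp_c",
    "phase": "phase",
}


def read_trace_csv(
    path,
    chamber_volume_l: float = 2.0,
    fish_id: str = "",
    column_map: dict[str, str] | None = None,
) -> O2Trace:
    """Read a delimited-text oxygen trace.

    ``column_map`` maps the canonical names (``time_s``, ``o2_mg_per_l``,
    ``temp_c``, optionally ``phase``) to the headers actually present,
    allowing ingestion of multi-channel sensor logs with other headers.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    missing = [cols[k] for k in ("time_s", "o2_mg_per_l", "temp_c") if cols[k] not in df]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    phase = None
    if cols["phase"] in df.columns:
        phase = df[cols["phase"]].to_numpy()
    return O2Trace(
        time_s=df[cols["time_s"]].to_numpy(),
        o2_mg_per_l=df[cols["o2_mg_per_l"]].to_numpy(),
        temp_c=df[cols["temp_c"]].to_numpy(),
        chamber_volume_l=chamber_volume_l,
        fish_id=fish_id,
        phase=phase,
    )


def write_trace_csv(trace: O2Trace, path) -> None:
    trace.to_frame().to_csv(path, index=False)
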