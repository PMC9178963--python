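"""Thermal tolerance and climate-risk metrics.

Two buffers are computed against the maximum weekly maximum stream
temperature (MWMT) of a fish's home site:

* thermal safety margin, TSM = CTmax - MWMT, the warming buffer before
  lethality (CTmax is the loss-of-equilibrium temperature under a
  controlled heating ramp);
* functional warming tolerance, WT = T_pejus - MWMT, the buffer before
  performance is impaired. T_pejus is operationalized as the
  temperature at which factorial aerobic scope (FAS = MMR/SMR) drops to
  a threshold (default 3, the level at which a subadult salmonid can
  digest a meal and still have scope for other activities), obtained by
  inverting a per-watershed linear model of FAS against mean test
  temperature.

Both metrics are evaluated under a baseline MWMT and a projected (2080)
MWMT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CTmaxRecord",
    "ThermalContext",
    "RiskMetrics",
    "TpejusFit",
    "thermal_safety_margin",
    "fit_tpejus",
    "warming_tolerance",
    "ctmax_from_trial",
    "DEFAULT_SITES",
    "default_site_table",
    "risk_table",
]


@dataclass
class CTmaxRecord:
    """One critical-thermal-maximum trial outcome."""

    fish_id: str
    loe_temp_c: float
    start_temp_c: float
    ramp_rate_c_per_min: float
    loe_time_min: float
    realized_rate_c_per_3min: float | None = None

    def __post_init__(self) -> None:
        if self.ramp_rate_c_per_min <= 0:
            raise ValueError("ramp rate must be positive")
        if self.loe_temp_c < self.start_temp_c:
            raise ValueError("loss-of-equilibrium temperature below ramp start")


@dataclass(frozen=True)
class ThermalContext:
    """Site environment: MWMT estimates and treatment temperatures (degC)."""

    watershed: str
    mwmt_baseline_c: float
    mwmt_2080_c: float
    ambient_mean_c: float
    max_treatment_c: float
    climate_treatment_c: float
    ambient_min_c: float | None = None
    ambient_max_c: float | None = None

    def __post_init__(self) -> None:
        if self.climate_treatment_c <= self.max_treatment_c:
            raise ValueError("climate treatment must exceed max treatment")
        if self.mwmt_2080_c <= self.mwmt_baseline_c:
            raise ValueError("2080 MWMT projection must exceed baseline")

    def treatment_temp(self, treatment: str) -> float:
        return {
            "Ambient": self.ambient_mean_c,
            "Max": self.max_treatment_c,
            "Climate": self.climate_treatment_c,
        }[treatment]


# Site table for the four study watersheds: NorWeST MWMT estimates
# (baseline = mean 2002-2011, and 2080 projection) and the temperature
# treatments used stream-side. Treatment temperatures are data, not
# derived values: the Climate - Max offset is 3 degC at the coastal
# sites and 5 degC at the Willamette-basin sites as run.
DEFAULT_SITES: dict[str, ThermalContext] = {
    "Alsea": ThermalContext(
        "Alsea", mwmt_baseline_c=16.97, mwmt_2080_c=18.77,
        ambient_mean_c=18.4, max_treatment_c=19.0, climate_treatment_c=22.0,
        ambient_min_c=16.6, ambient_max_c=20.0,
    ),
    "Siletz": ThermalContext(
        "Siletz", mwmt_baseline_c=18.87, mwmt_2080_c=20.79,
        ambient_mean_c=18.8, max_treatment_c=19.0, climate_treatment_c=22.0,
        ambient_min_c=16.6, ambient_max_c=20.0,
    ),
    "McKenzie": ThermalContext(
        "McKenzie", mwmt_baseline_c=15.60, mwmt_2080_c=17.32,
        ambient_mean_c=11.8, max_treatment_c=14.0, climate_treatment_c=19.0,
        ambient_min_c=10.4, ambient_max_c=13.4,
    ),
    "N. Santiam": ThermalContext(
        "N. Santiam", mwmt_baseline_c=15.79, mwmt_2080_c=17.52,
        ambient_mean_c=8.1, max_treatment_c=14.0, climate_treatment_c=19.0,
        ambient_min_c=6.3, ambient_max_c=10.3,
    ),
}


def default_site_table() -> pd.DataFrame:
    """The packaged site table as a DataFrame (one row per watershed)."""
    rows = []
    for ctx in DEFAULT_SITES.values():
        rows.append(
            {
                "watershed": ctx.watershed,
                "mwmt_baseline_c": ctx.mwmt_baseline_c,
                "mwmt_2080_c": ctx.mwmt_2080_c,
                "ambient_mean_c": ctx.ambient_mean_c,
                "max_treatment_c": ctx.max_treatment_c,
                "climate_treatment_c": ctx.climate_treatment_c,
                "ambient_min_c": ctx.ambient_min_c,
                "ambient_max_c": ctx.ambient_max_c,
            }
        )
    return pd.DataFrame(rows)


def read_site_table(path) -> dict[str, ThermalContext]:
    """Load site contexts from a CSV shaped like `default_site_table`."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        ctx = ThermalContext(
            watershed=str(row["watershed"]),
            mwmt_baseline_c=float(row["mwmt_baseline_c"]),
            mwmt_2080_c=float(row["mwmt_2080_c"]),
            ambient_mean_c=float(row["ambient_mean_c"]),
            max_treatment_c=float(row["max_treatment_c"]),
            climate_treatment_c=float(row["climate_treatment_c"]),
            ambient_min_c=float(row["ambient_min_c"]) if "ambient_min_c" in row else None,
            ambient_max_c=float(row["ambient_max_c"]) if "ambient_max_c" in row else None,
        )
        out[ctx.watershed] = ctx
    return out


def thermal_safety_margin(ctmax_c: float, mwmt_c: float) -> float:
    """TSM = CTmax - MWMT (degC); negative values signal lethal exposure."""
    if not (np.isfinite(ctmax_c) and np.isfinite(mwmt_c)):
        raise ValueError("TSM requires finite inputs")
    return ctmax_c - mwmt_c


@dataclass
class TpejusFit:
    """Result of inverting a linear FAS-vs-temperature model at a threshold."""

    tpejus_c: float | None
    intercept: float
    slope: float
    threshold: float
    n: int
    extrapolated: bool = False
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.tpejus_c is not None


def fit_tpejus(
    temps_c,
    fas,
    threshold: float = 3.0,
    slope_alpha: float | None = 0.05,
) -> TpejusFit:
    """Temperature at which the fitted FAS line crosses ``threshold``.

    Fits FAS = a + b*T by least squares over per-fish (mean test
    temperature, FAS) points, then solves for T at FAS = threshold. A
    non-negative slope means FAS is stable or rising with temperature,
    so the crossing is undefined (as when scope is insensitive to
    temperature in a cool, stable stream); the result then carries a
    reason code instead of a temperature. When ``slope_alpha`` is set
    (default 0.05), a slope that is not significantly below zero
    (one-sided t test) is likewise treated as stable: inverting a line
    indistinguishable from flat would extrapolate sampling noise.
    Crossings outside the observed temperature range are flagged as
    extrapolated.
    """
    t = np.asarray(temps_c, dtype=float)
    f = np.asarray(fas, dtype=float)
    if t.size != f.size:
        raise ValueError("temperature and FAS arrays must have equal length")
    if t.size < 6:
        raise ValueError("need at least 6 (temperature, FAS) points")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct temperatures")
    res = stats.linregress(t, f)
    a, b = float(res.intercept), float(res.slope)
    if b >= 0:
        return TpejusFit(
            tpejus_c=None, intercept=a, slope=b, threshold=threshold,
            n=int(t.size), reason="fas_not_declining",
        )
    if slope_alpha is not None and res.pvalue / 2.0 >= slope_alpha:
        return TpejusFit(
            tpejus_c=None, intercept=a, slope=b, threshold=threshold,
            n=int(t.size), reason="fas_slope_not_significant",
        )
    tp = (threshold - a) / b
    extrapolated = not (t.min() <= tp <= t.max())
    return TpejusFit(
        tpejus_c=float(tp), intercept=a, slope=b, threshold=threshold,
        n=int(t.size), extrapolated=extrapolated,
    )


def warming_tolerance(tpejus_c: float | None, mwmt_c: float) -> float | None:
    """WT = T_pejus - MWMT (degC); undefined T_pejus propagates as None."""
    if tpejus_c is None:
        return None
    return tpejus_c - mwmt_c


def ctmax_from_trial(
    ramp_time_min,
    ramp_temp_c,
    loe_time_min: float,
    fish_id: str = "",
) -> CTmaxRecord:
    """CTmax record from a heating-ramp log and a loss-of-equilibrium time.

    The loss-of-equilibrium temperature is read from the ramp log at
    ``loe_time_min`` (linear interpolation between log samples). The
    realized heating rate is reported per 3-minute window over the ramp
    up to the loss of equilibrium.
    """
    t = np.asarray(ramp_time_min, dtype=float)
    temp = np.asarray(ramp_temp_c, dtype=float)
    if t.size < 2:
        raise ValueError("ramp log needs at least 2 samples")
    if not (t[0] <= loe_time_min <= t[-1]):
        raise ValueError("loss-of-equilibrium time outside the ramp log")
    loe_temp = float(np.interp(loe_time_min, t, temp))
    start_temp = float(temp[0])
    # realized heating rate: temperature gained per 3-min window
    if loe_time_min - t[0] >= 3.0:
        grid = np.arange(t[0], loe_time_min + 1e-9, 3.0)
        temps = np.interp(grid, t, temp)
        rate3 = float(np.mean(np.diff(temps)))
    else:
        rate3 = float((loe_temp - start_temp) / max(loe_time_min - t[0], 1e-12) * 3.0)
    # nominal rate from the whole ramp log (robust to LOE at ramp start)
    nominal = float((temp[-1] - temp[0]) / (t[-1] - t[0]))
    return CTmaxRecord(
        fish_id=fish_id,
        loe_temp_c=loe_temp,
        start_temp_c=start_temp,
        ramp_rate_c_per_min=nominal,
        loe_time_min=float(loe_time_min),
        realized_rate_c_per_3min=rate3,
    )


@dataclass
class RiskMetrics:
    """Per-watershed thermal-risk summary for one MWMT horizon."""

    watershed: str
    horizon: str  # "baseline" | "2080"
    mwmt_c: float
    mean_ctmax_c: float | None
    tsm_c: float | None
    tpejus_c: float | None
    wt_c: float | None
    tpejus_reason: str | None = None


def risk_table(
    ctmax_by_watershed: dict[str, list[float]],
    fas_points_by_watershed: dict[str, tuple[list[float], list[float]]],
    sites: dict[str, ThermalContext] | None = None,
    fas_threshold: float = 3.0,
) -> pd.DataFrame:
    """TSM, T_pejus and WT per watershed under baseline and 2080 MWMT.

    ``ctmax_by_watershed`` maps watershed -> per-fish CTmax values;
    ``fas_points_by_watershed`` maps watershed -> (temps, FAS) points
    pooled across treatments. Group TSM is the mean of per-fish TSMs,
    which equals mean CTmax minus the site MWMT.
    """
    if sites is None:
        sites = DEFAULT_SITES
    rows = []
    for ws, ctx in sites.items():
        ctmaxes = ctmax_by_watershed.get(ws, [])
        mean_ctmax = float(np.mean(ctmaxes)) if len(ctmaxes) else None
        tp: TpejusFit | None = None
        if ws in fas_points_by_watershed:
            temps, fas = fas_points_by_watershed[ws]
            try:
                tp = fit_tpejus(temps, fas, threshold=fas_threshold)
            except ValueError:
                tp = None
        for horizon, mwmt in (
            ("baseline", ctx.mwmt_baseline_c),
            ("2080", ctx.mwmt_2080_c),
        ):
            tsm = thermal_safety_margin(mean_ctmax, mwmt) if mean_ctmax is not None else None
            tpejus = tp.tpejus_c if tp is not None else None
            rows.append(
                RiskMetrics(
                    watershed=ws,
                    horizon=horizon,
                    mwmt_c=mwmt,
                    mean_ctmax_c=mean_ctmax,
                    tsm_c=tsm,
                    tpejus_c=tpejus,
                    wt_c=warming_tolerance(tpejus, mwmt),
                    tpejus_reason=(tp.reason if tp is not None else "no_fas_data"),
                )
            )
    return pd.DataFrame([vars(r) for r in rows])
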