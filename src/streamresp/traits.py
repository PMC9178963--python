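"""Metabolic traits derived from per-cycle oxygen consumption series.

SMR (standard metabolic rate) is the mean of the lowest 20% of all
recorded MO2 values for a fish; MMR (maximum metabolic rate) is the
highest recorded value, elicited immediately after an exhaustive 3-min
chase and 30-s air exposure; aerobic scope follows as AAS = MMR - SMR
and FAS = MMR / SMR. RMR (routine metabolic rate) summarizes post-
recovery MO2 per 1 degC temperature bin, and Q10 expresses the
temperature sensitivity of a rate pair. Fulton's condition factor and
an allometric mass-scaling check on whole-animal rates round out the
per-fish trait set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traces import MO2Series

__all__ = [
    "TraitSet",
    "RmrEstimate",
    "Q10Result",
    "MassScalingResult",
    "estimate_smr",
    "estimate_mmr",
    "aerobic_scope",
    "estimate_rmr",
    "q10",
    "condition_factor",
    "mass_scaling_check",
    "lowest_quantile_count",
]


@dataclass
class TraitSet:
    """One fish's derived metabolic traits (rates in mg O2 kg^-1 min^-1)."""

    fish_id: str
    smr: float
    smr_temp_c: float
    smr_n: int
    mmr: float
    mmr_time_s: float
    mmr_temp_c: float
    aas: float
    fas: float
    condition_k: float | None = None


@dataclass
class RmrEstimate:
    """Routine metabolic rate in one temperature bin (bin centre degC)."""

    fish_id: str
    temp_bin_c: float
    rmr: float
    n: int


@dataclass
class Q10Result:
    r1: float
    r2: float
    t1: float
    t2: float
    q10: float


def lowest_quantile_count(n_entries: int, fraction: float = 0.2) -> int:
    """Half-up rounded count of the lowest-``fraction`` subset, at least 1."""
    return max(1, int(np.floor(fraction * n_entries + 0.5)))


def estimate_smr(series: MO2Series) -> tuple[float, float, int]:
    """SMR as the mean of the lowest 20% of recorded MO2 values.

    All recorded values enter the pool, including the post-chase
    recovery period; by construction the lowest-rate subset falls after
    recovery. Returns ``(smr, smr_temp_c, smr_n)`` where ``smr_temp_c``
    is the mean temperature of the same entries.
    """
    n = len(series)
    if n < 5:
        raise ValueError("SMR estimation needs at least 5 MO2 entries")
    k = lowest_quantile_count(n)
    order = np.argsort(series.mo2, kind="stable")[:k]
    smr = float(np.mean(series.mo2[order]))
    smr_temp = float(np.mean(series.temp_c[order]))
    return smr, smr_temp, k


def estimate_mmr(series: MO2Series) -> tuple[float, float, float]:
    """MMR as the highest per-cycle MO2; its timestamp anchors recovery.

    Returns ``(mmr, mmr_time_s, mmr_temp_c)``. The MMR timestamp
    defines t=0 for the recovery metrics (post-chase fish are sealed in
    at their metabolic peak, so this is normally the first cycle).
    """
    if len(series) == 0:
        raise ValueError("empty MO2 series")
    i = int(np.argmax(series.mo2))
    return (
        float(series.mo2[i]),
        float(series.mid_time_s[i]),
        float(series.temp_c[i]),
    )


def aerobic_scope(smr: float, mmr: float) -> tuple[float, float]:
    """Absolute (MMR - SMR) and factorial (MMR / SMR) aerobic scope."""
    if smr <= 0:
        raise ValueError("SMR must be positive")
    return mmr - smr, mmr / smr


def estimate_rmr(
    series: MO2Series,
    epoc_end_s: float,
    bin_width_c: float = 1.0,
    min_per_bin: int = 3,
) -> list[RmrEstimate]:
    """Routine metabolic rate per temperature bin, after recovery.

    Entries later than ``epoc_end_s`` are binned by their mean phase
    temperature (default 1 degC bins centred on integers); bins holding
    fewer than ``min_per_bin`` measurements for the fish are dropped.
    An empty post-recovery series yields an empty list.
    """
    if bin_width_c <= 0:
        raise ValueError("bin width must be positive")
    sel = series.mid_time_s > epoc_end_s
    if not np.any(sel):
        return []
    temps = series.temp_c[sel]
    mo2 = series.mo2[sel]
    centres = np.round(temps / bin_width_c) * bin_width_c
    out = []
    for centre in np.unique(centres):
        m = centres == centre
        if int(m.sum()) < min_per_bin:
            continue
        out.append(
            RmrEstimate(
                fish_id=series.fish_id,
                temp_bin_c=float(centre),
                rmr=float(np.mean(mo2[m])),
                n=int(m.sum()),
            )
        )
    return out


def q10(r1: float, r2: float, t1: float, t2: float) -> Q10Result:
    """Temperature coefficient Q10 = (R2/R1)**(10/(T2-T1)).

    1 means the rate is temperature independent; >1 means it rises with
    temperature.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("rates must be positive")
    if t1 == t2:
        raise ValueError("temperatures must differ")
    return Q10Result(r1=r1, r2=r2, t1=t1, t2=t2,
                     q10=float((r2 / r1) ** (10.0 / (t2 - t1))))


def condition_factor(mass_g, fork_length_mm):
    """Fulton's K = 100000 * M / L^3 (M in g, L in mm); vectorizes."""
    mass_g = np.asarray(mass_g, dtype=float)
    fork_length_mm = np.asarray(fork_length_mm, dtype=float)
    if np.any(mass_g <= 0) or np.any(fork_length_mm <= 0):
        raise ValueError("mass and fork length must be positive")
    k = 100000.0 * mass_g / fork_length_mm**3
    return float(k) if k.ndim == 0 else k


@dataclass
class MassScalingResult:
    slope: float
    ci_low: float
    ci_high: float
    n: int
    mass_correction_needed: bool


def mass_scaling_check(
    whole_animal_rate,
    mass_kg,
    alpha: float = 0.05,
    isometric_slope: float = 1.0,
) -> MassScalingResult:
    """Allometric scaling check: regress ln(rate) on ln(mass).

    For mass-specific rates expressed per kg, a whole-animal scaling
    exponent of 1 (the confidence interval containing
    ``isometric_slope``) means no further mass correction is needed.
    """
    rate = np.asarray(whole_animal_rate, dtype=float)
    mass = np.asarray(mass_kg, dtype=float)
    if rate.size != mass.size:
        raise ValueError("rate and mass arrays must have equal length")
    if rate.size < 3:
        raise ValueError("need at least 3 fish")
    if np.unique(mass).size < 2:
        raise ValueError("all masses equal: scaling slope undefined")
    if np.any(rate <= 0) or np.any(mass <= 0):
        raise ValueError("rates and masses must be positive for log transform")
    res = stats.linregress(np.log(mass), np.log(rate))
    if res.stderr == 0:
        lo = hi = float(res.slope)
    else:
        tcrit = stats.t.ppf(1 - alpha / 2, rate.size - 2)
        lo = float(res.slope - tcrit * res.stderr)
        hi = float(res.slope + tcrit * res.stderr)
    needed = not (lo - 1e-9 <= isometric_slope <= hi + 1e-9)
    return MassScalingResult(
        slope=float(res.slope), ci_low=lo, ci_high=hi,
        n=int(rate.size), mass_correction_needed=needed,
    )
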