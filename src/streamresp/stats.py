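"""Group-comparison statistics, coded from first principles.

Kruskal-Wallis on midranks with tie correction, Dunn's post hoc
pairwise z tests, classical one-way ANOVA, and the log-linear model of
routine metabolic rate against temperature with per-watershed
intercepts (a fixed-effects approximation of the field study's mixed
model). Only the reference distributions (chi-square, F, normal) come
from scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "GroupComparison",
    "RmrModelFit",
    "kruskal_wallis",
    "dunn_posthoc",
    "one_way_anova",
    "fit_rmr_model",
    "adjust_pvalues",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of a k-group test, optionally with pairwise follow-ups."""

    test: str
    statistic: float
    df: tuple[int, ...]
    p_value: float
    groups: list[tuple[str, int]]
    pairwise: pd.DataFrame | None = None


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Midranks (average rank for ties), 1-based."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def _as_groups(groups) -> tuple[list[np.ndarray], list[str]]:
    if isinstance(groups, dict):
        labels = list(groups.keys())
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for lab, a in zip(labels, arrays):
        if a.size == 0:
            raise ValueError(f"group {lab!r} is empty")
    return arrays, labels


def kruskal_wallis(groups) -> GroupComparison:
    """Kruskal-Wallis rank test with tie correction.

    H is computed on midranks of the pooled sample and divided by the
    standard tie-correction factor; the p-value comes from the
    chi-square distribution with k-1 degrees of freedom. When every
    pooled value is identical the correction factor vanishes and the
    convention H = 0, p = 1 is adopted.
    """
    arrays, labels = _as_groups(groups)
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += a.size * (np.mean(r) - (n_total + 1) / 2.0) ** 2
        start += a.size
    h *= 12.0 / (n_total * (n_total + 1))
    ties = _tie_counts(pooled)
    correction = 1.0 - np.sum(ties**3 - ties) / (n_total**3 - n_total)
    if correction <= 0:
        h_corr, p = 0.0, 1.0
    else:
        h_corr = h / correction
        p = float(spstats.chi2.sf(h_corr, df=len(arrays) - 1))
    return GroupComparison(
        test="kruskal-wallis",
        statistic=float(h_corr),
        df=(len(arrays) - 1,),
        p_value=p,
        groups=[(lab, int(a.size)) for lab, a in zip(labels, arrays)],
    )


def adjust_pvalues(p, method: str = "none") -> np.ndarray:
    """Multiplicity adjustment: ``none``, ``bonferroni`` or ``holm``."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment method {method!r}")


def dunn_posthoc(groups, adjustment: str = "none") -> pd.DataFrame:
    """Dunn's pairwise mean-rank comparisons after a Kruskal-Wallis test.

    For groups i, j with mean midranks rbar over the pooled sample,

        z_ij = (rbar_i - rbar_j) /
               sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)),

    where T = sum(t^3 - t) over tie groups; two-sided p-values come
    from the standard normal. ``adjustment`` applies Bonferroni or Holm
    correction across the k(k-1)/2 pairs.
    """
    arrays, labels = _as_groups(groups)
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = _midranks(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(float(np.mean(ranks[start : start + a.size])))
        start += a.size
    ties = _tie_counts(pooled)
    tie_term = float(np.sum(ties**3 - ties))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            var = base_var * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
            if var <= 0:
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = float(2.0 * spstats.norm.sf(abs(z)))
            rows.append(
                {"group_i": labels[i], "group_j": labels[j],
                 "z": float(z), "p_unadjusted": p}
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = adjust_pvalues(table["p_unadjusted"].to_numpy(), adjustment)
    return table


def one_way_anova(groups) -> GroupComparison:
    """Classical one-way ANOVA (between/within decomposition).

    Degenerate inputs follow the conventions: zero within-group variance
    with equal group means gives F = 0; with unequal means gives an
    infinite F (p = 0), flagged by the statistic itself.
    """
    arrays, labels = _as_groups(groups)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    if n_total <= k:
        raise ValueError("need more observations than groups")
    grand = np.mean(np.concatenate(arrays))
    ssb = sum(a.size * (np.mean(a) - grand) ** 2 for a in arrays)
    ssw = sum(float(np.sum((a - np.mean(a)) ** 2)) for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0:
        if ssb == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        p = float(spstats.f.sf(f_stat, df_b, df_w))
    return GroupComparison(
        test="one-way-anova",
        statistic=float(f_stat),
        df=(df_b, df_w),
        p_value=p,
        groups=[(lab, int(a.size)) for lab, a in zip(labels, arrays)],
    )


@dataclass
class RmrModelFit:
    """ln(RMR) ~ slope * temperature + intercept[watershed] fit."""

    slope_per_c: float
    intercepts: dict[str, float]
    residual_sd: float
    n: int
    n_dropped: int = 0

    def predict(self, temp_c: float, watershed: str) -> float:
        """Predicted RMR (back-transformed from the log scale)."""
        return float(np.exp(self.slope_per_c * temp_c + self.intercepts[watershed]))


def fit_rmr_model(rows: pd.DataFrame) -> RmrModelFit:
    """Log-linear routine-metabolic-rate model with watershed intercepts.

    Fits ln(rmr) = slope * temp_c + intercept[watershed] by ordinary
    least squares over a long-format table with columns ``rmr``,
    ``temp_c`` and ``watershed``. Non-positive RMR rows are dropped
    with a warning. This is a fixed-effects approximation: treatment
    and fish random intercepts are absorbed into the residual.
    """
    df = rows.copy()
    required = {"rmr", "temp_c", "watershed"}
    if not required.issubset(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    bad = df["rmr"] <= 0
    n_dropped = int(bad.sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} rows with non-positive RMR")
        df = df[~bad]
    watersheds = sorted(df["watershed"].unique())
    if len(watersheds) < 1 or len(df) < max(10, len(watersheds) + 1):
        raise ValueError("insufficient data for the RMR model")
    y = np.log(df["rmr"].to_numpy(dtype=float))
    temp = df["temp_c"].to_numpy(dtype=float)
    dummies = np.column_stack(
        [(df["watershed"] == w).to_numpy(dtype=float) for w in watersheds]
    )
    design = np.column_stack([temp, dummies])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = max(len(y) - design.shape[1], 1)
    return RmrModelFit(
        slope_per_c=float(coef[0]),
        intercepts={w: float(c) for w, c in zip(watersheds, coef[1:])},
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n=int(len(y)),
        n_dropped=n_dropped,
    )
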