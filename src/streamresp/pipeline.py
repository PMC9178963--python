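"""End-to-end runs: simulate (or read) trials -> traits -> recovery ->
routine rates -> thermal risk -> group statistics.

`run_pipeline` executes the whole analysis from a single `RunConfig`,
writing plain-CSV tables plus a manifest that records the seed and a
hash of every tunable, so a rerun with the same config in simulate mode
is reproducible row for row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import recovery as rec
from . import stats as gstats
from . import synthetic, thermal, traces as tr, traits

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "process_cohort"]


@dataclass
class RunConfig:
    """Tunable settings for one pipeline run."""

    mode: str = "simulate"  # "simulate" | "read-traces"
    seed: int = 0
    outdir: str = "streamresp_run"
    traces_dir: str | None = None  # read-traces mode
    metadata_path: str | None = None
    site_table_path: str | None = None
    measure_min: float = 6.0
    flush_min: float = 4.0
    trim_s: float = 0.0
    sample_interval_s: float = 5.0
    n_per_treatment: int = 8
    bin_width_c: float = 1.0
    fas_threshold: float = 3.0
    adjustment: str = "none"
    smoothing_lam: float | None = None
    background_interpolation: str = "linear"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    traits: pd.DataFrame
    recovery: pd.DataFrame
    rmr: pd.DataFrame
    risk: pd.DataFrame
    stats: pd.DataFrame
    pairwise: pd.DataFrame
    failures: pd.DataFrame
    manifest: dict


def _background_model(
    pre_trace: tr.O2Trace | None,
    post_trace: tr.O2Trace | None,
    plan: tr.CyclePlan,
    interpolation: str,
) -> tr.BackgroundModel:
    def first_slope(trace):
        if trace is None:
            return None
        bounds = tr.segment_cycles(trace, plan)
        slopes = [
            w.slope_mg_per_l_min
            for b in bounds
            if (w := tr.estimate_slope(trace, b, plan.trim_s)).valid
        ]
        return float(np.mean(slopes)) if slopes else None

    return tr.BackgroundModel(
        pre_slope=first_slope(pre_trace),
        post_slope=first_slope(post_trace),
        interpolation=interpolation,  # type: ignore[arg-type]
    )


def process_fish(
    trace: tr.O2Trace,
    background: tr.BackgroundModel,
    mass_g: float,
    fork_length_mm: float | None,
    plan: tr.CyclePlan,
    bin_width_c: float = 1.0,
    smoothing_lam: float | None = None,
) -> tuple[dict, dict, list[traits.RmrEstimate], tr.MO2Series]:
    """Single-fish analysis: one trait row, one recovery row, RMR bins."""
    series = tr.build_mo2_series(trace, plan, background, mass_g / 1000.0)
    smr, smr_temp, smr_n = traits.estimate_smr(series)
    mmr, mmr_time, mmr_temp = traits.estimate_mmr(series)
    aas, fas = traits.aerobic_scope(smr, mmr)
    k = (
        traits.condition_factor(mass_g, fork_length_mm)
        if fork_length_mm is not None
        else None
    )
    rr = rec.recovery_metrics(series, smr, mmr, mmr_time, lam=smoothing_lam)
    epoc_end_s = mmr_time + rr.time_epoc_h * 3600.0
    rmr_bins = traits.estimate_rmr(series, epoc_end_s, bin_width_c=bin_width_c)
    trait_row = {
        "fish_id": series.fish_id,
        "mass_g": mass_g,
        "fork_length_mm": fork_length_mm,
        "smr": smr,
        "smr_temp_c": smr_temp,
        "smr_n": smr_n,
        "mmr": mmr,
        "mmr_time_s": mmr_time,
        "mmr_temp_c": mmr_temp,
        "aas": aas,
        "fas": fas,
        "condition_k": k,
        "mean_test_temp_c": float(np.mean(series.temp_c)),
        "n_cycles": len(series),
        "background_fraction": series.background_fraction,
    }
    recovery_row = {
        "fish_id": series.fish_id,
        "time_mmr50_min": rr.time_mmr50_min,
        "time_epoc_h": rr.time_epoc_h,
        "crossed_50": rr.crossed_50,
        "crossed_epoc": rr.crossed_epoc,
        "smoothing_param": rr.smoothing_param,
    }
    return trait_row, recovery_row, rmr_bins, series


def process_cohort(
    dataset: synthetic.CohortDataset,
    config: RunConfig,
) -> PipelineResult:
    """Run the full analysis over a simulated cohort."""
    plan = tr.CyclePlan(config.measure_min, config.flush_min, config.trim_s)
    meta = dataset.metadata.set_index("fish_id")
    trait_rows, recovery_rows, rmr_rows, failures = [], [], [], []
    for fish_id, (trace, _gt) in dataset.trials.items():
        info = meta.loc[fish_id]
        try:
            bg = _background_model(
                dataset.background_pre.get(fish_id),
                dataset.background_post.get(fish_id),
                plan,
                config.background_interpolation,
            )
            trow, rrow, rmr_bins, _ = process_fish(
                trace, bg, float(info["mass_g"]), float(info["fork_length_mm"]),
                plan, config.bin_width_c, config.smoothing_lam,
            )
        except Exception as exc:  # keep going; report per-fish failures
            failures.append({"fish_id": fish_id, "error": str(exc)})
            continue
        for row in (trow, rrow):
            row["watershed"] = info["watershed"]
            row["treatment"] = info["treatment"]
        trait_rows.append(trow)
        recovery_rows.append(rrow)
        for b in rmr_bins:
            rmr_rows.append(
                {
                    "fish_id": fish_id,
                    "watershed": info["watershed"],
                    "treatment": info["treatment"],
                    "temp_bin_c": b.temp_bin_c,
                    "rmr": b.rmr,
                    "n": b.n,
                }
            )
    trait_df = pd.DataFrame(trait_rows)
    recovery_df = pd.DataFrame(recovery_rows)
    rmr_df = pd.DataFrame(rmr_rows)
    failures_df = pd.DataFrame(failures, columns=["fish_id", "error"])

    # thermal risk layer
    sites = (
        thermal.read_site_table(config.site_table_path)
        if config.site_table_path
        else {ws.context.watershed: ws.context for ws in dataset.scenario.watersheds.values()}
    )
    ctmax_by_ws: dict[str, list[float]] = {}
    meta_ws = meta["watershed"].to_dict()
    for rec_ in dataset.ctmax_records:
        ws = meta_ws.get(rec_.fish_id)
        if ws is not None:
            ctmax_by_ws.setdefault(ws, []).append(rec_.loe_temp_c)
    fas_points = {
        ws: (grp["mean_test_temp_c"].tolist(), grp["fas"].tolist())
        for ws, grp in trait_df.groupby("watershed")
    }
    risk_df = thermal.risk_table(
        ctmax_by_ws, fas_points, sites=sites, fas_threshold=config.fas_threshold
    )

    # group statistics: each trait across treatments within watershed
    stat_rows, pair_rows = [], []
    merged = trait_df.merge(
        recovery_df[["fish_id", "time_mmr50_min"]], on="fish_id"
    )
    for ws, grp in merged.groupby("watershed"):
        for var in ("smr", "mmr", "aas", "fas", "time_mmr50_min"):
            samples = {
                t: g[var].dropna().to_numpy() for t, g in grp.groupby("treatment")
            }
            samples = {t: v for t, v in samples.items() if v.size}
            if len(samples) < 2:
                continue
            kw = gstats.kruskal_wallis(samples)
            stat_rows.append(
                {
                    "watershed": ws,
                    "variable": var,
                    "test": kw.test,
                    "statistic": kw.statistic,
                    "df": kw.df[0],
                    "p_value": kw.p_value,
                }
            )
            if kw.p_value < gstats.ALPHA:
                table = gstats.dunn_posthoc(samples, adjustment=config.adjustment)
                table.insert(0, "variable", var)
                table.insert(0, "watershed", ws)
                pair_rows.append(table)
    stats_df = pd.DataFrame(stat_rows)
    pairwise_df = (
        pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame()
    )

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_fish": int(len(trait_df)),
        "n_failures": int(len(failures_df)),
    }
    return PipelineResult(
        traits=trait_df,
        recovery=recovery_df,
        rmr=rmr_df,
        risk=risk_df,
        stats=stats_df,
        pairwise=pairwise_df,
        failures=failures_df,
        manifest=manifest,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute a configured run and write all output tables to ``outdir``."""
    if config.mode == "simulate":
        design = synthetic.TrialDesign(
            measure_min=config.measure_min,
            flush_min=config.flush_min,
            sample_interval_s=config.sample_interval_s,
            seed=config.seed,
        )
        dataset = synthetic.simulate_cohort(
            synthetic.default_scenario(
                seed=config.seed, design=design,
                n_per_treatment=config.n_per_treatment,
            )
        )
        result = process_cohort(dataset, config)
    elif config.mode == "read-traces":
        result = _run_read_traces(config)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("traits", "recovery", "rmr", "risk", "stats", "pairwise", "failures"):
        getattr(result, name).to_csv(out / f"{name}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return result


def _run_read_traces(config: RunConfig) -> PipelineResult:
    """Process pre-recorded trace CSVs listed in a metadata table.

    The metadata CSV needs columns ``fish_id, trace_path, mass_g`` and
    optionally ``fork_length_mm, watershed, treatment, bg_pre_path,
    bg_post_path, chamber_volume_l``; paths are resolved relative to the
    metadata file.
    """
    if not config.metadata_path:
        raise ValueError("read-traces mode needs metadata_path")
    meta_path = Path(config.metadata_path)
    meta = pd.read_csv(meta_path)
    root = meta_path.parent
    plan = tr.CyclePlan(config.measure_min, config.flush_min, config.trim_s)
    trait_rows, recovery_rows, rmr_rows, failures = [], [], [], []
    for _, row in meta.iterrows():
        fish_id = str(row["fish_id"])
        try:
            vol = float(row.get("chamber_volume_l", 2.0))
            trace = tr.read_trace_csv(root / row["trace_path"], vol, fish_id)
            pre = post = None
            if isinstance(row.get("bg_pre_path"), str):
                pre = tr.read_trace_csv(root / row["bg_pre_path"], vol)
            if isinstance(row.get("bg_post_path"), str):
                post = tr.read_trace_csv(root / row["bg_post_path"], vol)
            if pre is None and post is None:
                bg = tr.BackgroundModel(pre_slope=0.0, post_slope=0.0)
            else:
                bg = _background_model(pre, post, plan, config.background_interpolation)
            fl = row.get("fork_length_mm")
            fl = float(fl) if pd.notna(fl) else None
            trow, rrow, rmr_bins, _ = process_fish(
                trace, bg, float(row["mass_g"]), fl, plan,
                config.bin_width_c, config.smoothing_lam,
            )
        except Exception as exc:
            failures.append({"fish_id": fish_id, "error": str(exc)})
            continue
        for out_row in (trow, rrow):
            out_row["watershed"] = row.get("watershed", "")
            out_row["treatment"] = row.get("treatment", "")
        trait_rows.append(trow)
        recovery_rows.append(rrow)
        for b in rmr_bins:
            rmr_rows.append(
                {"fish_id": fish_id, "watershed": row.get("watershed", ""),
                 "treatment": row.get("treatment", ""),
                 "temp_bin_c": b.temp_bin_c, "rmr": b.rmr, "n": b.n}
            )
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_fish": len(trait_rows),
        "n_failures": len(failures),
    }
    return PipelineResult(
        traits=pd.DataFrame(trait_rows),
        recovery=pd.DataFrame(recovery_rows),
        rmr=pd.DataFrame(rmr_rows),
        risk=pd.DataFrame(),
        stats=pd.DataFrame(),
        pairwise=pd.DataFrame(),
        failures=pd.DataFrame(failures, columns=["fish_id", "error"]),
        manifest=manifest,
    )
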