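"""End-to-end orchestration: simulate -> nulls -> optimize -> compare ->
loops/connectivity -> statistics.

A pipeline run produces, for each colony and day, the Eq-style percentile
of the observed network and of each optimized network against the random
ensemble (both null models by default), then aggregates day-averaged
percentiles per colony, runs the nonparametric battery (Friedman across
the three uncorrelated objectives, Conover-Iman post hoc, Wilcoxon paired
differences per objective, Spearman correlations among objectives), and
computes loop centered ranks and trail connectivity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

import trailnets
from trailnets import loops as _loops
from trailnets import nulls as _nulls
from trailnets import optimize as _opt
from trailnets import stats as _stats
from trailnets.core import VegetationMap, observed_network
from trailnets.synth import GenParams, generate_colony, generate_map

logger = logging.getLogger(__name__)

#: ensemble sizes: field-scale analyses run 100,000; the desk preset
#: uses 1,000 (Monte-Carlo SE of a percentile ~ sqrt(p(100-p)/n) points)
SCALE_PRESETS = {"field": 100_000, "desk": 1000, "mini": 100}


@dataclass
class PipelineConfig:
    map_files: Sequence[str] = ()
    n_colonies: int = 1
    gen_params: Optional[GenParams] = None
    models: Sequence[str] = ("dependent", "independent")
    scale: str = "desk"
    n_networks: Optional[int] = None  # overrides the scale preset
    seed: int = 1
    out_dir: Optional[str] = None

    @property
    def ensemble_size(self) -> int:
        if self.n_networks is not None:
            return self.n_networks
        return SCALE_PRESETS[self.scale]


@dataclass
class PipelineReport:
    records: pd.DataFrame  # colony, day, model, objective, pct_obs, pct_opt, n
    aggregates: dict[str, pd.DataFrame]  # model -> colony x objective means
    stats: dict
    loops: pd.DataFrame
    connectivity: dict[str, float]
    manifest: dict

    def write(self, out_dir: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "percentiles.csv", index=False)
        for model, agg in self.aggregates.items():
            agg.to_csv(out / f"mean_percentiles_{model}.csv")
        self.loops.to_csv(out / "loops.csv", index=False)
        with open(out / "stats.json", "w") as fh:
            json.dump(self.stats, fh, indent=1, default=_jsonable)
        with open(out / "connectivity.json", "w") as fh:
            json.dump(self.connectivity, fh, indent=1)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    return str(o)


def percentile_records(
    vmap: VegetationMap,
    ensembles: dict[int, list],
    model: str,
    optimized: dict[int, dict[str, _opt.OptimizedNetwork]],
    observed_vectors: dict[int, _stats.ObjectiveVector],
    random_vectors: dict[int, list[_stats.ObjectiveVector]],
) -> pd.DataFrame:
    """Percentiles of observed and optimized networks against one ensemble."""
    rows = []
    for di, nets in ensembles.items():
        ens_vecs = random_vectors[di]
        obs_vec = observed_vectors[di]
        for obj in _opt.OBJECTIVES:
            ens_vals = [v[obj] for v in ens_vecs if v[obj] is not None]
            if not ens_vals:
                continue
            n = len(ens_vals)
            if obs_vec[obj] is None:
                logger.info("day %d: observed %s undefined; skipped", di, obj)
                continue
            pct_obs = _stats.percentile(obs_vec[obj], ens_vals)
            opt_vec = _stats.compute_objectives(optimized[di][obj].network, vmap)
            pct_opt = (
                _stats.percentile(opt_vec[obj], ens_vals)
                if opt_vec[obj] is not None
                else np.nan
            )
            rows.append(
                {
                    "colony": vmap.colony,
                    "day": di,
                    "model": model,
                    "objective": obj,
                    "obs_value": obs_vec[obj],
                    "opt_value": opt_vec[obj],
                    "pct_obs": pct_obs,
                    "pct_opt": pct_opt,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def analyze_colony(
    vmap: VegetationMap,
    n_networks: int,
    seed: int,
    models: Sequence[str] = ("dependent", "independent"),
) -> tuple[pd.DataFrame, list[_stats.ObjectiveVector], pd.DataFrame, dict]:
    """Full per-colony analysis; returns (records, random vectors pooled,
    loop table, connectivity entry)."""
    t0 = time.perf_counter()
    day_idx = [d.day_index for d in vmap.days]
    observed = {di: observed_network(vmap, di) for di in day_idx}
    observed_vectors = {
        di: _stats.compute_objectives(net, vmap) for di, net in observed.items()
    }
    optimized = {di: _opt.optimize_all(vmap, di) for di in day_idx}
    frames = []
    pooled_vectors: list[_stats.ObjectiveVector] = []
    for mi, model in enumerate(models):
        spec = _nulls.EnsembleSpec(n_networks=n_networks, model=model, seed=seed + 7919 * mi)
        ens = _nulls.generate_ensemble(vmap, spec)
        random_vectors = {
            di: [_stats.compute_objectives(net, vmap) for net in nets]
            for di, nets in ens.items()
        }
        for vecs in random_vectors.values():
            pooled_vectors.extend(vecs)
        frames.append(
            percentile_records(vmap, ens, model, optimized, observed_vectors, random_vectors)
        )
    records = pd.concat(frames, ignore_index=True)

    loop_rows = []
    for di, net in observed.items():
        recs = _loops.rank_loops(_loops.find_loops(net, vmap), vmap)
        for r in recs:
            loop_rows.append(
                {
                    "colony": vmap.colony,
                    "day": di,
                    "source": r.source,
                    "target": r.target,
                    "n_candidates": len(r.candidate_paths),
                    **{f"cr_{k}": v for k, v in (r.centered_ranks or {}).items()},
                }
            )
    loop_table = pd.DataFrame(loop_rows)
    try:
        conn, n_off = _loops.connectivity(vmap, list(observed.values()))
    except ValueError:
        conn, n_off = float("nan"), 0
    conn_entry = {"connectivity": conn, "n_off_trail_edges": n_off}
    logger.info("colony %s analyzed in %.1fs", vmap.colony, time.perf_counter() - t0)
    return records, pooled_vectors, loop_table, conn_entry


def optimizer_dominance(
    seeds: Sequence[int], n_networks: int = 1000, n_terminals: int = 4
) -> pd.DataFrame:
    """Eq-style percentiles of heuristic networks for their own objective.

    For each seed, generates a one-day synthetic map (200 nodes,
    ``n_terminals`` terminals), draws ``n_networks`` independent random
    networks for that day, builds the total-nodes and average-TI heuristic
    networks, and scores each against the ensemble.  Returns one row per
    (seed, objective) pair.
    """
    rows = []
    for seed in seeds:
        params = GenParams(seed=seed, n_days=1, n_terminals_per_day=(n_terminals, n_terminals))
        vmap, _ = generate_map(params)
        spec = _nulls.EnsembleSpec(n_networks=n_networks, model="independent", seed=seed + 100)
        ens = _nulls.generate_ensemble(vmap, spec)
        vecs = [_stats.compute_objectives(n, vmap) for n in ens[1]]
        for obj, fn in (
            ("total_nodes", _opt.approx_min_total_nodes),
            ("avg_ti", _opt.greedy_min_avg_ti),
        ):
            res = fn(vmap, 1)
            val = _stats.compute_objectives(res.network, vmap)[obj]
            ens_vals = [v[obj] for v in vecs if v[obj] is not None]
            rows.append(
                {
                    "seed": seed,
                    "objective": obj,
                    "value": val,
                    "pct": _stats.percentile(val, ens_vals),
                    "n": len(ens_vals),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis over one or more colonies (files or synthetic)."""
    maps: list[VegetationMap] = []
    for f in config.map_files:
        maps.append(VegetationMap.from_json(Path(f).read_text()))
    base = config.gen_params or GenParams()
    for i in range(config.n_colonies if not config.map_files else 0):
        params = dataclasses.replace(base, seed=config.seed + i)
        vmap, _ = generate_colony(params)
        maps.append(vmap)
    if not maps:
        raise ValueError("no maps: provide map_files or n_colonies >= 1")

    n = config.ensemble_size
    all_records, all_vectors, all_loops, conn = [], [], [], {}
    for i, vmap in enumerate(maps):
        rec, vecs, loop_t, c = analyze_colony(
            vmap, n, seed=config.seed + 104729 * (i + 1), models=config.models
        )
        all_records.append(rec)
        all_vectors.extend(vecs)
        all_loops.append(loop_t)
        conn[vmap.colony] = c
    records = pd.concat(all_records, ignore_index=True)
    loops_df = pd.concat(all_loops, ignore_index=True) if all_loops else pd.DataFrame()

    stats_out: dict = {"underpowered": n < 100}
    aggregates: dict[str, pd.DataFrame] = {}
    for model in config.models:
        sub = records[records["model"] == model]
        agg = _stats.aggregate_percentiles(sub)
        aggregates[model] = agg
        battery = agg[list(_stats.BATTERY_OBJECTIVES)]
        model_stats: dict = {}
        if battery.shape[0] >= 2 and not battery.isna().any().any():
            q, p = _stats.friedman(battery.to_numpy())
            model_stats["friedman_objectives"] = {"Q": q, "p": p}
            ci = _stats.conover_iman(battery.to_numpy(), labels=list(battery.columns))
            model_stats["conover_iman"] = ci.to_dict(orient="records")
            qc, pc = _stats.friedman(battery.to_numpy().T)
            model_stats["friedman_colonies"] = {"Q": qc, "p": pc}
        else:
            model_stats["friedman_objectives"] = None
            model_stats["note"] = "single colony: Friedman across colonies needs >= 2 blocks"
            if battery.shape[0] == 1:
                per_day = records[
                    (records["model"] == model)
                ].pivot_table(index="day", columns="objective", values="pct_obs")
                per_day = per_day[list(_stats.BATTERY_OBJECTIVES)].dropna()
                if per_day.shape[0] >= 2:
                    q, p = _stats.friedman(per_day.to_numpy())
                    model_stats["friedman_objectives_day_blocks"] = {"Q": q, "p": p}
        wil = {}
        for obj in _opt.OBJECTIVES:
            sub_o = _stats.comparison_differences(
                sub[sub["objective"] == obj].dropna(subset=["pct_obs", "pct_opt"])
            )
            if len(sub_o) >= 5:
                w, p = _stats.wilcoxon_paired(sub_o["d_rand"], sub_o["d_opt"])
                wil[obj] = {
                    "W": w,
                    "p": p,
                    "mean_d_rand": float(sub_o["d_rand"].mean()),
                    "mean_d_opt": float(sub_o["d_opt"].mean()),
                }
        model_stats["wilcoxon"] = wil
        stats_out[model] = model_stats

    if len(all_vectors) >= 5:
        corr = _stats.objective_correlations(all_vectors)
        stats_out["objective_correlations"] = corr.to_dict(orient="records")
        cg = corr[(corr["a"] == "total_nodes") & (corr["b"] == "total_length")]
        stats_out["total_length_total_nodes_correlated"] = bool(
            len(cg) and cg["spearman_r"].iloc[0] > 0
        )
    else:
        stats_out["objective_correlations"] = None
        stats_out["total_length_total_nodes_correlated"] = None
    if not loops_df.empty:
        recs = [
            _loops.LoopRecord(
                0, "", "", (), (),
                {k.replace("cr_", ""): row[k] for k in loops_df.columns if k.startswith("cr_")},
            )
            for _, row in loops_df.iterrows()
        ]
        stats_out["loop_summary"] = _loops.loop_summary(recs)

    manifest = {
        "package_version": trailnets.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_networks": n,
        "scale": config.scale,
        "models": list(config.models),
        "colonies": [m.colony for m in maps],
        "gen_params": base if not config.map_files else None,
        "orientation_rule": "bfs-from-root, ties toward larger node-id",
    }
    report = PipelineReport(records, aggregates, stats_out, loops_df, conn, manifest)
    if config.out_dir:
        report.write(config.out_dir)
    return report
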