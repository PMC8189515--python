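"""Config-driven reproduction of the headline experiments.

Ensembles on synthetic hierarchies regenerate the network across a
small pool of independent draws and distribute replicates over the pool
round-robin, so reported means average over both graph realizations and
dynamical noise.  Master seeds are sequential offsets from a base seed;
reusing one base across compared configurations gives common random
numbers (identical thresholds and attempted transmission pathways).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import DosageParams, run_ensemble
from .layered import LayeredGraph
from .metrics import EnsembleSummary
from .network_gen import SyntheticConfig, build_synthetic_hierarchy, make_base_rgg
from .org_io import read_org_network
from .seeding import SeedSpec

__all__ = [
    "ExperimentConfig",
    "master_seed_range",
    "ensemble_over_pool",
    "synthetic_pool",
    "baseline_rgg_experiment",
    "table2_experiment",
    "er_density_sweep",
    "size_sweep",
    "sir_adoption_suite",
    "si_consensus_suite",
    "survival_vs_removal",
    "empirical_suite",
]


@dataclass
class ExperimentConfig:
    """File-backed experiment description.

    ``networks`` maps a name either to a synthetic-config mapping
    (``{"synthetic": {...SyntheticConfig fields...}}``) or to CSV paths
    (``{"nodes": ..., "edges": ...}``).  ``params`` holds DosageParams
    overrides; ``seed_levels``/``seed_fracs``/``strategies`` span the
    experiment grid.
    """

    networks: dict
    params: DosageParams = field(default_factory=DosageParams)
    seed_levels: tuple = (1, 2, 3, "all")
    seed_fracs: tuple = (None, 0.015)
    strategies: tuple = ("random", "degree", "voterank", "onion")
    n_runs: int = 200
    base_seed: int = 0
    outdir: Path = Path("results")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        kwargs["networks"] = raw["networks"]
        if "params" in raw:
            kwargs["params"] = DosageParams(**raw["params"])
        for key in ("seed_levels", "seed_fracs", "strategies"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        if "outdir" in raw:
            kwargs["outdir"] = Path(raw["outdir"])
        return cls(**kwargs)

    def load_networks(self) -> dict:
        out = {}
        for name, spec in self.networks.items():
            if "synthetic" in spec:
                cfg = SyntheticConfig(**spec["synthetic"])
                out[name] = build_synthetic_hierarchy(cfg)[0]
            else:
                out[name] = read_org_network(spec["nodes"], spec["edges"])
        return out

TABLE2_TOPOLOGIES = ("isolated", "full", "rgg", "ba", "er")


def master_seed_range(base_seed: int, n_runs: int) -> list:
    """Sequential, unique, sub-2^31 master seeds for one ensemble."""
    return [int((base_seed + j) % (2**31 - 1)) for j in range(n_runs)]


def _combine(summaries: list) -> EnsembleSummary:
    """Pool EnsembleSummaries over a graph pool (same N and horizon)."""
    n_runs = sum(s.n_runs for s in summaries)
    w = np.array([s.n_runs for s in summaries], dtype=float)[:, None]
    consensus = {}
    for lvl in summaries[0].consensus_epochs:
        consensus[lvl] = np.concatenate(
            [s.consensus_epochs[lvl] for s in summaries]
        )
    return EnsembleSummary(
        n_runs=n_runs,
        n_total=summaries[0].n_total,
        i_max=np.concatenate([s.i_max for s in summaries]),
        peak_epoch=np.concatenate([s.peak_epoch for s in summaries]),
        extinction_epoch=np.concatenate(
            [s.extinction_epoch for s in summaries]
        ),
        mean_s=(w * [s.mean_s for s in summaries]).sum(0) / n_runs,
        mean_i=(w * [s.mean_i for s in summaries]).sum(0) / n_runs,
        mean_r=(w * [s.mean_r for s in summaries]).sum(0) / n_runs,
        mean_survival=(w * [s.mean_survival for s in summaries]).sum(0)
        / n_runs,
        consensus_epochs=consensus,
    )


def ensemble_over_pool(
    graphs: list,
    params: DosageParams,
    seed_spec: SeedSpec,
    master_seeds: list,
    backend: str = "numba",
) -> EnsembleSummary:
    """Distribute replicates round-robin over a pool of graphs."""
    pool = len(graphs)
    parts = []
    for p, g in enumerate(graphs):
        seeds_p = master_seeds[p::pool]
        if not seeds_p:
            continue
        parts.append(
            run_ensemble(
                g, params, seed_spec, len(seeds_p), seeds_p, backend=backend
            )
        )
    return _combine(parts)


def synthetic_pool(
    cfg: SyntheticConfig, pool_size: int, base_seed: int
) -> list:
    """Independent hierarchy draws differing only in the generator seed."""
    graphs = []
    for p in range(pool_size):
        cfg_p = SyntheticConfig(
            n_staff=cfg.n_staff,
            k_avg=cfg.k_avg,
            c_frac=cfg.c_frac,
            manager_topology=cfg.manager_topology,
            manager_k_or_p=cfg.manager_k_or_p,
            rng_seed=int((base_seed + 7919 * p) % (2**31 - 1)),
        )
        graphs.append(build_synthetic_hierarchy(cfg_p)[0])
    return graphs


def baseline_rgg_experiment(
    n_staff: int = 1000,
    k_avg: float = 20.0,
    seed_count: int = 1,
    n_runs: int = 500,
    base_seed: int = 0,
    pool_size: int = 25,
    params: DosageParams | None = None,
) -> EnsembleSummary:
    """Dosage model on a bare RGG (no managers), random staff seeding."""
    params = params or DosageParams()
    graphs = [
        make_base_rgg(n_staff, k_avg, int((base_seed + 7919 * p) % (2**31 - 1)))
        for p in range(pool_size)
    ]
    spec = SeedSpec(strategy="random", level=1, count=seed_count)
    return ensemble_over_pool(
        graphs, params, spec, master_seed_range(base_seed, n_runs)
    )


def table2_experiment(
    topologies=TABLE2_TOPOLOGIES,
    n_staff: int = 1000,
    k_avg: float = 20.0,
    c_frac: float = 0.06,
    n_runs: int = 300,
    base_seed: int = 0,
    pool_size: int = 25,
    params: DosageParams | None = None,
    seed_layers=(1, 2),
    seed_fracs=(None, 0.015),
) -> pd.DataFrame:
    """Mean peak adoption per manager topology x seed layer x seed size.

    Seed-size fractions and the reported adoption fractions both use the
    staff-layer size ``N = n_staff`` as the system-size constant (the
    manager layer rides on top of N), so ``0.015N`` seeds 15 nodes at
    N=1000 and a peak of 583 adopters counts as 0.583.  All cells share
    master seeds (common random numbers).
    """
    params = params or DosageParams()
    master_seeds = master_seed_range(base_seed, n_runs)
    rows = []
    for topology in topologies:
        er_p = k_avg / (round(c_frac * n_staff) - 1)
        cfg = SyntheticConfig(
            n_staff=n_staff,
            k_avg=k_avg,
            c_frac=c_frac,
            manager_topology=topology,
            manager_k_or_p=er_p if topology == "er" else k_avg,
            rng_seed=base_seed,
        )
        graphs = synthetic_pool(cfg, pool_size, base_seed)
        n_total = graphs[0].n_nodes
        scale = n_total / n_staff  # re-normalize fractions to N = n_staff
        for layer in seed_layers:
            for frac in seed_fracs:
                count = 1 if frac is None else int(round(frac * n_staff))
                spec = SeedSpec(strategy="random", level=layer, count=count)
                summ = ensemble_over_pool(graphs, params, spec, master_seeds)
                rows.append(
                    {
                        "topology": topology,
                        "seed_layer": layer,
                        "seed_size": "minimal" if frac is None else f"{frac}N",
                        "seed_count": count,
                        "i_max_mean": summ.i_max_mean * scale,
                        "i_max_se": summ.i_max_se * scale,
                        "n_runs": summ.n_runs,
                    }
                )
    return pd.DataFrame(rows)


def er_density_sweep(
    p_values,
    seed_layer: int = 2,
    seed_frac: float | None = 0.015,
    n_staff: int = 1000,
    k_avg: float = 20.0,
    c_frac: float = 0.06,
    n_runs: int = 300,
    base_seed: int = 0,
    pool_size: int = 10,
    params: DosageParams | None = None,
) -> pd.DataFrame:
    """Mean peak adoption vs ER manager-connection probability p."""
    params = params or DosageParams()
    master_seeds = master_seed_range(base_seed, n_runs)
    rows = []
    for p in p_values:
        topology = "isolated" if p == 0 else "er"
        cfg = SyntheticConfig(
            n_staff=n_staff,
            k_avg=k_avg,
            c_frac=c_frac,
            manager_topology=topology,
            manager_k_or_p=float(p),
            rng_seed=base_seed,
        )
        graphs = synthetic_pool(cfg, pool_size, base_seed)
        scale = graphs[0].n_nodes / n_staff
        count = 1 if seed_frac is None else int(round(seed_frac * n_staff))
        spec = SeedSpec(strategy="random", level=seed_layer, count=count)
        summ = ensemble_over_pool(graphs, params, spec, master_seeds)
        rows.append(
            {
                "p": float(p),
                "i_max_mean": summ.i_max_mean * scale,
                "i_max_se": summ.i_max_se * scale,
                "n_runs": summ.n_runs,
            }
        )
    return pd.DataFrame(rows)


def size_sweep(
    n_values,
    seed_layer: int = 1,
    seed_frac: float = 0.015,
    k_avg: float = 20.0,
    c_frac: float = 0.06,
    n_runs: int = 200,
    base_seed: int = 0,
    pool_size: int = 10,
    params: DosageParams | None = None,
) -> pd.DataFrame:
    """Mean peak adoption vs system size at 1.5% seeding.

    Manager connections stay minimal (isolated) and the manager count
    scales as c = 0.06 N.
    """
    params = params or DosageParams()
    rows = []
    for n_staff in n_values:
        cfg = SyntheticConfig(
            n_staff=int(n_staff),
            k_avg=k_avg,
            c_frac=c_frac,
            manager_topology="isolated",
            rng_seed=base_seed,
        )
        graphs = synthetic_pool(cfg, pool_size, base_seed)
        n_total = graphs[0].n_nodes
        scale = n_total / int(n_staff)
        spec = SeedSpec(
            strategy="random",
            level=seed_layer,
            count=max(1, int(round(seed_frac * int(n_staff)))),
        )
        summ = ensemble_over_pool(
            graphs, params, spec, master_seed_range(base_seed, n_runs)
        )
        rows.append(
            {
                "n_staff": int(n_staff),
                "n_total": n_total,
                "i_max_mean": summ.i_max_mean * scale,
                "i_max_se": summ.i_max_se * scale,
                "n_runs": summ.n_runs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# empirical-network (or fixture) suites
# ---------------------------------------------------------------------------

def _seed_count(graph: LayeredGraph, frac) -> int:
    return 1 if frac is None else max(1, int(round(frac * graph.n_nodes)))


def sir_adoption_suite(
    networks: dict,
    seed_levels=(1, 2, 3),
    seed_fracs=(None, 0.015),
    strategies=("random",),
    include_flat: bool = True,
    n_runs: int = 200,
    base_seed: int = 0,
    params: DosageParams | None = None,
) -> pd.DataFrame:
    """SIR peak-adoption grid over networks, seeds, strategies and modes.

    ``networks`` maps a name to a LayeredGraph.  ``include_flat`` adds
    the monoplex ablation (identical edges, manager override off) for
    every cell; hierarchical and flat cells share master seeds (CRN).
    Strategy cells may also use ``level="all"``.
    """
    params = params or DosageParams()
    flat_params = DosageParams(
        **{**asdict(params), "manager_override": False}
    )
    master_seeds = master_seed_range(base_seed, n_runs)
    rows = []
    for name, graph in networks.items():
        for strategy in strategies:
            for level in seed_levels:
                if level != "all" and int(level) not in graph.layers:
                    continue
                for frac in seed_fracs:
                    count = _seed_count(graph, frac)
                    eligible = (
                        graph.n_nodes
                        if level == "all"
                        else len(graph.nodes_in_layer(int(level)))
                    )
                    if count > eligible:
                        continue
                    spec = SeedSpec(
                        strategy=strategy, level=level, count=count
                    )
                    modes = [("hierarchical", params)]
                    if include_flat:
                        modes.append(("flat", flat_params))
                    for mode, pars in modes:
                        summ = run_ensemble(
                            graph, pars, spec, n_runs, master_seeds
                        )
                        rows.append(
                            {
                                "network": name,
                                "strategy": strategy,
                                "seed_level": level,
                                "seed_size": (
                                    "minimal" if frac is None else f"{frac}N"
                                ),
                                "seed_count": count,
                                "mode": mode,
                                "i_max_mean": summ.i_max_mean,
                                "i_max_se": summ.i_max_se,
                            }
                        )
    return pd.DataFrame(rows)


def si_consensus_suite(
    networks: dict,
    seed_levels=(1, 2, 3),
    seed_fracs=(None, 0.015),
    n_runs: int = 100,
    base_seed: int = 0,
    params: DosageParams | None = None,
) -> pd.DataFrame:
    """Mean time to 50/74/90/100% consensus with removal switched off."""
    base = params or DosageParams()
    si_params = DosageParams(
        **{**asdict(base), "si_mode": True, "early_stop_on_extinction": True}
    )
    master_seeds = master_seed_range(base_seed, n_runs)
    rows = []
    for name, graph in networks.items():
        for level in seed_levels:
            if level != "all" and int(level) not in graph.layers:
                continue
            for frac in seed_fracs:
                count = _seed_count(graph, frac)
                if level != "all" and count > len(
                    graph.nodes_in_layer(int(level))
                ):
                    continue
                spec = SeedSpec(strategy="random", level=level, count=count)
                summ = run_ensemble(
                    graph, si_params, spec, n_runs, master_seeds
                )
                row = {
                    "network": name,
                    "seed_level": level,
                    "seed_count": count,
                }
                row.update(
                    {
                        k: v
                        for k, v in summ.summary().items()
                        if k.startswith("consensus_")
                    }
                )
                rows.append(row)
    return pd.DataFrame(rows)


def survival_vs_removal(
    graph: LayeredGraph,
    r_values,
    checkpoint: int = 515,
    seed_level: int = 1,
    seed_frac: float = 0.015,
    n_runs: int = 100,
    base_seed: int = 0,
    params: DosageParams | None = None,
) -> pd.DataFrame:
    """Surviving fraction of the peak population at a checkpoint vs r.

    Runs continue to the full step budget (no early-stop truncation of
    trajectories) so the checkpoint epoch is always recorded; all r
    values share master seeds (CRN).
    """
    base = params or DosageParams()
    master_seeds = master_seed_range(base_seed, n_runs)
    spec = SeedSpec(
        strategy="random",
        level=seed_level,
        count=_seed_count(graph, seed_frac),
    )
    rows = []
    for r in r_values:
        pars = DosageParams(
            **{
                **asdict(base),
                "r": float(r),
                "early_stop_on_extinction": False,
            }
        )
        summ = run_ensemble(graph, pars, spec, n_runs, master_seeds)
        surv = summ.mean_survival
        val = (
            float(surv[checkpoint]) if checkpoint < len(surv) else np.nan
        )
        rows.append(
            {
                "r": float(r),
                "survival_at_checkpoint": val,
                "raw_i_at_checkpoint": (
                    float(summ.mean_i[checkpoint]) / graph.n_nodes
                    if checkpoint < len(summ.mean_i)
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def empirical_suite(
    networks: dict,
    n_runs: int = 200,
    base_seed: int = 0,
    params: DosageParams | None = None,
    strategies=("random", "degree", "voterank", "onion"),
    seed_levels=(1, 2, 3, "all"),
    seed_fracs=(None, 0.015),
) -> dict:
    """SI consensus, SIR adoption (with flat ablation) and strategy grid.

    Returns a dict of DataFrames: ``si_consensus``, ``sir_adoption``
    (random seeding) and ``strategy_comparison`` (all strategies,
    including the "all"-levels variant).
    """
    params = params or DosageParams()
    random_levels = tuple(l for l in seed_levels if l != "all")
    return {
        "si_consensus": si_consensus_suite(
            networks,
            seed_levels=random_levels,
            seed_fracs=seed_fracs,
            n_runs=max(n_runs // 2, 1),
            base_seed=base_seed,
            params=params,
        ),
        "sir_adoption": sir_adoption_suite(
            networks,
            seed_levels=random_levels,
            seed_fracs=seed_fracs,
            strategies=("random",),
            n_runs=n_runs,
            base_seed=base_seed,
            params=params,
        ),
        "strategy_comparison": sir_adoption_suite(
            networks,
            seed_levels=seed_levels,
            seed_fracs=seed_fracs,
            strategies=tuple(s for s in strategies if s != "random"),
            n_runs=n_runs,
            base_seed=base_seed,
            params=params,
        ),
    }
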