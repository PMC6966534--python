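"""Benchmark orchestration: simulate -> infer -> evaluate -> aggregate.

Runs the full tumor-biogeography experiment: simulated datasets for every
(seeding scenario x tumor-count class) cell, migration-history inference
with the parsimony and Bayesian methods, and F1 / path-type scoring
against the true migration graphs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import McmcConfig, MkModel, infer_bbm
from .evaluate import evaluate_graph, aggregate_benchmark, pooled_path_type_rates
from .graphs import MigrationGraph
from .parsimony import MigrationHistory, infer_pmh, resolve_polytomies_pmh_tr
from .phylo import GERMLINE, PRIMARY_SITE
from .simulate import (
    SCENARIOS,
    SimConfig,
    SimulatedDataset,
    simulate_dataset,
)

logger = logging.getLogger("tumorbiogeo")

METHODS = ("pmh-con", "pmh-tr", "pmh-unconstrained", "bbm-exact", "bbm-mcmc")
DEFAULT_METHODS = ("pmh-con", "pmh-tr", "bbm-exact")

__all__ = [
    "BenchmarkConfig",
    "METHODS",
    "DEFAULT_METHODS",
    "infer_dataset",
    "run_benchmark",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """One benchmark run.

    ``datasets_per_cell`` datasets are simulated for every scenario x
    tumor-class cell; the default of 10 per cell gives 20 datasets per
    scenario split evenly over the m5 and m8 classes.
    """

    scenarios: tuple[str, ...] = SCENARIOS
    tumor_classes: tuple[str, ...] = ("m5", "m8")
    datasets_per_cell: int = 10
    methods: tuple[str, ...] = DEFAULT_METHODS
    master_seed: int = 0
    mcmc_generations: int = 50_000
    mcmc_chains: int = 3
    mcmc_sample_interval: int = 10
    mcmc_burnin_samples: int = 500
    branch_scale: float = 0.05

    def __post_init__(self):
        if self.datasets_per_cell < 1:
            raise ValueError("need at least one dataset per cell")
        if not self.methods:
            raise ValueError("need at least one method")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")

    def full_scale(self) -> "BenchmarkConfig":
        """MCMC at full production scale (3 chains x 5M generations)."""
        return BenchmarkConfig(
            scenarios=self.scenarios,
            tumor_classes=self.tumor_classes,
            datasets_per_cell=self.datasets_per_cell,
            methods=self.methods,
            master_seed=self.master_seed,
            mcmc_generations=5_000_000,
            mcmc_chains=3,
            mcmc_sample_interval=1000,
            mcmc_burnin_samples=1000,
            branch_scale=self.branch_scale,
        )


def infer_dataset(
    ds: SimulatedDataset,
    method: str,
    branch_scale: float = 0.05,
    mcmc: McmcConfig | None = None,
) -> MigrationHistory:
    """Run one inference method on one dataset.

    Parsimony methods drop the germline leaf and constrain the root to
    the primary site (except ``pmh-unconstrained``); Bayesian methods keep
    the germline outgroup as the observation that pins the root to P.
    """
    sites = tuple(sorted(set(ds.leaf_labels.values()) | {PRIMARY_SITE}))
    has_germline = GERMLINE in ds.tree.parent or GERMLINE == ds.tree.root
    if method.startswith("pmh"):
        tree = ds.tree.without_leaf(GERMLINE) if has_germline else ds.tree
        if method == "pmh-con":
            return infer_pmh(tree, ds.leaf_labels, PRIMARY_SITE, sites=sites)
        if method == "pmh-unconstrained":
            return infer_pmh(tree, ds.leaf_labels, None, sites=sites)
        if method == "pmh-tr":
            _resolved, hist = resolve_polytomies_pmh_tr(
                tree, ds.leaf_labels, PRIMARY_SITE, sites=sites
            )
            return hist
    if method in ("bbm-exact", "bbm-mcmc"):
        labels = dict(ds.leaf_labels)
        if has_germline:
            labels[GERMLINE] = PRIMARY_SITE
        model = MkModel(n_states=len(sites), scale=branch_scale)
        hist, _post = infer_bbm(
            ds.tree,
            labels,
            model,
            mcmc=mcmc,
            estimator="exact-pruning" if method == "bbm-exact" else "mcmc",
            sites=sites,
        )
        return hist
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(config: BenchmarkConfig) -> dict:
    """Simulate, infer, and score the whole benchmark.

    Returns a dict with:
    - ``per_dataset``: DataFrame, one row per dataset x method;
    - ``summary_scenario`` / ``tests_scenario``: mean F1 per method x
      scenario and pairwise Z / Welch-t tests between scenarios;
    - ``summary_class`` / ``tests_class``: the same per tumor-count class;
    - ``path_rates``: micro-averaged FP/FN rates per path type per method.

    Per-dataset seeds are derived deterministically from the master seed,
    so reruns reproduce the exact methods bit for bit.
    """
    rows = []
    path_frames: dict[str, list] = {m: [] for m in config.methods}
    ss = np.random.SeedSequence(config.master_seed)
    n_cells = len(config.scenarios) * len(config.tumor_classes)
    cell_seeds = ss.spawn(n_cells * config.datasets_per_cell)
    mcmc_seed_root = int(ss.generate_state(1)[0] % (2**31 - 1))

    idx = 0
    for scenario in config.scenarios:
        for tclass in config.tumor_classes:
            for rep in range(config.datasets_per_cell):
                seed = int(cell_seeds[idx].generate_state(1)[0] % (2**31 - 1))
                idx += 1
                sim = SimConfig(scenario=scenario, tumor_class=tclass, seed=seed)
                t0 = time.perf_counter()
                ds = simulate_dataset(sim)
                name = f"{scenario}-{tclass}-{rep}"
                for method in config.methods:
                    mcmc = McmcConfig(
                        chains=config.mcmc_chains,
                        generations=config.mcmc_generations,
                        sample_interval=config.mcmc_sample_interval,
                        burnin_samples=config.mcmc_burnin_samples,
                        seed=(mcmc_seed_root + idx) % (2**31 - 1),
                    )
                    try:
                        hist = infer_dataset(ds, method, config.branch_scale, mcmc)
                    except Exception:
                        logger.exception("inference failed: %s on %s", method, name)
                        continue
                    report = evaluate_graph(hist.graph, ds.true_graph)
                    row = {
                        "dataset": name,
                        "scenario": scenario,
                        "tumor_class": tclass,
                        "seed": seed,
                        "method": method,
                        "n_clones": len(ds.leaf_labels),
                        "n_sites": len(ds.sites),
                        "migrations": hist.migrations,
                        "comigrations": hist.comigrations,
                        "sources": hist.sources,
                    }
                    row.update(report.as_row())
                    rows.append(row)
                    path_frames[method].append(report.path_counts)
                logger.info(
                    "%s done in %.2fs", name, time.perf_counter() - t0
                )

    per_dataset = pd.DataFrame(rows)
    summary_scenario, tests_scenario = aggregate_benchmark(
        per_dataset, ("method", "scenario")
    )
    summary_class, tests_class = aggregate_benchmark(
        per_dataset, ("method", "tumor_class")
    )
    path_rates = {
        m: pooled_path_type_rates(frames)
        for m, frames in path_frames.items()
        if frames
    }
    return {
        "per_dataset": per_dataset,
        "summary_scenario": summary_scenario,
        "tests_scenario": tests_scenario,
        "summary_class": summary_class,
        "tests_class": tests_class,
        "path_rates": path_rates,
    }


def write_benchmark(results: dict, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    results["per_dataset"].to_csv(d / "per_dataset.csv", index=False)
    results["summary_scenario"].to_csv(d / "summary_scenario.csv", index=False)
    results["tests_scenario"].to_csv(d / "tests_scenario.csv", index=False)
    results["summary_class"].to_csv(d / "summary_class.csv", index=False)
    results["tests_class"].to_csv(d / "tests_class.csv", index=False)
    for method, frame in results["path_rates"].items():
        frame.to_csv(d / f"path_rates_{method.replace('-', '_')}.csv")
    return d
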