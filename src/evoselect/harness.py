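"""Replicated selection experiments, feature-frequency rankings, and
cross-method comparison tables.

``run_replicated_experiment`` repeats a selector ``n_runs`` times with seeds
derived from one master seed, recording each run's operating-point accuracy,
subset size, wall time, and which features were selected.  Rankings count
how often each feature appears across runs; the comparison table reports
each method's mean (SD) accuracy and time difference from the cross-method
average.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CohortLabels, FeatureTable, SplitSpec
from .fitness import EvalConfig
from .metaheuristics import MetaheuristicConfig, run_method
from .nsga2 import NSGA2Config, nsga2_run

__all__ = [
    "ReplicationSummary",
    "ComparisonTable",
    "run_replicated_experiment",
    "feature_frequency_ranking",
    "compare_methods",
]

METHODS = ("nsga2", "ga", "aco", "sa", "pso")


@dataclass
class ReplicationSummary:
    """Bookkeeping for one method across n_runs seeded runs."""

    method: str
    n_runs: int
    feature_names: tuple[str, ...]
    accuracies: np.ndarray  # one per completed run
    subset_sizes: np.ndarray
    wall_times: np.ndarray
    selection_counts: np.ndarray  # per feature, <= n_runs
    run_seeds: list[int]
    failures: list[dict] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def mean_time(self) -> float:
        return float(np.mean(self.wall_times))

    @property
    def complete(self) -> bool:
        return not self.failures

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_runs": self.n_runs,
            "run_seeds": self.run_seeds,
            "accuracies": [float(a) for a in self.accuracies],
            "subset_sizes": [int(s) for s in self.subset_sizes],
            "wall_times": [float(t) for t in self.wall_times],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "selection_counts": {
                name: int(c) for name, c in zip(self.feature_names, self.selection_counts)
            },
            "failures": self.failures,
            "complete": self.complete,
        }


def _run_seeds(master_seed: int, n_runs: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n_runs)
    return [int(s) for s in state]


def run_replicated_experiment(
    table: FeatureTable,
    labels: CohortLabels,
    method: str,
    n_runs: int = 100,
    master_seed: int = 0,
    eval_cfg: EvalConfig | None = None,
    nsga2_cfg: NSGA2Config | None = None,
    meta_cfg: MetaheuristicConfig | None = None,
) -> ReplicationSummary:
    """n_runs independent seeded runs of one selector.

    Each run gets its own method seed and split seed (both derived from the
    master seed), so runs differ in initialisation and in the 80/20 split —
    mirroring repeated simulations.  Failed runs are recorded in
    ``failures`` and excluded from the aggregates.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    eval_cfg = eval_cfg or EvalConfig()
    seeds = _run_seeds(master_seed, n_runs)

    accuracies: list[float] = []
    sizes: list[int] = []
    times: list[float] = []
    counts = np.zeros(table.n_features, dtype=int)
    failures: list[dict] = []
    for run_i, seed in enumerate(seeds):
        split = replace(eval_cfg.split, seed=seed)
        cfg_run = eval_cfg.with_split(split)
        t0 = time.perf_counter()
        try:
            if method == "nsga2":
                cfg = replace(nsga2_cfg or NSGA2Config(), seed=seed)
                res = nsga2_run(table, labels, cfg_run, cfg)
                mask = res.operating_point
                record = res.operating_record
            else:
                cfg = replace(meta_cfg or MetaheuristicConfig(), seed=seed)
                res = run_method(method, table, labels, cfg_run, cfg)
                mask = res.best_mask
                record = res.best_record
        except Exception as exc:  # noqa: BLE001 — runs are independent
            failures.append({"run": run_i, "seed": seed, "error": repr(exc)})
            continue
        times.append(time.perf_counter() - t0)
        accuracies.append(record.accuracy)
        sizes.append(record.n_features)
        counts += mask.astype(int)

    return ReplicationSummary(
        method=method,
        n_runs=n_runs,
        feature_names=table.feature_names,
        accuracies=np.asarray(accuracies),
        subset_sizes=np.asarray(sizes, dtype=int),
        wall_times=np.asarray(times),
        selection_counts=counts,
        run_seeds=seeds,
        failures=failures,
    )


def feature_frequency_ranking(summary: ReplicationSummary, top_k: int = 5) -> list[str]:
    """Features sorted by how often they were selected across runs
    (descending), ties broken alphabetically; the first top_k are returned."""
    p = len(summary.feature_names)
    if top_k > p:
        raise ValueError(f"top_k={top_k} exceeds the feature count {p}")
    order = sorted(
        range(p), key=lambda j: (-summary.selection_counts[j], summary.feature_names[j])
    )
    return [summary.feature_names[j] for j in order[:top_k]]


@dataclass
class ComparisonTable:
    """Per-method mean (SD) accuracy and wall-time deltas vs the cross-method
    average; deltas sum to ~0 across methods."""

    methods: list[str]
    accuracy_delta_mean: np.ndarray
    accuracy_delta_sd: np.ndarray
    time_delta_mean: np.ndarray
    time_delta_sd: np.ndarray
    aligned: bool  # True when all methods completed the same runs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.methods,
                "accuracy_delta_mean": self.accuracy_delta_mean,
                "accuracy_delta_sd": self.accuracy_delta_sd,
                "time_delta_mean": self.time_delta_mean,
                "time_delta_sd": self.time_delta_sd,
            }
        )


def compare_methods(summaries: Sequence[ReplicationSummary]) -> ComparisonTable:
    """Mean (SD) per-method difference from the all-method average.

    When every summary holds the same number of completed runs, deltas are
    computed per run (each run's value minus that run's cross-method mean),
    giving paired SDs.  Otherwise methods are compared on their means alone
    and the table is flagged as unaligned.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two method summaries to compare")
    methods = [s.method for s in summaries]
    lengths = {len(s.accuracies) for s in summaries}
    aligned = len(lengths) == 1

    if aligned:
        acc = np.vstack([s.accuracies for s in summaries])  # (methods, runs)
        tim = np.vstack([s.wall_times for s in summaries])
        acc_delta = acc - acc.mean(axis=0, keepdims=True)
        tim_delta = tim - tim.mean(axis=0, keepdims=True)
        ddof = 1 if acc.shape[1] > 1 else 0
        return ComparisonTable(
            methods=methods,
            accuracy_delta_mean=acc_delta.mean(axis=1),
            accuracy_delta_sd=acc_delta.std(axis=1, ddof=ddof),
            time_delta_mean=tim_delta.mean(axis=1),
            time_delta_sd=tim_delta.std(axis=1, ddof=ddof),
            aligned=True,
        )

    acc_means = np.array([s.mean_accuracy for s in summaries])
    tim_means = np.array([s.mean_time for s in summaries])
    return ComparisonTable(
        methods=methods,
        accuracy_delta_mean=acc_means - acc_means.mean(),
        accuracy_delta_sd=np.array([s.sd_accuracy for s in summaries]),
        time_delta_mean=tim_means - tim_means.mean(),
        time_delta_sd=np.array(
            [float(np.std(s.wall_times, ddof=1)) if len(s.wall_times) > 1 else 0.0 for s in summaries]
        ),
        aligned=False,
    )
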