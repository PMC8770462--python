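"""Single-objective binary subset selectors: GA, ACO, SA and PSO.

All four minimize the scalarized fitness

    value = classification_error + lam * (n_selected / p)

so that subset size is lightly penalized and results are comparable with the
two-objective selector.  Every method shares the same evaluation budget
semantics (population/colony/swarm size x iterations, plus initialisation)
and is fully seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import CohortLabels, FeatureTable
from .fitness import EvalConfig, FitnessRecord, SubsetEvaluator

__all__ = [
    "MetaheuristicConfig",
    "BestSubsetResult",
    "scalar_fitness",
    "ga_run",
    "aco_run",
    "sa_run",
    "pso_run",
    "run_method",
]


def scalar_fitness(record: FitnessRecord, lam: float, p: int) -> float:
    """error + lam * (n_features / p); reduces to pure error at lam = 0."""
    return record.error + lam * (record.n_features / p)


@dataclass(frozen=True)
class MetaheuristicConfig:
    """Shared knobs plus per-algorithm rates (unused ones are ignored)."""

    population_size: int = 25
    iterations: int = 50
    lam: float = 0.01
    seed: int = 0
    # GA
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    # ACO
    evaporation: float = 0.2
    tau_min: float = 0.05
    tau_max: float = 0.95
    # SA (iterations for SA are single-candidate steps)
    t_init: float = 0.1
    cooling: float = 0.95
    # PSO
    inertia: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    v_max: float = 4.0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for r in (self.crossover_rate, self.mutation_rate, self.evaporation):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if not (0.0 < self.tau_min < self.tau_max < 1.0):
            raise ValueError("need 0 < tau_min < tau_max < 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class BestSubsetResult:
    """Best mask found, its fitness, and the best-so-far trajectory."""

    method: str
    best_mask: np.ndarray
    best_fitness: float
    best_record: FitnessRecord
    trajectory: np.ndarray  # best-so-far value per iteration
    evaluation_count: int
    training_count: int
    seed: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "best_mask": "".join("1" if b else "0" for b in self.best_mask),
            "best_fitness": self.best_fitness,
            "error": self.best_record.error,
            "accuracy": self.best_record.accuracy,
            "n_features": self.best_record.n_features,
            "trajectory": [float(v) for v in self.trajectory],
            "evaluation_count": self.evaluation_count,
            "training_count": self.training_count,
        }


class _Tracker:
    """Keeps the global best and the per-iteration best-so-far trajectory."""

    def __init__(self, evaluator: SubsetEvaluator, lam: float, p: int):
        self.evaluator = evaluator
        self.lam = lam
        self.p = p
        self.best_value = np.inf
        self.best_mask: np.ndarray | None = None
        self.best_record: FitnessRecord | None = None
        self.trajectory: list[float] = []

    def score(self, mask: np.ndarray) -> float:
        rec = self.evaluator.evaluate(mask)
        value = scalar_fitness(rec, self.lam, self.p)
        if value < self.best_value:
            self.best_value = value
            self.best_mask = np.asarray(mask, dtype=bool).copy()
            self.best_record = rec
        return value

    def tick(self) -> None:
        self.trajectory.append(self.best_value)

    def result(self, method: str, seed: int, extras: dict | None = None) -> BestSubsetResult:
        return BestSubsetResult(
            method=method,
            best_mask=self.best_mask,
            best_fitness=self.best_value,
            best_record=self.best_record,
            trajectory=np.asarray(self.trajectory),
            evaluation_count=self.evaluator.call_count,
            training_count=self.evaluator.train_count,
            seed=seed,
            extras=extras or {},
        )


def _make_tracker(table, labels, eval_cfg, cfg, evaluator):
    if evaluator is None:
        evaluator = SubsetEvaluator(table, labels, eval_cfg)
    return _Tracker(evaluator, cfg.lam, table.n_features)


def _random_nonempty(rng: np.random.Generator, p: int) -> np.ndarray:
    mask = rng.random(p) < 0.5
    while not mask.any():
        mask = rng.random(p) < 0.5
    return mask


def ga_run(
    table: FeatureTable,
    labels: CohortLabels,
    eval_cfg: EvalConfig,
    cfg: MetaheuristicConfig,
    evaluator: SubsetEvaluator | None = None,
) -> BestSubsetResult:
    """Generational GA: binary tournament, uniform crossover, per-bit mutation,
    elitism of one."""
    rng = np.random.default_rng(cfg.seed)
    tracker = _make_tracker(table, labels, eval_cfg, cfg, evaluator)
    p = table.n_features
    N = cfg.population_size

    pop = np.array([_random_nonempty(rng, p) for _ in range(N)])
    values = np.array([tracker.score(m) for m in pop])
    for _ in range(cfg.iterations):
        elite = int(np.argmin(values))
        children = [pop[elite].copy()]
        while len(children) < N:
            ia, ib = rng.integers(0, N, size=2)
            pa = pop[ia] if values[ia] <= values[ib] else pop[ib]
            ic, idx = rng.integers(0, N, size=2)
            pb = pop[ic] if values[ic] <= values[idx] else pop[idx]
            if rng.random() < cfg.crossover_rate:
                take = rng.random(p) < 0.5
                child = np.where(take, pa, pb)
            else:
                child = pa.copy()
            child = child ^ (rng.random(p) < cfg.mutation_rate)
            children.append(child)
        pop = np.array(children)
        values = np.array([tracker.score(m) for m in pop])
        tracker.tick()
    return tracker.result("ga", cfg.seed)


def aco_run(
    table: FeatureTable,
    labels: CohortLabels,
    eval_cfg: EvalConfig,
    cfg: MetaheuristicConfig,
    evaluator: SubsetEvaluator | None = None,
) -> BestSubsetResult:
    """Binary ant colony: per-feature pheromone tau_j is the inclusion
    probability; evaporation pulls tau toward the global-best mask, clamped to
    [tau_min, tau_max]."""
    rng = np.random.default_rng(cfg.seed)
    tracker = _make_tracker(table, labels, eval_cfg, cfg, evaluator)
    p = table.n_features
    tau = np.full(p, 0.5)

    # global best starts at the empty subset (the sentinel worst fitness)
    tracker.score(np.zeros(p, dtype=bool))
    for _ in range(cfg.iterations):
        for _ant in range(cfg.population_size):
            mask = rng.random(p) < tau
            tracker.score(mask)
        if tracker.best_mask is not None:
            deposit = tracker.best_mask.astype(float)
            tau = (1.0 - cfg.evaporation) * tau + cfg.evaporation * deposit
        tau = np.clip(tau, cfg.tau_min, cfg.tau_max)
        tracker.tick()
    return tracker.result("aco", cfg.seed, extras={"pheromone": tau})


def sa_run(
    table: FeatureTable,
    labels: CohortLabels,
    eval_cfg: EvalConfig,
    cfg: MetaheuristicConfig,
    evaluator: SubsetEvaluator | None = None,
) -> BestSubsetResult:
    """Simulated annealing on single-bit flips with Metropolis acceptance and
    geometric cooling; tracks the best subset ever visited."""
    rng = np.random.default_rng(cfg.seed)
    tracker = _make_tracker(table, labels, eval_cfg, cfg, evaluator)
    p = table.n_features

    current = _random_nonempty(rng, p)
    cur_val = tracker.score(current)
    temp = cfg.t_init
    for _ in range(cfg.iterations):
        j = int(rng.integers(0, p))
        cand = current.copy()
        cand[j] = ~cand[j]
        cand_val = tracker.score(cand)
        delta = cand_val - cur_val
        if delta <= 0:
            accept = True
        elif temp > 0:
            accept = rng.random() < math.exp(-delta / temp)
        else:
            accept = False
        if accept:
            current, cur_val = cand, cand_val
        temp *= cfg.cooling
        tracker.tick()
    return tracker.result("sa", cfg.seed, extras={"final_temperature": temp})


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def pso_run(
    table: FeatureTable,
    labels: CohortLabels,
    eval_cfg: EvalConfig,
    cfg: MetaheuristicConfig,
    evaluator: SubsetEvaluator | None = None,
) -> BestSubsetResult:
    """Binary PSO: real velocities, bit j resampled 1 with probability
    sigmoid(v_j); personal/global best updates with inertia, velocities
    clamped to +-v_max."""
    rng = np.random.default_rng(cfg.seed)
    tracker = _make_tracker(table, labels, eval_cfg, cfg, evaluator)
    p = table.n_features
    N = cfg.population_size

    pos = np.array([_random_nonempty(rng, p) for _ in range(N)])
    vel = np.zeros((N, p))
    pvals = np.array([tracker.score(m) for m in pos])
    pbest = pos.copy()
    gbest = tracker.best_mask.copy()
    for _ in range(cfg.iterations):
        r1 = rng.random((N, p))
        r2 = rng.random((N, p))
        vel = (
            cfg.inertia * vel
            + cfg.c1 * r1 * (pbest.astype(float) - pos.astype(float))
            + cfg.c2 * r2 * (gbest.astype(float)[np.newaxis, :] - pos.astype(float))
        )
        np.clip(vel, -cfg.v_max, cfg.v_max, out=vel)
        pos = rng.random((N, p)) < _sigmoid(vel)
        vals = np.array([tracker.score(m) for m in pos])
        improved = vals < pvals
        pbest[improved] = pos[improved]
        pvals[improved] = vals[improved]
        gbest = tracker.best_mask.copy()
        tracker.tick()
    return tracker.result("pso", cfg.seed, extras={"velocity_max_abs": float(np.abs(vel).max())})


_RUNNERS: dict[str, Callable] = {
    "ga": ga_run,
    "aco": aco_run,
    "sa": sa_run,
    "pso": pso_run,
}


def run_method(
    name: str,
    table: FeatureTable,
    labels: CohortLabels,
    eval_cfg: EvalConfig,
    cfg: MetaheuristicConfig,
    evaluator: SubsetEvaluator | None = None,
) -> BestSubsetResult:
    try:
        runner = _RUNNERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(_RUNNERS)}") from None
    return runner(table, labels, eval_cfg, cfg, evaluator)
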