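"""NSGA-II binary feature selection minimizing (classification error, subset size).

The population is a set of binary inclusion masks.  Each generation fills a
mating pool by binary tournament on (nondomination rank, crowding distance),
applies uniform crossover to a configured fraction of the pool and per-bit
mutation to another fraction, merges parents, offspring and mutants, and
truncates back to the population size by (rank, crowding).  The returned
Pareto front is the nondominated subset of the final population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import CohortLabels, FeatureTable
from .fitness import EvalConfig, FitnessRecord, SubsetEvaluator

__all__ = [
    "NSGA2Config",
    "ParetoResult",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "nsga2_run",
    "select_operating_point",
]


def dominates(a, b) -> bool:
    """True iff a <= b in every objective and a < b in at least one (minimization)."""
    a = tuple(a)
    b = tuple(b)
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def fast_nondominated_sort(objectives) -> list[list[int]]:
    """Partition points into fronts: front 1 is the maximal nondominated set,
    front i+1 is nondominated once fronts <= i are removed.  O(M N^2)."""
    objs = [tuple(o) for o in objectives]
    n = len(objs)
    if n == 0:
        raise ValueError("objectives must be non-empty")
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominators = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                n_dominators[j] += 1
            elif dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                n_dominators[i] += 1
    fronts: list[list[int]] = []
    current = [i for i in range(n) if n_dominators[i] == 0]
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                n_dominators[j] -= 1
                if n_dominators[j] == 0:
                    nxt.append(j)
        current = sorted(nxt)
    return fronts


def crowding_distance(front_objectives) -> np.ndarray:
    """Per-member diversity: sum over objectives of the normalized gap between
    each member's neighbours; boundary members get infinity; a zero-range
    objective contributes nothing."""
    objs = np.asarray([tuple(o) for o in front_objectives], dtype=float)
    n, m = objs.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(objs[:, k], kind="stable")
        lo, hi = objs[order[0], k], objs[order[-1], k]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if hi > lo:
            gaps = (objs[order[2:], k] - objs[order[:-2], k]) / (hi - lo)
            interior = order[1:-1]
            finite = np.isfinite(dist[interior])
            dist[interior[finite]] += gaps[finite]
    return dist


@dataclass(frozen=True)
class NSGA2Config:
    """Population/operator settings (defaults follow the study configuration:
    population 25 = mating pool, crossover 14%, mutation percentage 0.4 with
    per-bit rate 0.1)."""

    population_size: int = 25
    mating_pool_size: int | None = None
    crossover_percentage: float = 0.14
    mutation_percentage: float = 0.4
    mutation_rate: float = 0.1
    max_generations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.crossover_percentage, self.mutation_percentage, self.mutation_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")

    @property
    def pool_size(self) -> int:
        return self.population_size if self.mating_pool_size is None else self.mating_pool_size


@dataclass
class ParetoResult:
    """Final population, its nondominated front, and the chosen operating point."""

    population_masks: np.ndarray  # (N, p) bool
    population_records: list[FitnessRecord]
    front_indices: list[int]  # indices into the final population
    operating_point: np.ndarray  # mask of the chosen front member
    operating_record: FitnessRecord
    generations_run: int
    evaluation_count: int
    training_count: int
    seed: int

    @property
    def front_masks(self) -> np.ndarray:
        return self.population_masks[self.front_indices]

    @property
    def front_records(self) -> list[FitnessRecord]:
        return [self.population_records[i] for i in self.front_indices]

    def front_objectives(self) -> set[tuple[float, int]]:
        return {r.objectives for r in self.front_records}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "generations_run": self.generations_run,
            "evaluation_count": self.evaluation_count,
            "training_count": self.training_count,
            "population": [
                {
                    "mask": "".join("1" if b else "0" for b in row),
                    "error": rec.error,
                    "n_features": rec.n_features,
                    "accuracy": rec.accuracy,
                }
                for row, rec in zip(self.population_masks, self.population_records)
            ],
            "front_indices": list(self.front_indices),
            "operating_point": {
                "mask": "".join("1" if b else "0" for b in self.operating_point),
                "error": self.operating_record.error,
                "n_features": self.operating_record.n_features,
                "accuracy": self.operating_record.accuracy,
            },
        }


def _rank_and_crowding(records: list[FitnessRecord]) -> tuple[np.ndarray, np.ndarray]:
    objs = [r.objectives for r in records]
    fronts = fast_nondominated_sort(objs)
    rank = np.zeros(len(objs), dtype=int)
    crowd = np.zeros(len(objs))
    for fi, front in enumerate(fronts):
        rank[front] = fi
        crowd[front] = crowding_distance([objs[i] for i in front])
    return rank, crowd


def _tournament(rng: np.random.Generator, rank: np.ndarray, crowd: np.ndarray) -> int:
    i, j = rng.integers(0, rank.size, size=2)
    if rank[i] != rank[j]:
        return int(i if rank[i] < rank[j] else j)
    if crowd[i] != crowd[j]:
        return int(i if crowd[i] > crowd[j] else j)
    return int(i)


def _uniform_crossover(
    rng: np.random.Generator, a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    take_a = rng.random(a.size) < 0.5
    c1 = np.where(take_a, a, b)
    c2 = np.where(take_a, b, a)
    return c1, c2


def nsga2_run(
    table: FeatureTable,
    labels: CohortLabels,
    eval_cfg: EvalConfig,
    cfg: NSGA2Config,
    evaluator: SubsetEvaluator | None = None,
) -> ParetoResult:
    """Run NSGA-II over feature subsets; seeded and fully deterministic."""
    rng = np.random.default_rng(cfg.seed)
    if evaluator is None:
        evaluator = SubsetEvaluator(table, labels, eval_cfg)
    p = table.n_features
    N = cfg.population_size

    pop = rng.random((N, p)) < 0.5
    for i in range(N):  # re-draw empty masks at init
        while not pop[i].any():
            pop[i] = rng.random(p) < 0.5
    records = [evaluator.evaluate(m) for m in pop]

    generations = 0
    for _ in range(cfg.max_generations):
        rank, crowd = _rank_and_crowding(records)
        pool_idx = [_tournament(rng, rank, crowd) for _ in range(cfg.pool_size)]
        pool = pop[pool_idx]

        n_pairs = math.ceil(cfg.crossover_percentage * cfg.pool_size)
        offspring = []
        for _ in range(n_pairs):
            ia, ib = rng.integers(0, cfg.pool_size, size=2)
            c1, c2 = _uniform_crossover(rng, pool[ia], pool[ib])
            offspring.extend([c1, c2])

        n_mut = math.ceil(cfg.mutation_percentage * cfg.pool_size)
        mutants = []
        for _ in range(n_mut):
            im = rng.integers(0, cfg.pool_size)
            flips = rng.random(p) < cfg.mutation_rate
            mutants.append(pool[im] ^ flips)

        new = offspring + mutants
        merged = np.vstack([pop] + [m[np.newaxis, :] for m in new]) if new else pop
        merged_records = records + [evaluator.evaluate(m) for m in new]

        rank, crowd = _rank_and_crowding(merged_records)
        # sort by (rank asc, crowding desc); stable for determinism
        order = sorted(range(len(merged_records)), key=lambda i: (rank[i], -crowd[i]))
        keep = order[:N]
        pop = merged[keep]
        records = [merged_records[i] for i in keep]
        generations += 1

    fronts = fast_nondominated_sort([r.objectives for r in records])
    front = fronts[0]
    op_idx = select_operating_point(pop, records, front)
    return ParetoResult(
        population_masks=pop,
        population_records=records,
        front_indices=front,
        operating_point=pop[op_idx].copy(),
        operating_record=records[op_idx],
        generations_run=generations,
        evaluation_count=evaluator.call_count,
        training_count=evaluator.train_count,
        seed=cfg.seed,
    )


def select_operating_point(
    masks: np.ndarray, records: list[FitnessRecord], front: list[int]
) -> int:
    """Front member with minimum error; ties to fewer features, then to the
    lexicographically smallest mask.  Returns its population index."""
    if not front:
        raise ValueError("front must be non-empty")
    return min(
        front,
        key=lambda i: (records[i].error, records[i].n_features, tuple(masks[i].astype(int))),
    )
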