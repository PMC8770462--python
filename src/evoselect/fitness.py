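"""Subset fitness: train the MLP on the selected features, score validation accuracy.

This is the wrapper objective every selector optimizes.  An evaluation
restricts the table to the columns of a binary mask, z-scores on the
training split only, trains ``n_restarts`` networks (keeping the one with
the lowest training MSE), and classifies the validation subjects at the
decision threshold.  Results are deterministic functions of
(table, labels, config, mask): restart seeds are derived from the mask bits,
so the same subset always receives the same fitness within a run — which
also makes caching sound.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .data import CohortLabels, FeatureTable, SplitSpec, standardize, stratified_split
from .mlp import TrainConfig, forward, init_network, train_lmbp

__all__ = ["EvalConfig", "FitnessRecord", "SubsetEvaluator", "evaluate_subset"]


@dataclass(frozen=True)
class FitnessRecord:
    """Objective pair (classification error, subset size) plus held-out accuracy."""

    error: float
    n_features: int
    accuracy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        if abs(self.error + self.accuracy - 1.0) > 1e-12:
            raise ValueError("error must equal 1 - accuracy")

    @property
    def objectives(self) -> tuple[float, int]:
        return (self.error, self.n_features)


@dataclass(frozen=True)
class EvalConfig:
    """How a subset is scored: split, trainer settings, restarts, threshold."""

    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_restarts: int = 3
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def with_split(self, split: SplitSpec) -> "EvalConfig":
        return replace(self, split=split)


SENTINEL_EMPTY = FitnessRecord(error=1.0, n_features=0, accuracy=0.0)


class SubsetEvaluator:
    """Caches the split, the standardized table, and per-mask fitness records."""

    def __init__(self, table: FeatureTable, labels: CohortLabels, cfg: EvalConfig):
        self.table = table
        self.labels = labels
        self.cfg = cfg
        self.train_idx, self.val_idx = stratified_split(labels, cfg.split)
        # z-scoring is column-wise, so standardizing the full table once and
        # subsetting columns later equals subset-then-standardize
        self._z = standardize(table, self.train_idx).values
        self._y = labels.labels.astype(float)
        self._cache: dict[bytes, FitnessRecord] = {}
        self.call_count = 0
        self.train_count = 0

    def _restart_seed(self, mask_key: bytes, restart: int) -> int:
        digest = zlib.crc32(mask_key)
        ss = np.random.SeedSequence([self.cfg.split.seed, digest, restart])
        return int(ss.generate_state(1)[0])

    def evaluate(self, mask: np.ndarray) -> FitnessRecord:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.table.n_features,):
            raise ValueError("mask length must equal the feature count")
        self.call_count += 1
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if not mask.any():
            self._cache[key] = SENTINEL_EMPTY
            return SENTINEL_EMPTY

        cols = np.flatnonzero(mask)
        X_tr = self._z[np.ix_(self.train_idx, cols)]
        X_val = self._z[np.ix_(self.val_idx, cols)]
        y_tr = self._y[self.train_idx][:, np.newaxis]
        y_val = self._y[self.val_idx]

        best_net = None
        best_mse = np.inf
        for r in range(self.cfg.n_restarts):
            net = init_network(cols.size, self._restart_seed(key, r))
            net, history = train_lmbp(net, X_tr, y_tr, self.cfg.train)
            out, _ = forward(net, X_tr)
            mse = float(np.mean((y_tr - out) ** 2))
            if mse < best_mse:
                best_mse = mse
                best_net = net
            self.train_count += 1

        out_val, _ = forward(best_net, X_val)
        pred = (out_val[:, 0] >= self.cfg.decision_threshold).astype(float)
        accuracy = float(np.mean(pred == y_val))
        rec = FitnessRecord(error=1.0 - accuracy, n_features=int(cols.size), accuracy=accuracy)
        self._cache[key] = rec
        return rec


def evaluate_subset(
    table: FeatureTable, labels: CohortLabels, mask: np.ndarray, cfg: EvalConfig
) -> FitnessRecord:
    """One-shot subset evaluation (empty mask returns the worst-fitness sentinel)."""
    return SubsetEvaluator(table, labels, cfg).evaluate(mask)
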