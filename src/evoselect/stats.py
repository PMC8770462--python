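"""Rank-sum tests, FDR correction, and the p-value-ranked accuracy baseline.

The two-sample comparison is a Mann-Whitney/Wilcoxon rank-sum test: exact by
enumeration of all group assignments when the pooled sample has at most
``EXACT_LIMIT`` observations, otherwise the tie-corrected normal
approximation.  Multiple comparisons are corrected with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data import CohortLabels, FeatureTable, SplitSpec
from .errors import EmptyGroupError

__all__ = [
    "RankSumResult",
    "AccuracyCurve",
    "ranksum_test",
    "fdr_adjust",
    "feature_test_table",
    "pvalue_ranked_accuracy_curve",
]

EXACT_LIMIT = 12


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided rank-sum test result for one feature."""

    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class AccuracyCurve:
    """Mean validation accuracy of the top-k smallest-p features, per k."""

    k_values: np.ndarray
    accuracy: np.ndarray
    sd: np.ndarray
    n_repeats: int
    feature_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.k_values) == len(self.accuracy) == len(self.sd)):
            raise ValueError("k_values/accuracy/sd lengths differ")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_values, "mean_accuracy": self.accuracy, "sd_accuracy": self.sd}
        )


def _u_statistic(pooled_ranks: np.ndarray, a_pos: np.ndarray, n_a: int) -> float:
    return float(pooled_ranks[a_pos].sum() - n_a * (n_a + 1) / 2.0)


def ranksum_test(group_a: Sequence[float], group_b: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum test of two independent samples.

    Exact two-sided p (probability, under random assignment of the pooled
    values to groups, of a U at least as far from its null mean n_a*n_b/2 as
    observed) when ``len(a) + len(b) <= EXACT_LIMIT``; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroupError("both groups must contain at least one value")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, np.arange(n_a), n_a)

    if n_a + n_b <= EXACT_LIMIT:
        mu = n_a * n_b / 2.0
        dev = abs(u_obs - mu)
        total = comb(n_a + n_b, n_a)
        hits = 0
        for pos in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks, np.array(pos), n_a)
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        return RankSumResult(u_obs, hits / total, "exact")

    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(res.statistic), float(res.pvalue), "asymptotic")


def fdr_adjust(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (significance mask, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must lie in (0, 1), got {q}")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def feature_test_table(
    table: FeatureTable, labels: CohortLabels, q: float = 0.05
) -> pd.DataFrame:
    """Per-feature rank-sum tests with BH correction across all features."""
    y = labels.labels
    rows = []
    for j, name in enumerate(table.feature_names):
        col = table.values[:, j]
        res = ranksum_test(col[y == 0], col[y == 1])
        rows.append((name, res.statistic, res.p_value, res.method))
    df = pd.DataFrame(rows, columns=["feature", "statistic", "p_value", "method"])
    sig, p_adj = fdr_adjust(df["p_value"].to_numpy(), q=q)
    df["p_adjusted"] = p_adj
    df["significant"] = sig
    return df


def pvalue_order(p_values: np.ndarray) -> np.ndarray:
    """Feature indices sorted by ascending p; ties keep original column order."""
    return np.argsort(p_values, kind="stable")


def pvalue_ranked_accuracy_curve(
    table: FeatureTable,
    labels: CohortLabels,
    k_max: int,
    eval_cfg,
    n_repeats: int = 1,
) -> AccuracyCurve:
    """Accuracy of the classifier on the top-k smallest-p features, k = 1..k_max.

    For each repeat a fresh split seed (derived from the evaluation config's
    split seed) is used; the curve reports mean and SD over repeats.  The
    curve is a pure function of (table, labels, eval_cfg, n_repeats).
    """
    from .fitness import SubsetEvaluator  # local import to avoid a cycle

    if k_max > table.n_features:
        raise ValueError("k_max exceeds the number of features")
    tests = feature_test_table(table, labels)
    order = pvalue_order(tests["p_value"].to_numpy())

    p = table.n_features
    acc = np.zeros((n_repeats, k_max))
    base_split = eval_cfg.split
    for r in range(n_repeats):
        split = SplitSpec(base_split.train_fraction, base_split.stratified, base_split.seed + r)
        cfg_r = eval_cfg.with_split(split)
        evaluator = SubsetEvaluator(table, labels, cfg_r)
        for k in range(1, k_max + 1):
            mask = np.zeros(p, dtype=bool)
            mask[order[:k]] = True
            acc[r, k - 1] = evaluator.evaluate(mask).accuracy
    return AccuracyCurve(
        k_values=np.arange(1, k_max + 1),
        accuracy=acc.mean(axis=0),
        sd=acc.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(k_max),
        n_repeats=n_repeats,
        feature_order=tuple(table.feature_names[i] for i in order[:k_max]),
    )
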