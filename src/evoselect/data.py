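"""Feature tables, cohort labels, synthetic cohort generation and splits.

A :class:`FeatureTable` is a named subjects-by-features matrix of positive
volumetric measurements (volumes, percentages, asymmetry indices — units are
arbitrary and heterogeneous).  Labels are binary: 0 = control, 1 = case.

The synthetic generator emulates a two-group cohort with correlated,
right-skewed positive marginals and a small planted subset of informative
features whose group means differ by a configured standardized effect on the
latent (log) scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import (
    ConstantFeatureWarning,
    DuplicateFeatureNameError,
    InvalidCorrelationError,
    InvalidSplitError,
    MissingValueError,
    NonNumericValueError,
    SingleClassLabelError,
)

__all__ = [
    "FeatureTable",
    "CohortLabels",
    "SynthConfig",
    "SplitSpec",
    "SynthCohort",
    "read_feature_table",
    "write_feature_table",
    "generate_synthetic_cohort",
    "standardize",
    "stratified_split",
]


@dataclass(frozen=True)
class FeatureTable:
    """Named subjects x features matrix.

    Invariants enforced at construction: unique feature names, dimensions
    consistent with the id/name lists, all values finite.
    """

    subject_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        object.__setattr__(self, "values", values)
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = sorted({f for f in self.feature_names if self.feature_names.count(f) > 1})
            raise DuplicateFeatureNameError(f"duplicate feature names: {dupes}")
        if values.ndim != 2 or values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(values)):
            raise MissingValueError("feature table contains missing or non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def select_features(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            self.subject_ids,
            tuple(self.feature_names[i] for i in idx),
            self.values[:, idx],
        )


@dataclass(frozen=True)
class CohortLabels:
    """One binary label per subject (0 = control, 1 = case)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        uniq = set(np.unique(labels).tolist())
        if not uniq <= {0, 1} or len(uniq) != 2:
            raise SingleClassLabelError(f"labels must contain both classes 0 and 1, got {sorted(uniq)}")

    @property
    def group_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def __len__(self) -> int:
        return int(self.labels.shape[0])


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic two-group cohort generator.

    ``correlation`` is the equicorrelation of the latent Gaussian (log-scale)
    features; ``skew`` scales the latent before exponentiation, so larger
    values give more strongly right-skewed marginals.  ``effect_sizes`` are
    standardized mean shifts applied to the latent scale of the informative
    features for the case group (scalar broadcasts to all of them).
    """

    n_per_group: tuple[int, int] = (56, 54)
    p: int = 142
    k_informative: int = 8
    effect_sizes: float | tuple[float, ...] = 1.0
    correlation: float = 0.3
    skew: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.p:
            raise ValueError("k_informative must be <= p")
        if not (0.0 <= self.correlation < 1.0):
            raise InvalidCorrelationError(
                f"equicorrelation must lie in [0, 1), got {self.correlation}"
            )
        eff = np.atleast_1d(np.asarray(self.effect_sizes, dtype=float))
        if not np.all(np.isfinite(eff)):
            raise ValueError("effect sizes must be finite")
        if eff.size not in (1, self.k_informative) and self.k_informative > 0:
            raise ValueError("effect_sizes must be scalar or length k_informative")

    def effects(self) -> np.ndarray:
        eff = np.atleast_1d(np.asarray(self.effect_sizes, dtype=float))
        if eff.size == 1:
            eff = np.full(self.k_informative, float(eff[0]))
        return eff


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split specification (default 80/20, stratified)."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise InvalidSplitError(
                f"train_fraction must lie strictly in (0, 1), got {self.train_fraction}"
            )


class SynthCohort(NamedTuple):
    table: FeatureTable
    labels: CohortLabels
    metadata: dict


def read_feature_table(path: str | Path, label_column: str) -> tuple[FeatureTable, CohortLabels]:
    """Read a delimited feature table (comma or tab, header row, row = subject).

    The first column is taken as the subject identifier when named ``subject``
    or ``subject_id``; otherwise the row index is used.  The label column must
    contain exactly two distinct values; they are mapped to 0/1 in sorted
    order (e.g. ``CN`` -> 0, ``EMCI`` -> 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such feature table: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    # detect duplicate headers from the raw first line (pandas mangles them)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in first else ","
    names = [c.strip() for c in first.split(sep)]
    seen: set[str] = set()
    for c in names:
        if c in seen:
            raise DuplicateFeatureNameError(f"duplicated column {c!r} in {path}")
        seen.add(c)
    df.columns = names

    if label_column not in df.columns:
        raise KeyError(f"label column {label_column!r} not found in {path}")
    id_col = None
    for cand in ("subject", "subject_id", "id"):
        if cand in df.columns:
            id_col = cand
            break
    subject_ids = (
        df[id_col].tolist() if id_col is not None else [str(i) for i in range(len(df))]
    )
    raw_labels = df[label_column].tolist()
    distinct = sorted(set(raw_labels))
    if len(distinct) != 2:
        raise SingleClassLabelError(
            f"label column {label_column!r} must have exactly 2 distinct values, got {distinct}"
        )
    labels = CohortLabels(np.array([distinct.index(v) for v in raw_labels]))

    feat_cols = [c for c in df.columns if c != label_column and c != id_col]
    values = np.empty((len(df), len(feat_cols)), dtype=float)
    for j, c in enumerate(feat_cols):
        col = df[c].to_numpy()
        if np.any(col == ""):
            raise MissingValueError(f"missing value(s) in column {c!r}")
        try:
            values[:, j] = col.astype(float)
        except ValueError as exc:
            raise NonNumericValueError(f"non-numeric value in column {c!r}: {exc}") from exc
    if np.any(~np.isfinite(values)):
        raise MissingValueError("non-finite value(s) in feature table")
    return FeatureTable(tuple(subject_ids), tuple(feat_cols), values), labels


def write_feature_table(
    table: FeatureTable,
    labels: CohortLabels,
    path: str | Path,
    label_column: str = "group",
    label_names: tuple[str, str] = ("CN", "EMCI"),
) -> None:
    """Write a table + labels as CSV (column order: subject, label, features)."""
    df = pd.DataFrame(table.values, columns=list(table.feature_names))
    df.insert(0, label_column, [label_names[v] for v in labels.labels])
    df.insert(0, "subject", list(table.subject_ids))
    df.to_csv(path, index=False, float_format="%.10g")


def generate_synthetic_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a reproducible two-group cohort of correlated log-normal features.

    Latent scale: ``z = sqrt(rho) * g + sqrt(1 - rho) * eps`` with a shared
    factor ``g`` per subject (equicorrelation ``rho``), unit marginal variance.
    Informative features of case subjects are shifted by the standardized
    effect on the latent scale; observed values are
    ``exp(base_j + skew * z)`` — positive and right-skewed.

    Returns the table, labels, and a metadata dict recording the informative
    feature indices so recovery experiments can score selections.
    """
    rng = np.random.default_rng(config.seed)
    n0, n1 = config.n_per_group
    n = n0 + n1
    p = config.p
    rho = config.correlation

    shared = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, p))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps

    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    informative = np.sort(rng.choice(p, size=config.k_informative, replace=False))
    effects = config.effects()
    # cases show lower latent values (atrophy-like shift)
    if config.k_informative > 0:
        z[np.ix_(labels == 1, informative)] -= effects[np.newaxis, :]

    base = rng.uniform(1.0, 8.0, size=p)  # heterogeneous per-feature log-scales
    values = np.exp(base[np.newaxis, :] + config.skew * z)

    subject_ids = tuple(
        [f"CN_{i + 1:03d}" for i in range(n0)] + [f"CASE_{i + 1:03d}" for i in range(n1)]
    )
    feature_names = tuple(f"feat_{j + 1:04d}" for j in range(p))
    table = FeatureTable(subject_ids, feature_names, values)
    meta = {
        "seed": config.seed,
        "informative_indices": informative.tolist(),
        "informative_names": [feature_names[j] for j in informative],
        "effect_sizes": effects.tolist(),
        "config": {
            "n_per_group": list(config.n_per_group),
            "p": p,
            "k_informative": config.k_informative,
            "correlation": rho,
            "skew": config.skew,
        },
    }
    return SynthCohort(table, CohortLabels(labels), meta)


def write_cohort_metadata(meta: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def standardize(table: FeatureTable, train_index: Sequence[int]) -> FeatureTable:
    """Z-score every feature using mean/SD of the training subjects only.

    The transform is fit on ``train_index`` rows and applied to all rows —
    validation subjects never influence the parameters.  A zero-variance
    training feature is mapped to all zeros and a
    :class:`ConstantFeatureWarning` is emitted.
    """
    idx = np.asarray(train_index, dtype=int)
    if idx.size == 0:
        raise InvalidSplitError("train_index must be non-empty")
    train = table.values[idx]
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    constant = sd == 0.0
    if np.any(constant):
        names = [table.feature_names[j] for j in np.flatnonzero(constant)]
        warnings.warn(
            f"zero-variance training feature(s) mapped to zeros: {names}",
            ConstantFeatureWarning,
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    z = (table.values - mean) / safe_sd
    z[:, constant] = 0.0
    return FeatureTable(table.subject_ids, table.feature_names, z)


def stratified_split(labels: CohortLabels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation subject index sets.

    Stratified (per-class proportions within one subject of the global
    fraction) unless ``spec.stratified`` is off.  Seeded-reproducible.
    """
    y = labels.labels
    n0, n1 = labels.group_counts
    if min(n0, n1) < 2:
        raise InvalidSplitError("each class needs at least 2 members to split")
    indices = np.arange(len(y))
    try:
        train_idx, val_idx = train_test_split(
            indices,
            train_size=spec.train_fraction,
            stratify=y if spec.stratified else None,
            random_state=spec.seed,
            shuffle=True,
        )
    except ValueError as exc:
        raise InvalidSplitError(f"infeasible split: {exc}") from exc
    train_idx = np.sort(train_idx)
    val_idx = np.sort(val_idx)
    if len(set(y[train_idx])) < 2 or len(set(y[val_idx])) < 2:
        raise InvalidSplitError("split left a side with a single class; adjust fraction")
    return train_idx, val_idx
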