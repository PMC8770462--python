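"""Shared fixtures: tiny CSV tables, separable toy cohorts, fast eval configs."""

import numpy as np
import pytest

from evoselect import (
    CohortLabels,
    EvalConfig,
    FeatureTable,
    SplitSpec,
    TrainConfig,
)


@pytest.fixture
def tiny_csv(tmp_path):
    """4 subjects x 3 features, labels CN/CN/EMCI/EMCI."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "subject,group,vol_a,vol_b,vol_c\n"
        "s1,CN,1.0,2.0,3.0\n"
        "s2,CN,1.5,2.5,3.5\n"
        "s3,EMCI,0.9,1.8,2.7\n"
        "s4,EMCI,1.1,2.2,3.3\n"
    )
    return path


@pytest.fixture
def dup_column_csv(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text(
        "subject,group,CA1,CA1\ns1,CN,1.0,2.0\ns2,CN,1.1,2.1\ns3,EMCI,0.9,1.9\n"
    )
    return path


def make_separable_cohort(p=8, n_per_group=20, sep_feature=0, seed=0):
    """Toy cohort where one feature alone separates the groups perfectly."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    values = np.exp(rng.standard_normal((n, p)))
    values[:n_per_group, sep_feature] = rng.uniform(1.0, 2.0, n_per_group)
    values[n_per_group:, sep_feature] = rng.uniform(3.0, 4.0, n_per_group)
    table = FeatureTable(
        [f"s{i}" for i in range(n)], [f"f{j}" for j in range(p)], values
    )
    labels = CohortLabels(
        np.concatenate([np.zeros(n_per_group, int), np.ones(n_per_group, int)])
    )
    return table, labels


@pytest.fixture
def separable_cohort():
    return make_separable_cohort()


@pytest.fixture
def fast_eval_cfg():
    """Cheap deterministic evaluation config for selector tests."""
    return EvalConfig(
        split=SplitSpec(seed=0),
        train=TrainConfig(max_iterations=25),
        n_restarts=1,
    )
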