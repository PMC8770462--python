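"""Feature-table IO, synthetic cohorts, standardization, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoselect import (
    CohortLabels,
    FeatureTable,
    SplitSpec,
    SynthConfig,
    generate_synthetic_cohort,
    read_feature_table,
    standardize,
    stratified_split,
    write_feature_table,
)
from evoselect.errors import (
    ConstantFeatureWarning,
    DuplicateFeatureNameError,
    InvalidCorrelationError,
    InvalidSplitError,
    MissingValueError,
    NonNumericValueError,
    SingleClassLabelError,
)
from evoselect.stats import ranksum_test


class TestReadFeatureTable:
    def test_tiny_fixture(self, tiny_csv):
        table, labels = read_feature_table(tiny_csv, "group")
        assert table.feature_names == ("vol_a", "vol_b", "vol_c")
        assert table.subject_ids == ("s1", "s2", "s3", "s4")
        np.testing.assert_array_equal(labels.labels, [0, 0, 1, 1])
        assert table.values[0, 2] == 3.0

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_feature_table(tmp_path / "nope.csv", "group")

    def test_duplicate_column(self, dup_column_csv):
        with pytest.raises(DuplicateFeatureNameError):
            read_feature_table(dup_column_csv, "group")

    def test_non_numeric_cell(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject,group,a\ns1,CN,1.0\ns2,CN,oops\ns3,EMCI,2.0\n")
        with pytest.raises(NonNumericValueError):
            read_feature_table(path, "group")

    def test_missing_value(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("subject,group,a\ns1,CN,1.0\ns2,CN,\ns3,EMCI,2.0\n")
        with pytest.raises(MissingValueError):
            read_feature_table(path, "group")

    def test_single_class(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text("subject,group,a\ns1,CN,1.0\ns2,CN,2.0\n")
        with pytest.raises(SingleClassLabelError):
            read_feature_table(path, "group")

    def test_tsv(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("subject\tgroup\ta\ns1\tCN\t1.5\ns2\tEMCI\t2.5\n")
        table, labels = read_feature_table(path, "group")
        assert table.values[1, 0] == 2.5
        np.testing.assert_array_equal(labels.labels, [0, 1])

    def test_round_trip(self, tmp_path):
        table, labels, _ = generate_synthetic_cohort(SynthConfig(p=6, k_informative=2, seed=5))
        path = tmp_path / "rt.csv"
        write_feature_table(table, labels, path)
        table2, labels2 = read_feature_table(path, "group")
        assert table2.feature_names == table.feature_names
        np.testing.assert_allclose(table2.values, table.values, rtol=1e-9)
        np.testing.assert_array_equal(labels2.labels, labels.labels)


class TestFeatureTableInvariants:
    def test_duplicate_names_rejected(self):
        with pytest.raises(DuplicateFeatureNameError):
            FeatureTable(["s1"], ["a", "a"], [[1.0, 2.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FeatureTable(["s1", "s2"], ["a"], [[1.0]])

    def test_nan_rejected(self):
        with pytest.raises(MissingValueError):
            FeatureTable(["s1"], ["a"], [[np.nan]])

    def test_labels_need_both_classes(self):
        with pytest.raises(SingleClassLabelError):
            CohortLabels(np.zeros(4, dtype=int))


class TestSyntheticCohort:
    def test_seeded_determinism(self):
        a = generate_synthetic_cohort(SynthConfig(seed=11))
        b = generate_synthetic_cohort(SynthConfig(seed=11))
        np.testing.assert_array_equal(a.table.values, b.table.values)
        np.testing.assert_array_equal(a.labels.labels, b.labels.labels)
        assert a.metadata == b.metadata

    def test_shapes_and_positivity(self):
        table, labels, meta = generate_synthetic_cohort(SynthConfig(seed=2))
        assert table.values.shape == (110, 142)
        assert labels.group_counts == (56, 54)
        assert np.all(table.values > 0)
        assert len(meta["informative_indices"]) == 8

    def test_right_skew(self):
        from scipy.stats import skew

        table, _, _ = generate_synthetic_cohort(
            SynthConfig(n_per_group=(400, 400), p=30, k_informative=0, seed=3)
        )
        sk = skew(table.values, axis=0)
        assert np.mean(sk > 0) > 0.9  # log-normal marginals are right-skewed

    def test_invalid_correlation(self):
        with pytest.raises(InvalidCorrelationError):
            SynthConfig(correlation=1.0)

    def test_k_exceeds_p(self):
        with pytest.raises(ValueError):
            SynthConfig(p=5, k_informative=6)

    def test_latent_correlation_converges(self):
        cfg = SynthConfig(
            n_per_group=(2500, 2500), p=12, k_informative=0, correlation=0.3, seed=7
        )
        table, _, _ = generate_synthetic_cohort(cfg)
        logs = np.log(table.values)
        corr = np.corrcoef(logs.T)
        off = corr[np.triu_indices(12, k=1)]
        assert abs(off.mean() - 0.3) < 0.05

    def test_informative_power(self):
        # effect 1.2 at n = 56/54: each informative feature detectable at
        # p < 0.05 in >= 90% of replicates
        hits = 0
        total = 0
        for rep in range(30):
            cfg = SynthConfig(p=10, k_informative=3, effect_sizes=1.2, seed=100 + rep)
            table, labels, meta = generate_synthetic_cohort(cfg)
            y = labels.labels
            for j in meta["informative_indices"]:
                col = table.values[:, j]
                res = ranksum_test(col[y == 0], col[y == 1])
                hits += res.p_value < 0.05
                total += 1
        assert hits / total >= 0.90


class TestStandardize:
    def test_hand_computed(self):
        # 3 subjects x 2 features, train on all rows
        table = FeatureTable(["a", "b", "c"], ["f1", "f2"], [[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        z = standardize(table, [0, 1, 2])
        # mean 2, population sd sqrt(2/3) for f1
        sd1 = np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(z.values[:, 0], (np.array([1, 2, 3]) - 2) / sd1)
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(
            [f"s{i}" for i in range(10)], ["a", "b"], rng.standard_normal((10, 2))
        )
        once = standardize(table, np.arange(10))
        twice = standardize(once, np.arange(10))
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_feature_warns_and_zeroes(self):
        table = FeatureTable(["a", "b"], ["c1", "c2"], [[5.0, 1.0], [5.0, 2.0]])
        with pytest.warns(ConstantFeatureWarning):
            z = standardize(table, [0, 1])
        np.testing.assert_array_equal(z.values[:, 0], [0.0, 0.0])

    def test_no_leakage_from_validation_rows(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((12, 3))
        table = FeatureTable([f"s{i}" for i in range(12)], ["a", "b", "c"], vals)
        train = np.arange(8)
        z1 = standardize(table, train)
        vals2 = vals.copy()
        vals2[8:] = rng.standard_normal((4, 3)) * 100  # permute/replace validation rows
        table2 = FeatureTable(table.subject_ids, table.feature_names, vals2)
        z2 = standardize(table2, train)
        np.testing.assert_allclose(z1.values[train], z2.values[train], atol=1e-12)


class TestStratifiedSplit:
    def test_80_20_counts(self):
        labels = CohortLabels(np.concatenate([np.zeros(56, int), np.ones(54, int)]))
        train, val = stratified_split(labels, SplitSpec(train_fraction=0.8, seed=0))
        assert len(train) == 88 and len(val) == 22
        # per-class proportions within one subject of the global fraction
        y = labels.labels
        for cls, n_cls in ((0, 56), (1, 54)):
            n_train_cls = int(np.sum(y[train] == cls))
            assert abs(n_train_cls - 0.8 * n_cls) <= 1

    def test_fraction_one_rejected(self):
        with pytest.raises(InvalidSplitError):
            SplitSpec(train_fraction=1.0)

    def test_seeded_determinism(self):
        labels = CohortLabels(np.concatenate([np.zeros(10, int), np.ones(10, int)]))
        a = stratified_split(labels, SplitSpec(seed=3))
        b = stratified_split(labels, SplitSpec(seed=3))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_small_class_rejected(self):
        labels = np.array([0, 0, 0, 1])
        with pytest.raises(InvalidSplitError):
            stratified_split(CohortLabels(labels), SplitSpec())

    @settings(max_examples=30, deadline=None)
    @given(
        n0=st.integers(4, 40),
        n1=st.integers(4, 40),
        seed=st.integers(0, 2**16),
        frac=st.floats(0.5, 0.9),
    )
    def test_partition_property(self, n0, n1, seed, frac):
        from hypothesis import assume

        # each side must be able to hold both classes
        assume((n0 + n1) * (1 - frac) >= 3 and (n0 + n1) * frac >= 3)
        labels = CohortLabels(np.concatenate([np.zeros(n0, int), np.ones(n1, int)]))
        train, val = stratified_split(labels, SplitSpec(train_fraction=frac, seed=seed))
        union = np.sort(np.concatenate([train, val]))
        np.testing.assert_array_equal(union, np.arange(n0 + n1))
        assert len(np.intersect1d(train, val)) == 0
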