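"""Benchmark curation: filters, target transform, split, normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from cppuptake.curation import (
    SplitSpec,
    apply_benchmark_filters,
    rank_feature_correlations,
    remove_null_variance,
    remove_outliers,
    split_and_normalize,
    standardize_units,
    transform_target,
)
from cppuptake.schema_io import FeatureMatrix, FeatureSchema
from cppuptake.synthetic_data import GeneratorSpec, generate_dataset

from conftest import make_record


class TestUnits:
    def test_synonyms_collapse_to_canonical(self):
        records = [
            make_record("a", uptake_unit="MFI"),
            make_record("b", uptake_unit="mean fluorescence intensity"),
            make_record("c", uptake_unit="Mean Fluorescence Intensity"),
        ]
        out, info = standardize_units(records)
        assert {r.uptake_unit for r in out} == {"MFI"}
        assert info["units_unknown"] == {}

    def test_idempotent_on_canonical_labels(self):
        once, _ = standardize_units([make_record(uptake_unit="a.u.")])
        twice, _ = standardize_units(once)
        assert twice[0].uptake_unit == once[0].uptake_unit == "arbitrary-units"

    def test_unknown_units_bucketed_not_dropped(self):
        out, info = standardize_units([make_record(uptake_unit="AU-ish")])
        assert len(out) == 1
        assert info["units_unknown"] == {"AU-ish": 1}


def dirty_fixture():
    """10 rows: 2 missing conc, 3 non-fluorescence, 1 relative unit,
    1 unusable conc, 1 anomaly-heavy; 2 fully clean."""
    return [
        make_record("clean1"),
        make_record("clean2", sequence="KLWKKLLKW"),
        make_record("noconc1", concentration_uM=None),
        make_record("noconc2", concentration_uM=None),
        make_record("mass1", method="mass spectrometry"),
        make_record("mass2", method="radiolabeling"),
        make_record("mass3", method="western blot"),
        make_record("rel1", uptake_unit="% of control"),
        make_record("badconc", concentration_uM=0.0),
        make_record("anom", sequence="grkkrrqrr"),  # all-D, fraction 1.0
    ]


class TestBenchmarkFilters:
    def test_hand_traced_counts(self):
        survivors, report = apply_benchmark_filters(dirty_fixture())
        assert report.counts_after[:5] == [8, 5, 4, 3, 2]
        # step 6 is a guarded no-op below 4 values
        assert report.counts_after[5] == 2
        assert {r.record_id for r in survivors} == {"clean1", "clean2"}

    def test_step_attribution(self):
        _, report = apply_benchmark_filters(dirty_fixture())
        removed = dict(zip(report.step_names, report.removed_ids))
        assert set(removed["missing_concentration_or_unclear_sequence"]) == {
            "noconc1", "noconc2",
        }
        assert set(removed["non_fluorescence_method"]) == {
            "mass1", "mass2", "mass3",
        }
        assert removed["relative_uptake_units"] == ["rel1"]
        assert removed["unusable_concentration"] == ["badconc"]
        assert removed["anomalous_sequence"] == ["anom"]

    def test_all_clean_input_is_untouched(self):
        records = [make_record(f"r{i}") for i in range(6)]
        survivors, report = apply_benchmark_filters(records)
        assert len(survivors) == 6
        assert report.counts_after == [6] * 6

    def test_empty_input(self):
        survivors, report = apply_benchmark_filters([])
        assert survivors == [] and report.counts_after == [0] * 6

    def test_conservation_on_random_synthetic_datasets(self):
        for seed in range(100):
            ds = generate_dataset(GeneratorSpec(n_records=25, seed=seed))
            survivors, report = apply_benchmark_filters(ds.records)
            report.validate()
            removed = sum(len(ids) for ids in report.removed_ids)
            assert removed + len(survivors) == len(ds.records)
            counts = [report.n_input] + report.counts_after
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestTargetTransform:
    @pytest.mark.parametrize("value,expected", [(1000.0, 3.0), (1.0, 0.0)])
    def test_exact_powers(self, value, expected):
        assert transform_target(value) == expected

    def test_non_positive_excluded(self):
        with pytest.raises(ValueError, match="positive"):
            transform_target(0.0)


class TestOutliers:
    def test_distant_point_removed(self):
        targets = [i / 10 for i in range(11)] + [100.0]
        kept, bounds = remove_outliers(targets)
        assert kept == list(range(11))
        assert bounds[1] < 100

    def test_identical_values_keep_everything(self):
        kept, _ = remove_outliers([2.0] * 8)
        assert kept == list(range(8))

    def test_small_n_is_warned_noop(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept, bounds = remove_outliers([1.0, 2.0, 3.0])
        assert kept == [0, 1, 2] and bounds is None


def tiny_matrix(values, target=None, names=None):
    names = names or [f"f{i}" for i in range(np.asarray(values).shape[1])]
    schema = FeatureSchema(blocks=[("blk", names)])
    return FeatureMatrix(
        row_ids=[f"r{i}" for i in range(len(values))],
        schema=schema,
        values=np.asarray(values, dtype=float),
        target=target,
    )


class TestNullVariance:
    def test_constant_column_removed_single_differing_kept(self):
        fm = tiny_matrix([[1.0, 5.0], [1.0, 5.0], [1.0, 6.0]])
        pruned, removed = remove_null_variance(fm)
        assert removed == ["blk__f0"]
        assert list(pruned.columns) == ["blk__f1"]

    def test_idempotent(self):
        fm = tiny_matrix([[1.0, 5.0], [1.0, 4.0]])
        pruned, removed = remove_null_variance(fm)
        again = pruned.loc[:, (pruned != pruned.iloc[0]).any()]
        pd.testing.assert_frame_equal(pruned, again)


@pytest.fixture(scope="module")
def matrix_1263():
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.normal(size=(1263, 8)), columns=[f"f{i}" for i in range(8)]
    )
    df["target"] = rng.normal(size=1263)
    return df


class TestSplitAndNormalize:

    def test_floor_convention_884_379(self, matrix_1263):
        train, test, _ = split_and_normalize(matrix_1263, SplitSpec(seed=17))
        assert len(train) == 884 and len(test) == 379
        assert set(train.index).isdisjoint(test.index)
        assert len(train) + len(test) == 1263

    def test_train_columns_are_standardized(self, matrix_1263):
        train, _, stats = split_and_normalize(matrix_1263, SplitSpec(seed=17))
        X = train[[c for c in train.columns if c != "target"]].to_numpy()
        assert np.abs(X.mean(axis=0)).max() < 1e-9
        assert np.abs(X.std(axis=0) - 1).max() < 1e-9

    def test_same_seed_same_partition(self, matrix_1263):
        t1, s1, _ = split_and_normalize(matrix_1263, SplitSpec(seed=3))
        t2, s2, _ = split_and_normalize(matrix_1263, SplitSpec(seed=3))
        assert list(t1.index) == list(t2.index)
        assert list(s1.index) == list(s2.index)

    def test_inverse_transform_recovers_train_values(self, matrix_1263):
        train, _, stats = split_and_normalize(matrix_1263, SplitSpec(seed=17))
        feats = [c for c in train.columns if c != "target"]
        back = stats.invert(train[feats].to_numpy())
        orig = matrix_1263.loc[train.index, feats].to_numpy()
        np.testing.assert_allclose(back, orig, atol=1e-9)

    def test_zero_variance_columns_pass_through(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"a": rng.normal(size=20), "b": np.ones(20)}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            train, test, stats = split_and_normalize(df, SplitSpec(seed=1))
        assert (train["b"] == 0.0).all()  # centered but not scaled
        assert stats.sd[list(stats.columns).index("b")] == 1.0

    def test_too_few_rows_error(self):
        df = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ValueError, match="at least 10"):
            split_and_normalize(df, SplitSpec(seed=0))


class TestCorrelationRanking:
    def test_target_copy_ranks_first(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        vals = np.column_stack([rng.normal(size=200), y, rng.normal(size=200)])
        fm = tiny_matrix(vals, target=y)
        ranked = rank_feature_correlations(fm)
        assert ranked.iloc[0]["feature"] == "f1"
        assert ranked.iloc[0]["pearson_r"] == pytest.approx(1.0)
        assert len(ranked) == 3

    def test_noise_column_correlation_is_small(self):
        rng = np.random.default_rng(2)
        n = 4000
        y = rng.normal(size=n)
        fm = tiny_matrix(rng.normal(size=(n, 2)), target=y)
        ranked = rank_feature_correlations(fm)
        assert ranked["pearson_r"].abs().max() < 3 / math.sqrt(n)

    def test_zero_variance_column_flagged_with_r_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fm = tiny_matrix(
            np.column_stack([np.ones(4), y]), target=y
        )
        ranked = rank_feature_correlations(fm)
        flagged = ranked[ranked["zero_variance"]]
        assert len(flagged) == 1 and flagged.iloc[0]["pearson_r"] == 0.0

    def test_requires_target(self):
        fm = tiny_matrix([[1.0], [2.0]])
        with pytest.raises(ValueError, match="target"):
            rank_feature_correlations(fm)
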