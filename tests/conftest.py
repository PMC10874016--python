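"""Shared fixtures: synthetic datasets, featurized benchmarks, toy records."""

from __future__ import annotations

import numpy as np
import pytest

from cppuptake.curation import (
    SplitSpec,
    apply_benchmark_filters,
    remove_null_variance,
    split_and_normalize,
    transform_target,
)
from cppuptake.pipeline import CPPFeaturizer
from cppuptake.schema_io import PeptideRecord
from cppuptake.synthetic_data import GeneratorSpec, generate_dataset


def make_record(record_id="r1", sequence="GRKKRRQRRR", **kw) -> PeptideRecord:
    """A valid baseline record; keyword overrides for per-test variation."""
    base = dict(
        record_id=record_id,
        sequence=sequence,
        cargoes=["FITC"],
        cell_line="HeLa",
        tissue="cervix",
        concentration_uM=10.0,
        temperature_label="37",
        incubation_available=True,
        incubation_min=60.0,
        uptake_value=1500.0,
        uptake_unit="MFI",
        method="flow cytometry",
    )
    base.update(kw)
    return PeptideRecord(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """400-record synthetic dataset with default dirty rates."""
    return generate_dataset(GeneratorSpec(n_records=400, seed=101))


@pytest.fixture(scope="session")
def small_benchmark(small_dataset):
    """Curated + featurized + split version of the small dataset."""
    ds = small_dataset
    survivors, report = apply_benchmark_filters(ds.records)
    fz = CPPFeaturizer(genomics_table=ds.genomics_table).fit(survivors)
    fm = fz.transform(survivors)
    fm.target = np.array(
        [transform_target(r.uptake_value) for r in survivors]
    )
    pruned, removed = remove_null_variance(fm)
    train_df, test_df, stats = split_and_normalize(pruned, SplitSpec(seed=5))
    feats = [c for c in train_df.columns if c != "target"]
    return {
        "dataset": ds,
        "survivors": survivors,
        "report": report,
        "featurizer": fz,
        "fm": fm,
        "pruned": pruned,
        "removed": removed,
        "train": train_df,
        "test": test_df,
        "stats": stats,
        "feature_cols": feats,
    }
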