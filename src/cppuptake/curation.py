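"""Benchmark construction: unit harmonization, filtering, split, scaling.

The benchmark procedure applies six ordered filters with per-step
accounting, a log10 transform of the uptake target, Tukey-fence outlier
removal, null-variance column pruning, a seeded 70–30 split, and
z-scoring with train-fitted statistics. Every step reports which rows it
removed; counts are non-increasing and removed + kept always equals the
input (conservation).

Filter semantics (rule-based statements of the published procedure):
  1. drop rows lacking a concentration value or with an unclear sequence;
  2. keep fluorescence-determined measurements only;
  3. drop relative uptake units (percent/fold-type readouts);
  4. drop unusable concentrations (non-positive or non-finite);
  5. drop sequences whose anomalous-token fraction exceeds a threshold
     (default 50%) or that contain unmappable payloads;
  6. drop uptake outliers (Tukey fences at 1.5 x IQR on log10 uptake).
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .encoders import (
    STANDARD_AA,
    AnomalySubstitutionMap,
    load_default_anomaly_map,
    tokenize_sequence,
)
from .schema_io import FeatureMatrix, PeptideRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CurationReport",
    "SplitSpec",
    "NormalizationStats",
    "load_default_unit_map",
    "standardize_units",
    "apply_benchmark_filters",
    "transform_target",
    "remove_outliers",
    "remove_null_variance",
    "split_and_normalize",
    "rank_feature_correlations",
    "FLUORESCENCE_METHODS",
]

#: Canonical method labels treated as fluorescence-based readouts.
FLUORESCENCE_METHODS = (
    "flow cytometry",
    "fluorescence microscopy",
    "fluorescence spectroscopy",
    "facs",
    "confocal microscopy",
)

STEP_NAMES = (
    "missing_concentration_or_unclear_sequence",
    "non_fluorescence_method",
    "relative_uptake_units",
    "unusable_concentration",
    "anomalous_sequence",
    "uptake_outliers",
)


@dataclass
class CurationReport:
    """Ordered per-step accounting of the benchmark filters."""

    n_input: int
    step_names: list[str] = field(default_factory=list)
    counts_after: list[int] = field(default_factory=list)
    removed_ids: list[list[str]] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def add_step(self, name: str, removed: list[str], n_after: int) -> None:
        self.step_names.append(name)
        self.removed_ids.append(removed)
        self.counts_after.append(n_after)

    def validate(self) -> None:
        counts = [self.n_input] + self.counts_after
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError("curation counts must be non-increasing")
        all_removed = [i for step in self.removed_ids for i in step]
        if len(all_removed) != len(set(all_removed)):
            raise AssertionError("a row was removed by two different steps")
        if self.counts_after and (
            self.counts_after[-1] + len(all_removed) != self.n_input
        ):
            raise AssertionError("removed + kept != input rows")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step_names,
                "rows_after": self.counts_after,
                "rows_removed": [len(r) for r in self.removed_ids],
            }
        )


@dataclass
class SplitSpec:
    """Seeded train/test partition with train-fitted normalization."""

    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class NormalizationStats:
    """Per-feature train mean/sd (sd of zero-variance columns kept at 1)."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray  # boolean mask of passthrough columns

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd

    def invert(self, values: np.ndarray) -> np.ndarray:
        return values * self.sd + self.mean


def load_default_unit_map() -> dict:
    """raw spelling -> (canonical label, is_relative)."""
    with resources.files("cppuptake.data").joinpath(
        "unit_synonyms.csv"
    ).open() as fh:
        rows = list(csv.DictReader(fh))
    return {
        r["raw"].lower(): (r["canonical"], r["relative"] == "1") for r in rows
    }


def standardize_units(
    records: Sequence[PeptideRecord],
    unit_map: Optional[dict] = None,
) -> tuple[list[PeptideRecord], dict]:
    """Collapse synonymous unit spellings onto canonical labels.

    Values are untouched. Unmapped spellings are kept verbatim and
    reported in the ``units_unknown`` bucket of the returned summary.
    """
    unit_map = unit_map if unit_map is not None else load_default_unit_map()
    out: list[PeptideRecord] = []
    unknown: dict[str, int] = {}
    for r in records:
        key = r.uptake_unit.strip().lower()
        if key in unit_map:
            canonical, _ = unit_map[key]
            if canonical != r.uptake_unit:
                r = PeptideRecord(**{**r.__dict__, "uptake_unit": canonical})
        else:
            unknown[r.uptake_unit] = unknown.get(r.uptake_unit, 0) + 1
        out.append(r)
    return out, {"units_unknown": unknown}


def _is_relative_unit(unit: str, unit_map: dict) -> bool:
    key = unit.strip().lower()
    if key in unit_map:
        return unit_map[key][1]
    # canonical labels appear as map values too
    for canonical, rel in unit_map.values():
        if key == canonical.lower():
            return rel
    return False


def _sequence_unclear(seq: str) -> bool:
    s = seq.strip()
    return not s or not any(c.isalpha() for c in s)


def _anomaly_fraction(
    seq: str, amap: AnomalySubstitutionMap
) -> Optional[float]:
    """Fraction of anomalous tokens; None if any token is unmappable."""
    toks = tokenize_sequence(seq.strip())
    if not toks:
        return None
    n_anom = 0
    for t in toks:
        if t in STANDARD_AA:
            continue
        if t not in amap.entries:
            return None
        n_anom += 1
    return n_anom / len(toks)


def apply_benchmark_filters(
    records: Sequence[PeptideRecord],
    unit_map: Optional[dict] = None,
    anomaly_map: Optional[AnomalySubstitutionMap] = None,
    fluorescence_methods: Sequence[str] = FLUORESCENCE_METHODS,
    max_anomaly_fraction: float = 0.5,
    outlier_multiplier: float = 1.5,
) -> tuple[list[PeptideRecord], CurationReport]:
    """Apply the six ordered benchmark filters with per-step accounting."""
    unit_map = unit_map if unit_map is not None else load_default_unit_map()
    amap = anomaly_map or load_default_anomaly_map()
    fluoro = {m.lower() for m in fluorescence_methods}
    report = CurationReport(n_input=len(records))
    current = list(records)

    def run_step(name: str, keep_fn) -> None:
        nonlocal current
        kept, removed = [], []
        for r in current:
            (kept if keep_fn(r) else removed).append(r)
        report.add_step(name, [r.record_id for r in removed], len(kept))
        current = kept

    run_step(
        STEP_NAMES[0],
        lambda r: r.concentration_uM is not None
        and not _sequence_unclear(r.sequence),
    )
    run_step(
        STEP_NAMES[1],
        lambda r: r.method.strip().lower() in fluoro
        or "fluor" in r.method.lower(),
    )
    run_step(
        STEP_NAMES[2], lambda r: not _is_relative_unit(r.uptake_unit, unit_map)
    )
    run_step(
        STEP_NAMES[3],
        lambda r: r.concentration_uM is not None
        and math.isfinite(r.concentration_uM)
        and r.concentration_uM > 0,
    )
    run_step(
        STEP_NAMES[4],
        lambda r: (
            (f := _anomaly_fraction(r.sequence, amap)) is not None
            and f <= max_anomaly_fraction
        ),
    )

    # step 6: outliers on the log10 uptake of the survivors
    positive = [r for r in current if r.uptake_value > 0]
    nonpos = [r for r in current if not (r.uptake_value > 0)]
    logt = np.log10([r.uptake_value for r in positive])
    kept_idx, bounds = remove_outliers(logt, multiplier=outlier_multiplier)
    kept_set = set(kept_idx)
    survivors = [r for i, r in enumerate(positive) if i in kept_set]
    removed6 = [
        r.record_id for i, r in enumerate(positive) if i not in kept_set
    ] + [r.record_id for r in nonpos]
    report.add_step(STEP_NAMES[5], removed6, len(survivors))
    report.details["outlier_bounds"] = bounds
    report.validate()
    return survivors, report


def transform_target(uptake_value: float) -> float:
    """log10 transform of a positive uptake value."""
    if not (uptake_value > 0) or not math.isfinite(uptake_value):
        raise ValueError(
            f"uptake value {uptake_value!r} cannot be log-transformed "
            "(must be a finite positive number)"
        )
    return math.log10(uptake_value)


def remove_outliers(
    targets: Sequence[float], multiplier: float = 1.5
) -> tuple[list[int], Optional[tuple[float, float]]]:
    """Tukey-fence outlier removal; returns kept indices and the fences.

    With fewer than 4 values the quartiles are unstable and the step is a
    warned no-op. Identical values give zero IQR and remove nothing
    (fences are inclusive).
    """
    t = np.asarray(targets, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("targets must be finite")
    if t.size < 4:
        if t.size:
            warnings.warn(
                "fewer than 4 values: outlier removal skipped", stacklevel=2
            )
        return list(range(t.size)), None
    q1, q3 = np.percentile(t, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    kept = [i for i, v in enumerate(t) if lo <= v <= hi]
    return kept, (float(lo), float(hi))


def remove_null_variance(
    fm: FeatureMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns constant over all rows; keep the mapping for reuse.

    Returns the pruned matrix as a DataFrame (block-prefixed column
    names) plus the removed column list, so prediction-time vectors can
    be pruned identically.
    """
    df = fm.to_frame().set_index("row_id")
    target = df.pop("target") if "target" in df.columns else None
    if len(df):
        constant = (df == df.iloc[0]).all(axis=0)
        removed = list(df.columns[constant])
    else:
        removed = []
    pruned = df.drop(columns=removed).copy()
    if target is not None:
        pruned["target"] = target
    return pruned, removed


def split_and_normalize(
    matrix: pd.DataFrame,
    spec: SplitSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, NormalizationStats]:
    """Seeded 70–30 split then z-scoring with train-fitted statistics.

    Train size is ``floor(train_fraction * n)``. Zero-variance columns
    pass through unscaled (sd kept at 1) with a warning. The ``target``
    column, when present, is carried through unnormalized.
    """
    n = len(matrix)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    feature_cols = [c for c in matrix.columns if c != "target"]
    n_train = int(math.floor(spec.train_fraction * n))
    train_df, test_df = train_test_split(
        matrix, train_size=n_train, random_state=spec.seed, shuffle=True
    )
    scaler = StandardScaler()
    scaler.fit(train_df[feature_cols].to_numpy())
    zero_var = scaler.var_ == 0.0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance column(s) pass through "
            "unscaled",
            stacklevel=2,
        )
    stats = NormalizationStats(
        columns=feature_cols,
        mean=scaler.mean_.copy(),
        sd=scaler.scale_.copy(),  # sklearn keeps scale 1 for zero variance
        zero_variance=zero_var,
    )
    out = []
    for df in (train_df, test_df):
        z = pd.DataFrame(
            stats.apply(df[feature_cols].to_numpy()),
            columns=feature_cols,
            index=df.index,
        )
        if "target" in df.columns:
            z["target"] = df["target"]
        out.append(z)
    return out[0], out[1], stats


def rank_feature_correlations(fm: FeatureMatrix) -> pd.DataFrame:
    """Pearson correlation of every feature with the target, |r|-ranked.

    Zero-variance columns get r = 0 with a flag rather than NaN.
    """
    if fm.target is None:
        raise ValueError("feature matrix has no target")
    y = fm.target - fm.target.mean()
    X = fm.values - fm.values.mean(axis=0)
    sx = X.std(axis=0)
    sy = y.std()
    zero = (sx == 0) | (sy == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X.T @ y) / (len(y) * np.where(zero, 1.0, sx) * (sy or 1.0))
    r = np.where(zero, 0.0, r)
    blocks = [
        block for block, cols in fm.schema.blocks for _ in cols
    ]
    df = pd.DataFrame(
        {
            "feature": fm.schema.column_names(),
            "block": blocks,
            "pearson_r": r,
            "zero_variance": zero,
        }
    )
    return (
        df.reindex(df["pearson_r"].abs().sort_values(ascending=False).index)
        .reset_index(drop=True)
    )
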