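"""Feature assembly: records -> the full 2,908-column feature matrix.

Block order (frozen): whole-peptide descriptors (31), position one-hot
(2,000), anomaly indicators (70), genomics (735), genomics match flag (1),
concentration (1), temperature one-hot (5), incubation (2), cargo
multi-hot (63). With the default vocabularies this totals 2,908 columns.

`CPPFeaturizer` follows the sklearn transformer protocol so it composes
with pipelines and model selection; `assemble_features` is the thin
functional wrapper. For the forked network, `branch_block_indices` groups
the schema into the seven model-input branches (experimental, cargo,
anomaly types, whole-peptide, sequence encoding, genomics, anomalous
positions).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import descriptors as desc
from . import encoders as enc
from .genomics import DEFAULT_N_GENES, GenomicsTable, join_genomics
from .schema_io import (
    TEMPERATURE_CATEGORIES,
    FeatureMatrix,
    FeatureSchema,
    PeptideRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "build_schema",
    "placeholder_gene_names",
    "branch_block_indices",
    "branch_indices_for_columns",
    "CPPFeaturizer",
    "assemble_features",
    "FeaturizationError",
]

BRANCH_NAMES = (
    "experimental",
    "cargo",
    "anomaly_type",
    "whole_peptide",
    "sequence",
    "genomics",
    "anomaly_position",
)


class FeaturizationError(ValueError):
    """Featurization failure for one record, with its id attached."""

    def __init__(self, record_id: str, stage: str, message: str):
        super().__init__(f"record {record_id!r} [{stage}]: {message}")
        self.record_id = record_id
        self.stage = stage


def placeholder_gene_names(n_genes: int = DEFAULT_N_GENES) -> list[str]:
    """Synthetic stand-in gene list for schema-complete degraded mode."""
    return [f"G{i:04d}" for i in range(1, n_genes + 1)]


def build_schema(
    gene_names: Optional[Sequence[str]] = None,
    observed_types: Optional[Sequence[str]] = None,
    cargo_vocab: Optional[Sequence[str]] = None,
    max_len: int = enc.MAX_PEPTIDE_LEN,
) -> FeatureSchema:
    """Construct the full feature schema from the active vocabularies."""
    if observed_types is None:
        observed_types = enc.load_default_anomaly_map().observed_types
    if cargo_vocab is None:
        cargo_vocab = enc.load_default_cargo_vocab()
    if gene_names is None:
        gene_names = placeholder_gene_names()
    return FeatureSchema(
        blocks=[
            ("whole_peptide", list(desc.DESCRIPTOR_NAMES)),
            ("position_onehot", enc.position_column_names(max_len)),
            ("anomaly", enc.anomaly_column_names(observed_types)),
            ("genomics", list(gene_names)),
            ("genomics_match", ["genomics_match"]),
            ("concentration", ["concentration_uM"]),
            ("temperature", [f"temp_{c}" for c in TEMPERATURE_CATEGORIES]),
            ("incubation", ["incubation_available", "incubation_min"]),
            ("cargo", [f"cargo_{label}" for label in cargo_vocab]),
        ]
    )


def branch_block_indices(schema: FeatureSchema) -> dict[str, np.ndarray]:
    """Column indices for each of the seven forked-net input branches."""
    slices = schema.block_slices()
    names = schema.column_names()

    def cols(block: str, prefix: str | None = None) -> np.ndarray:
        if block not in slices:  # absent in reduced/toy schemas
            return np.array([], dtype=int)
        s = slices[block]
        idx = np.arange(s.start, s.stop)
        if prefix is not None:
            idx = idx[[names[i].startswith(prefix) for i in idx]]
        return idx

    return {
        "experimental": np.concatenate(
            [cols("concentration"), cols("temperature"), cols("incubation")]
        ).astype(int),
        "cargo": cols("cargo"),
        "anomaly_type": cols("anomaly", "anom_type_"),
        "whole_peptide": cols("whole_peptide"),
        "sequence": cols("position_onehot"),
        "genomics": np.concatenate(
            [cols("genomics"), cols("genomics_match")]
        ).astype(int),
        "anomaly_position": cols("anomaly", "anom_pos_"),
    }


def branch_indices_for_columns(
    schema: FeatureSchema, prefixed_columns: Sequence[str]
) -> dict[str, np.ndarray]:
    """Branch routing for a pruned matrix given its kept column names.

    ``prefixed_columns`` are block-prefixed names (``block__column``) in
    matrix order, e.g. the surviving columns after null-variance pruning;
    the returned indices are positions within that pruned ordering.
    """
    full = branch_block_indices(schema)
    prefixed_all = [
        f"{block}__{c}" for block, cols in schema.blocks for c in cols
    ]
    col_to_branch: dict[str, str] = {}
    for branch, idx in full.items():
        for i in idx:
            col_to_branch[prefixed_all[i]] = branch
    out: dict[str, list[int]] = {b: [] for b in full}
    for pos, col in enumerate(prefixed_columns):
        if col not in col_to_branch:
            raise ValueError(f"column {col!r} is not part of the schema")
        out[col_to_branch[col]].append(pos)
    return {b: np.asarray(ix, dtype=int) for b, ix in out.items()}


class CPPFeaturizer(TransformerMixin, BaseEstimator):
    """Transform peptide records into the assembled feature matrix.

    Parameters
    ----------
    genomics_table : GenomicsTable, optional
        Cell-line mutation table. When absent the genomics block is
        all-zero with match flag 0 (degraded mode, schema width kept).
    anomaly_map : AnomalySubstitutionMap, optional
        Token substitution vocabulary; defaults to the packaged one.
    cargo_vocab : sequence of str, optional
        Cargo label vocabulary; defaults to the packaged 63 labels.
    tissue_map : dict, optional
        tissue -> preferred proxy cell-line name for genomics fallback.
    max_len : int
        Maximum peptide length for the position one-hot block.

    Attributes
    ----------
    schema_ : FeatureSchema
        The fitted column layout (2,908 columns with defaults).
    n_features_out_ : int
        Total number of output columns.
    """

    def __init__(
        self,
        genomics_table: Optional[GenomicsTable] = None,
        anomaly_map=None,
        cargo_vocab: Optional[Sequence[str]] = None,
        tissue_map: Optional[dict] = None,
        max_len: int = enc.MAX_PEPTIDE_LEN,
    ):
        self.genomics_table = genomics_table
        self.anomaly_map = anomaly_map
        self.cargo_vocab = cargo_vocab
        self.tissue_map = tissue_map
        self.max_len = max_len

    def fit(self, X: Sequence[PeptideRecord], y=None) -> "CPPFeaturizer":
        amap = self.anomaly_map or enc.load_default_anomaly_map()
        vocab = (
            list(self.cargo_vocab)
            if self.cargo_vocab is not None
            else enc.load_default_cargo_vocab()
        )
        genes = (
            list(self.genomics_table.gene_order)
            if self.genomics_table is not None
            else placeholder_gene_names()
        )
        self._amap = amap
        self._vocab = vocab
        self.schema_ = build_schema(
            gene_names=genes,
            observed_types=amap.observed_types,
            cargo_vocab=vocab,
            max_len=self.max_len,
        )
        self.n_features_out_ = self.schema_.n_features
        return self

    def _featurize_one(self, r: PeptideRecord) -> np.ndarray:
        try:
            clean, ann = enc.substitute_anomalies(r.sequence, self._amap)
        except ValueError as e:
            raise FeaturizationError(r.record_id, "anomaly", str(e)) from e
        try:
            pep = desc.compute_descriptors(clean)
            pos = enc.encode_positions(clean, self.max_len)
        except ValueError as e:
            raise FeaturizationError(r.record_id, "sequence", str(e)) from e
        anom = enc.encode_anomalies(ann, self._amap.observed_types)
        if self.genomics_table is not None:
            geno = join_genomics(r, self.genomics_table, self.tissue_map)
        else:
            geno = np.zeros(DEFAULT_N_GENES + 1)
        conc = np.array(
            [r.concentration_uM if r.concentration_uM is not None else 0.0]
        )
        temp = enc.encode_temperature(r.temperature_label)
        inc = enc.encode_incubation(r.incubation_available, r.incubation_min)
        try:
            cargo = enc.encode_cargo(r.cargoes, self._vocab)
        except ValueError as e:
            raise FeaturizationError(r.record_id, "cargo", str(e)) from e
        return np.concatenate([pep, pos, anom, geno, conc, temp, inc, cargo])

    def transform(
        self, X: Sequence[PeptideRecord], y=None
    ) -> FeatureMatrix:
        if not hasattr(self, "schema_"):
            raise RuntimeError("CPPFeaturizer must be fitted before transform")
        rows = [self._featurize_one(r) for r in X]
        values = (
            np.vstack(rows)
            if rows
            else np.empty((0, self.schema_.n_features))
        )
        return FeatureMatrix(
            row_ids=[r.record_id for r in X],
            schema=self.schema_,
            values=values,
        )

    def transform_with_failures(
        self, X: Sequence[PeptideRecord]
    ) -> tuple[FeatureMatrix, list[FeaturizationError]]:
        """Like transform, but collects per-record failures instead of
        aborting the batch (prediction-time contract)."""
        ok_rows, ok_records, failures = [], [], []
        for r in X:
            try:
                ok_rows.append(self._featurize_one(r))
                ok_records.append(r)
            except FeaturizationError as e:
                failures.append(e)
        values = (
            np.vstack(ok_rows)
            if ok_rows
            else np.empty((0, self.schema_.n_features))
        )
        fm = FeatureMatrix(
            row_ids=[r.record_id for r in ok_records],
            schema=self.schema_,
            values=values,
        )
        return fm, failures


def assemble_features(
    records: Sequence[PeptideRecord],
    genomics_table: Optional[GenomicsTable] = None,
    targets: Optional[np.ndarray] = None,
    **featurizer_kwargs,
) -> FeatureMatrix:
    """One-call assembly of the full feature matrix for a record list."""
    fz = CPPFeaturizer(genomics_table=genomics_table, **featurizer_kwargs)
    fm = fz.fit(records).transform(records)
    if targets is not None:
        fm.target = np.asarray(targets, dtype=float)
        if fm.target.shape != (fm.n_samples,):
            raise ValueError("targets length does not match records")
    return fm
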