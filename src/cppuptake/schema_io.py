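"""Dataset schema and I/O for the standard formats the toolkit touches.

The raw tabular format mirrors how quantitative CPP uptake screens are
usually shared: one row per (peptide, cargo, cell line, condition)
measurement with an uptake value, its unit, and the evaluation method.
Column-name mapping is config-driven because published tables rarely agree
on headers; a default mapping covering the common layout is shipped.

Reading is lossless: uptake values/units and raw sequences (including
anomalous residue tokens) are kept verbatim. Harmonization and
substitution happen downstream in :mod:`cppuptake.curation` and
:mod:`cppuptake.encoders`.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideRecord",
    "RejectedRow",
    "FeatureSchema",
    "FeatureMatrix",
    "DEFAULT_DIALECT",
    "TEMPERATURE_CATEGORIES",
    "read_dataset",
    "write_dataset",
    "read_fasta",
    "write_feature_matrix",
    "read_feature_matrix",
    "parse_duration_minutes",
]

#: Closed category set for incubation temperature (degrees Celsius labels).
#: Five categories are used: the biologically meaningful assay temperatures,
#: a catch-all, and an explicit "unknown" for missing annotations.
TEMPERATURE_CATEGORIES = ("4", "25", "37", "other", "unknown")


@dataclass
class PeptideRecord:
    """One raw dataset row, as read (no harmonization applied)."""

    record_id: str
    sequence: str
    cargoes: list[str] = field(default_factory=list)
    cell_line: str = ""
    tissue: Optional[str] = None
    concentration_uM: Optional[float] = None
    temperature_label: str = "unknown"
    incubation_available: bool = False
    incubation_min: float = 0.0
    uptake_value: float = float("nan")
    uptake_unit: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        if len(self.cargoes) > 2:
            raise ValueError(
                f"record {self.record_id!r}: at most two cargoes per peptide "
                f"(got {len(self.cargoes)})"
            )
        if self.temperature_label not in TEMPERATURE_CATEGORIES:
            raise ValueError(
                f"record {self.record_id!r}: temperature label "
                f"{self.temperature_label!r} not in {TEMPERATURE_CATEGORIES}"
            )
        if not self.incubation_available and self.incubation_min != 0.0:
            raise ValueError(
                f"record {self.record_id!r}: incubation_min must be 0 when "
                "incubation is unavailable"
            )
        if self.incubation_min < 0:
            raise ValueError(
                f"record {self.record_id!r}: negative incubation time"
            )


@dataclass
class RejectedRow:
    """A raw row that failed type coercion, kept for auditability."""

    row_number: int  # 1-based, excluding the header
    reason: str
    raw: dict


@dataclass
class FeatureSchema:
    """Ordered description of all feature blocks and their column names."""

    blocks: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        names = self.column_names()
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))
            raise ValueError(f"duplicate feature column name: {dup!r}")

    def column_names(self) -> list[str]:
        return [c for _, cols in self.blocks for c in cols]

    def block_sizes(self) -> dict[str, int]:
        return {name: len(cols) for name, cols in self.blocks}

    def block_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, cols in self.blocks:
            out[name] = slice(start, start + len(cols))
            start += len(cols)
        return out

    @property
    def n_features(self) -> int:
        return sum(len(cols) for _, cols in self.blocks)


@dataclass
class FeatureMatrix:
    """Samples x features numeric table with block annotations."""

    row_ids: list[str]
    schema: FeatureSchema
    values: np.ndarray
    target: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length does not match values rows")
        if self.values.shape[1] != self.schema.n_features:
            raise ValueError(
                f"values have {self.values.shape[1]} columns, schema defines "
                f"{self.schema.n_features}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if self.target.shape != (self.values.shape[0],):
                raise ValueError("target length does not match rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{block}__{c}" for block, cs in self.schema.blocks for c in cs
        ]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "row_id", self.row_ids)
        if self.target is not None:
            df["target"] = self.target
        return df


#: Default column mapping for raw CSVs (field -> header name).
DEFAULT_DIALECT = {
    "record_id": "record_id",
    "sequence": "sequence",
    "cargo1": "cargo1",
    "cargo2": "cargo2",
    "cell_line": "cell_line",
    "tissue": "tissue",
    "concentration_uM": "concentration_uM",
    "temperature_C": "temperature_C",
    "incubation_time": "incubation_time",
    "uptake_value": "uptake_value",
    "uptake_unit": "uptake_unit",
    "method": "method",
}

_MANDATORY_FIELDS = ("sequence", "uptake_value", "uptake_unit", "method")

_DURATION_RE = re.compile(
    r"^\s*([0-9]*\.?[0-9]+)\s*(h|hr|hrs|hour|hours|min|mins|minute|minutes|m|s|sec|secs|seconds)?\s*$",
    re.IGNORECASE,
)


def parse_duration_minutes(text: str) -> Optional[float]:
    """Parse an incubation duration into minutes.

    Accepts bare numbers (minutes), and ``h``/``min``/``s`` suffixes,
    e.g. ``"60"``, ``"1 h"``, ``"90 min"``. Returns None when unparseable.
    """
    m = _DURATION_RE.match(text)
    if not m:
        return None
    value = float(m.group(1))
    unit = (m.group(2) or "min").lower()
    if unit.startswith("h"):
        return value * 60.0
    if unit.startswith("s"):
        return value / 60.0
    return value


def categorize_temperature(text: str) -> str:
    """Map a raw temperature annotation onto the closed category set."""
    text = text.strip().rstrip("Cc").rstrip("°").strip()
    if text in TEMPERATURE_CATEGORIES:  # already categorical (round-trip)
        return text
    if not text or text.lower() in {"na", "n/a", "unknown", "-", "?"}:
        return "unknown"
    try:
        value = float(text)
    except ValueError:
        return "unknown"
    for cat in ("4", "25", "37"):
        if math.isclose(value, float(cat), abs_tol=0.5):
            return cat
    return "other"


def _parse_float(text: str) -> Optional[float]:
    try:
        v = float(text)
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else v  # non-finite kept; curation decides


def read_dataset(
    path: str | Path,
    dialect: Optional[dict] = None,
) -> tuple[list[PeptideRecord], list[RejectedRow]]:
    """Read a raw CPP uptake CSV into typed records plus a reject list.

    Rows that fail type coercion (e.g. a non-numeric uptake value, or a
    concentration like ``"n/a"``) are routed to the reject list with a
    reason — never silently dropped. A genuinely *empty* concentration
    cell is allowed and yields ``concentration_uM=None`` (the benchmark
    filters handle it).
    """
    path = Path(path)
    cmap = dict(DEFAULT_DIALECT)
    if dialect:
        cmap.update(dialect)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: no header row")
        header = set(reader.fieldnames)
        missing = [
            cmap[f] for f in _MANDATORY_FIELDS if cmap[f] not in header
        ]
        if missing:
            raise ValueError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        records: list[PeptideRecord] = []
        rejects: list[RejectedRow] = []
        for i, row in enumerate(reader, start=1):
            def get(fld: str) -> str:
                col = cmap.get(fld)
                return (row.get(col) or "").strip() if col else ""

            reason = None
            uptake = _parse_float(get("uptake_value"))
            if uptake is None:
                reason = "unparseable uptake value"

            conc_text = get("concentration_uM")
            conc: Optional[float] = None
            if reason is None and conc_text:
                conc = _parse_float(conc_text)
                if conc is None:
                    reason = "unparseable concentration"

            inc_text = get("incubation_time")
            inc_min: Optional[float] = None
            if reason is None and inc_text and inc_text.lower() not in {
                "na", "n/a", "-", "?", "unknown",
            }:
                inc_min = parse_duration_minutes(inc_text)
                if inc_min is None or inc_min < 0:
                    reason = "unparseable incubation time"

            if reason is not None:
                rejects.append(RejectedRow(i, reason, dict(row)))
                continue

            cargoes = [c for c in (get("cargo1"), get("cargo2")) if c]
            records.append(
                PeptideRecord(
                    record_id=get("record_id") or f"row{i}",
                    sequence=get("sequence"),
                    cargoes=cargoes,
                    cell_line=get("cell_line"),
                    tissue=get("tissue") or None,
                    concentration_uM=conc,
                    temperature_label=categorize_temperature(
                        get("temperature_C")
                    ),
                    incubation_available=inc_min is not None,
                    incubation_min=inc_min if inc_min is not None else 0.0,
                    uptake_value=uptake,
                    uptake_unit=get("uptake_unit"),
                    method=get("method"),
                )
            )
    return records, rejects


def write_dataset(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records back to the default CSV dialect (inverse of read)."""
    cols = list(DEFAULT_DIALECT.values())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=cols, quoting=csv.QUOTE_MINIMAL)
        w.writeheader()
        for r in records:
            w.writerow(
                {
                    "record_id": r.record_id,
                    "sequence": r.sequence,
                    "cargo1": r.cargoes[0] if r.cargoes else "",
                    "cargo2": r.cargoes[1] if len(r.cargoes) > 1 else "",
                    "cell_line": r.cell_line,
                    "tissue": r.tissue or "",
                    "concentration_uM": (
                        "" if r.concentration_uM is None
                        else repr(r.concentration_uM)
                    ),
                    "temperature_C": (
                        "" if r.temperature_label == "unknown"
                        else r.temperature_label
                    ),
                    "incubation_time": (
                        repr(r.incubation_min) if r.incubation_available else ""
                    ),
                    "uptake_value": repr(r.uptake_value),
                    "uptake_unit": r.uptake_unit,
                    "method": r.method,
                }
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs, order preserved.

    Sequences are upper-cased. Content before the first header is a parse
    error reported with its line number.
    """
    from Bio import SeqIO

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: expected FASTA header line "
                    f"starting with '>', got {line.strip()[:30]!r}"
                )
            break
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV with block-prefixed column names."""
    fm.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(
    path: str | Path, schema: FeatureSchema
) -> FeatureMatrix:
    """Read a CSV written by :func:`write_feature_matrix` back, losslessly."""
    df = pd.read_csv(path)
    expected = [
        f"{block}__{c}" for block, cs in schema.blocks for c in cs
    ]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing feature columns (first: {missing[0]!r})"
        )
    target = df["target"].to_numpy() if "target" in df.columns else None
    return FeatureMatrix(
        row_ids=[str(x) for x in df["row_id"]],
        schema=schema,
        values=df[expected].to_numpy(dtype=float),
        target=target,
    )
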