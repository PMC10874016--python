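"""Categorical feature blocks: position one-hot, anomalies, conditions, cargo.

Anomalous residues (D-enantiomers written in lowercase, single-letter
non-standard codes, and bracketed modification tokens such as ``[Orn]``)
are substituted by their closest standard amino acid before sequence
featurization; each substitution's 1-based position and type label are
kept and flagged in a dedicated block. The default substitution
vocabulary (56 types, of which 46 are emitted as indicator columns) ships
as ``anomaly_map_synthetic.csv`` — a synthetic curated default, not a
transcription of any published table.

Layout conventions (frozen for bit-exact export):
  * position one-hot: position-major, residues in alphabetical order
    (``pos001_A, pos001_C, ..., pos100_Y``), 100 x 20 = 2,000 columns;
  * anomaly block: 24 position indicators then the observed substitution
    types in vocabulary order (24 + 46 = 70 columns);
  * temperature: one-hot over the five closed categories;
  * cargo: multi-hot over the 63-label vocabulary (at most two set).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .schema_io import TEMPERATURE_CATEGORIES

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
MAX_PEPTIDE_LEN = 100
MAX_ANOMALY_POS = 24

__all__ = [
    "AnomalySubstitutionMap",
    "AnomalyAnnotation",
    "load_default_anomaly_map",
    "load_default_cargo_vocab",
    "substitute_anomalies",
    "encode_positions",
    "encode_anomalies",
    "encode_temperature",
    "encode_incubation",
    "encode_cargo",
    "position_column_names",
    "anomaly_column_names",
]


@dataclass(frozen=True)
class AnomalySubstitutionMap:
    """Map from anomalous token -> (standard replacement, type label)."""

    entries: dict  # token -> (replacement, type_label)
    observed_types: tuple  # type labels emitted as indicator columns

    def __post_init__(self) -> None:
        types = [t for _, t in self.entries.values()]
        if len(types) != len(set(types)):
            raise ValueError("substitution type labels must be unique")
        bad = {
            r for r, _ in self.entries.values() if r not in STANDARD_AA
        }
        if bad:
            raise ValueError(
                f"replacements must be standard amino acids, got {bad}"
            )
        unknown = set(self.observed_types) - set(types)
        if unknown:
            raise ValueError(
                f"observed types not in vocabulary: {sorted(unknown)}"
            )


@dataclass
class AnomalyAnnotation:
    """Positions (1-based) and type labels of performed substitutions."""

    positions: list[int] = field(default_factory=list)
    types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.types):
            raise ValueError("positions and types must be parallel")


def load_default_anomaly_map() -> AnomalySubstitutionMap:
    with resources.files("cppuptake.data").joinpath(
        "anomaly_map_synthetic.csv"
    ).open() as fh:
        rows = list(csv.DictReader(fh))
    entries = {r["token"]: (r["replacement"], r["type"]) for r in rows}
    observed = tuple(r["type"] for r in rows if r["observed"] == "1")
    return AnomalySubstitutionMap(entries=entries, observed_types=observed)


def load_default_cargo_vocab() -> list[str]:
    with resources.files("cppuptake.data").joinpath(
        "cargo_vocab_synthetic.csv"
    ).open() as fh:
        return [r["label"] for r in csv.DictReader(fh)]


_TOKEN_RE = re.compile(r"\[[^\[\]]*\]|.")


def tokenize_sequence(raw_seq: str) -> list[str]:
    """Split a raw sequence into residue tokens (``[...]`` is one token)."""
    return _TOKEN_RE.findall(raw_seq)


def substitute_anomalies(
    raw_seq: str, amap: Optional[AnomalySubstitutionMap] = None
) -> tuple[str, AnomalyAnnotation]:
    """Replace anomalous tokens by their closest standard residue.

    Returns the clean sequence (standard residues only) and an annotation
    recording each substitution's 1-based position and type label.
    Raises on any token the map does not cover.
    """
    amap = amap or load_default_anomaly_map()
    clean: list[str] = []
    ann = AnomalyAnnotation()
    for pos, tok in enumerate(tokenize_sequence(raw_seq), start=1):
        if tok in STANDARD_AA:
            clean.append(tok)
            continue
        if tok not in amap.entries:
            raise ValueError(
                f"anomalous token {tok!r} at position {pos} is not covered "
                "by the substitution map"
            )
        repl, type_label = amap.entries[tok]
        clean.append(repl)
        ann.positions.append(pos)
        ann.types.append(type_label)
    return "".join(clean), ann


def position_column_names(max_len: int = MAX_PEPTIDE_LEN) -> list[str]:
    return [
        f"pos{i:03d}_{a}" for i in range(1, max_len + 1) for a in STANDARD_AA
    ]


def encode_positions(
    clean_seq: str, max_len: int = MAX_PEPTIDE_LEN
) -> np.ndarray:
    """Position one-hot encoding padded with zeros to ``max_len`` x 20."""
    if len(clean_seq) > max_len:
        raise ValueError(
            f"sequence length {len(clean_seq)} exceeds the maximum of "
            f"{max_len} residues"
        )
    out = np.zeros(max_len * len(STANDARD_AA))
    for i, a in enumerate(clean_seq):
        j = STANDARD_AA.index(a)
        if j < 0:  # pragma: no cover - guarded upstream
            raise ValueError(f"non-standard residue {a!r}")
        out[i * len(STANDARD_AA) + j] = 1.0
    return out


def anomaly_column_names(
    observed_types: Sequence[str], max_pos: int = MAX_ANOMALY_POS
) -> list[str]:
    return [f"anom_pos_{i:02d}" for i in range(1, max_pos + 1)] + [
        f"anom_type_{t}" for t in observed_types
    ]


def encode_anomalies(
    ann: AnomalyAnnotation,
    observed_types: Sequence[str],
    max_pos: int = MAX_ANOMALY_POS,
) -> np.ndarray:
    """Indicator block for substitution positions (<= 24) and types.

    Positions beyond ``max_pos`` are not featurized (warned); unknown type
    labels are an error.
    """
    out = np.zeros(max_pos + len(observed_types))
    type_index = {t: i for i, t in enumerate(observed_types)}
    for pos, typ in zip(ann.positions, ann.types):
        if pos > max_pos:
            warnings.warn(
                f"substitution at position {pos} beyond the featurized "
                f"maximum of {max_pos}; position flag dropped",
                stacklevel=2,
            )
        else:
            out[pos - 1] = 1.0
        if typ in type_index:
            out[max_pos + type_index[typ]] = 1.0
        elif typ not in _known_types(observed_types):
            raise ValueError(f"unknown substitution type label {typ!r}")
    return out


def _known_types(observed_types: Sequence[str]) -> set:
    # A type absent from the observed list is legal only if the default
    # vocabulary knows it (the 10 never-observed types encode as all-zero).
    try:
        full = {t for _, t in load_default_anomaly_map().entries.values()}
    except Exception:  # pragma: no cover
        full = set()
    return full | set(observed_types)


def encode_temperature(label: str) -> np.ndarray:
    """One-hot over the closed five-category temperature set."""
    if label not in TEMPERATURE_CATEGORIES:
        raise ValueError(
            f"temperature label {label!r} not in {TEMPERATURE_CATEGORIES}; "
            "use 'other' for uncommon assay temperatures"
        )
    out = np.zeros(len(TEMPERATURE_CATEGORIES))
    out[TEMPERATURE_CATEGORIES.index(label)] = 1.0
    return out


def encode_incubation(available: bool, minutes: float = 0.0) -> np.ndarray:
    """(availability indicator, duration in minutes); (0, 0) if unavailable."""
    if not available:
        return np.array([0.0, 0.0])
    if minutes < 0:
        raise ValueError(f"negative incubation time: {minutes}")
    return np.array([1.0, float(minutes)])


def encode_cargo(
    cargoes: Sequence[str], vocab: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Multi-hot cargo encoding (up to two cargoes; duplicates collapse)."""
    vocab = list(vocab) if vocab is not None else load_default_cargo_vocab()
    if len(cargoes) > 2:
        raise ValueError("at most two cargoes per peptide")
    out = np.zeros(len(vocab))
    for c in cargoes:
        if c not in vocab:
            near = sorted(vocab, key=lambda v: _lev(c.lower(), v.lower()))[:3]
            raise ValueError(
                f"unknown cargo label {c!r}; nearest vocabulary entries: "
                f"{near}"
            )
        out[vocab.index(c)] = 1.0
    return out


def _lev(a: str, b: str) -> int:
    # small edit-distance helper for error messages only
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]
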