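"""Cell-line genomics features: gene-mutation indicators joined per record.

A genomics table (GDSC-style export: one row per cell line, binary gene
mutation indicators plus a tissue label) is joined onto each record by
normalized cell-line name. Records whose cell line is absent fall back to
a same-tissue proxy line (alphabetically first normalized name, unless a
tissue-proxy map overrides), with the final column — the exact-match flag
— distinguishing true matches (1) from proxy or missing joins (0).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema_io import PeptideRecord

logger = logging.getLogger(__name__)

DEFAULT_N_GENES = 735

__all__ = [
    "GenomicsTable",
    "DEFAULT_N_GENES",
    "normalize_cell_line_name",
    "load_genomics_table",
    "join_genomics",
]

_NORM_RE = re.compile(r"[\s\-\._/]+")


def normalize_cell_line_name(name: str) -> str:
    """Case-folded, separator-insensitive canonical cell-line name."""
    if not name or not name.strip():
        raise ValueError("empty cell-line name")
    return _NORM_RE.sub("", name.strip().lower())


@dataclass
class GenomicsTable:
    """Cell line -> (tissue, binary mutation indicators over gene_order)."""

    frame: pd.DataFrame  # index: normalized cell-line name; col 'tissue' + genes
    gene_order: list[str]

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValueError(f"duplicate cell line after normalization: {dup!r}")
        missing = [g for g in self.gene_order if g not in self.frame.columns]
        if missing:
            raise ValueError(f"genes missing from table: {missing[:5]}")
        vals = self.frame[self.gene_order].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation indicators must be binary")

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)

    def cell_lines(self) -> list[str]:
        return list(self.frame.index)

    def row(self, normalized_name: str) -> np.ndarray:
        return self.frame.loc[normalized_name, self.gene_order].to_numpy(
            dtype=float
        )

    def tissue_of(self, normalized_name: str) -> str:
        return str(self.frame.loc[normalized_name, "tissue"])


def load_genomics_table(
    path,
    expected_genes: int = DEFAULT_N_GENES,
    allow_gene_count_mismatch: bool = False,
) -> GenomicsTable:
    """Load a genomics CSV (cell_line, tissue, gene_1..gene_N).

    The gene count must equal ``expected_genes`` unless explicitly
    overridden (useful for reduced stand-in tables in tests).
    """
    df = pd.read_csv(path)
    for col in ("cell_line", "tissue"):
        if col not in df.columns:
            raise ValueError(f"genomics table missing column {col!r}")
    genes = [c for c in df.columns if c not in ("cell_line", "tissue")]
    if len(genes) != expected_genes:
        if not allow_gene_count_mismatch:
            raise ValueError(
                f"genomics table has {len(genes)} gene columns, expected "
                f"{expected_genes}; pass allow_gene_count_mismatch=True for "
                "stand-in tables"
            )
        warnings.warn(
            f"genomics table has {len(genes)} genes instead of "
            f"{expected_genes}; proceeding with override",
            stacklevel=2,
        )
    df = df.copy()
    df.index = pd.Index(
        [normalize_cell_line_name(n) for n in df["cell_line"]], name="cell_line"
    )
    # binarize: any recorded mutation count -> 1
    df[genes] = (df[genes].to_numpy() != 0).astype(int)
    return GenomicsTable(frame=df[["tissue"] + genes], gene_order=genes)


def join_genomics(
    record: PeptideRecord,
    table: GenomicsTable,
    tissue_map: dict | None = None,
) -> np.ndarray:
    """Per-record genomics block: N gene indicators + 1 exact-match flag.

    Exact-name hit -> that row with flag 1. Miss with a known tissue ->
    the tissue proxy row with flag 0 (alphabetically first same-tissue
    line, unless ``tissue_map`` maps the tissue to a specific line).
    Total miss -> zeros with flag 0 and a logged warning.
    """
    try:
        key = normalize_cell_line_name(record.cell_line)
    except ValueError:
        key = ""
    if key and key in table.frame.index:
        return np.concatenate([table.row(key), [1.0]])

    tissue = (record.tissue or "").strip().lower()
    if tissue:
        proxy = None
        if tissue_map and tissue in tissue_map:
            cand = normalize_cell_line_name(tissue_map[tissue])
            if cand in table.frame.index:
                proxy = cand
        if proxy is None:
            same = sorted(
                n
                for n in table.frame.index
                if table.tissue_of(n).strip().lower() == tissue
            )
            proxy = same[0] if same else None
        if proxy is not None:
            logger.info(
                "cell line %r not in genomics table; using same-tissue proxy %r",
                record.cell_line,
                proxy,
            )
            return np.concatenate([table.row(proxy), [0.0]])

    logger.warning(
        "cell line %r (record %s) has no genomics match or tissue proxy; "
        "encoding zeros with match flag 0",
        record.cell_line,
        record.record_id,
    )
    return np.concatenate([np.zeros(table.n_genes), [0.0]])
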