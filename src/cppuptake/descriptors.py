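"""Whole-peptide physicochemical descriptors (31 values per sequence).

The roster is a fixed, documented convention: ten scalar descriptors
(length, average molecular weight, net charge at pH 7, isoelectric point,
aliphatic index, Boman index, instability index, mean hydrophobicity, and
the helical/sheet hydrophobic moments at 100 deg and 160 deg) followed by
the per-residue scale-set means of the Kidera factors (10), Cruciani
properties (3), Z-scales (5) and MS-WHIM scores (3) — 31 in total. The
roster order is frozen so feature matrices are bit-reproducible.

Scale tables ship as packaged CSVs (one per scale) and are loaded by name;
net charge uses the EMBOSS pKa set by default, hydrophobicity defaults to
Kyte–Doolittle. Instability-index dipeptide weights come from Biopython's
published table.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
WATER_MASS_DA = 18.01524

__all__ = [
    "STANDARD_AA",
    "DESCRIPTOR_NAMES",
    "ResidueScaleTable",
    "load_scale",
    "load_scale_set",
    "load_pka_set",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "aliphatic_index",
    "instability_index",
    "boman_index",
    "hydrophobicity_mean",
    "hydrophobic_moment",
    "scale_set_means",
    "compute_descriptors",
]


@dataclass(frozen=True)
class ResidueScaleTable:
    """A named per-residue scale: exactly one finite value per standard AA."""

    name: str
    values: dict

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_AA):
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                "amino acids"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has non-finite values")


def _data_path(fname: str):
    return resources.files("cppuptake.data.scales").joinpath(fname)


@functools.lru_cache(maxsize=None)
def load_scale(name: str) -> ResidueScaleTable:
    """Load a single-column residue scale by name (CSV: residue,value)."""
    import csv

    with _data_path(f"{name}.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    return ResidueScaleTable(
        name, {r["residue"]: float(r["value"]) for r in rows}
    )


@functools.lru_cache(maxsize=None)
def load_scale_set(name: str) -> list[ResidueScaleTable]:
    """Load a multi-component scale family (Kidera, Cruciani, ...)."""
    import csv

    with _data_path(f"{name}.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    comps = [c for c in rows[0] if c != "residue"]
    return [
        ResidueScaleTable(
            f"{name}.{c}", {r["residue"]: float(r[c]) for r in rows}
        )
        for c in comps
    ]


@functools.lru_cache(maxsize=None)
def load_pka_set(name: str = "emboss") -> dict:
    """Load a pKa set: group -> (pKa, charge sign of the ionized form)."""
    import csv

    with _data_path(f"pka_{name}.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    return {r["group"]: (float(r["pka"]), int(r["charge"])) for r in rows}


def _validate(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    for i, a in enumerate(seq, start=1):
        if a not in STANDARD_AA:
            raise ValueError(
                f"unknown residue {a!r} at position {i}; run anomaly "
                "substitution first"
            )
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    _validate(seq)
    masses = load_scale("residue_mass_average").values
    return sum(masses[a] for a in seq) + WATER_MASS_DA


def net_charge(seq: str, pH: float = 7.0, pka_set: str = "emboss") -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Sums the partial charges of the N-terminus, C-terminus, and the
    ionizable side chains (D, E, C, Y, H, K, R). Basic groups contribute
    ``+1/(1+10^(pH-pKa))``, acidic groups ``-1/(1+10^(pKa-pH))``.
    """
    _validate(seq)
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    pka = load_pka_set(pka_set)

    def partial(pk: float, sign: int) -> float:
        if sign > 0:
            return 1.0 / (1.0 + 10.0 ** (pH - pk))
        return -1.0 / (1.0 + 10.0 ** (pk - pH))

    charge = partial(*pka["Nterm"]) + partial(*pka["Cterm"])
    for a in seq:
        if a in pka:
            charge += partial(*pka[a])
    return charge


def isoelectric_point(seq: str, pka_set: str = "emboss") -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The termini guarantee a positive charge at pH 0 and a non-positive
    one at pH 14, so a root always exists and the iteration converges to
    ``|charge| < 1e-4``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka_set)
        if abs(q) < 1e-4:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def aliphatic_index(seq: str) -> float:
    """Relative volume of aliphatic side chains.

    ``X_Ala + 2.9 * X_Val + 3.9 * (X_Ile + X_Leu)`` with X in mole percent.
    """
    _validate(seq)
    n = len(seq)
    x = {a: 100.0 * seq.count(a) / n for a in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def instability_index(seq: str, diwv: dict | None = None) -> float:
    """Dipeptide-weight instability index: (10/L) * sum of DIWV weights.

    Weights default to the published dipeptide instability table
    (via Biopython's ProtParam data).
    """
    _validate(seq)
    if len(seq) < 2:
        raise ValueError("instability index requires length >= 2")
    if diwv is None:
        from Bio.SeqUtils import ProtParamData

        diwv = ProtParamData.DIWV
    total = sum(diwv[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 / len(seq) * total


def boman_index(seq: str, scale: ResidueScaleTable | None = None) -> float:
    """Mean per-residue solubility value (protein-binding potential)."""
    _validate(seq)
    values = (scale or load_scale("boman")).values
    return sum(values[a] for a in seq) / len(seq)


def hydrophobicity_mean(
    seq: str, scale: ResidueScaleTable | None = None
) -> float:
    """Arithmetic mean of a per-residue hydrophobicity scale."""
    _validate(seq)
    values = (scale or load_scale("kyte_doolittle")).values
    return sum(values[a] for a in seq) / len(seq)


def hydrophobic_moment(
    seq: str,
    angle_deg: float = 100.0,
    scale: ResidueScaleTable | None = None,
) -> float:
    """Amphipathicity: magnitude of the periodic hydrophobicity projection.

    ``sqrt((sum H_i sin(i*delta))^2 + (sum H_i cos(i*delta))^2) / N`` with
    delta in radians and i = 0..N-1. 100 deg probes the alpha-helix period,
    160 deg the beta-sheet period.
    """
    _validate(seq)
    if not 0.0 < angle_deg < 360.0:
        raise ValueError(f"angle must be in (0, 360), got {angle_deg}")
    values = (scale or load_scale("kyte_doolittle")).values
    delta = math.radians(angle_deg)
    h = np.array([values[a] for a in seq])
    i = np.arange(len(seq))
    return float(
        math.hypot(float(h @ np.sin(i * delta)), float(h @ np.cos(i * delta)))
        / len(seq)
    )


_SCALE_SET_NAMES = ("kidera", "cruciani", "zscales", "mswhim")


def scale_set_means(
    seq: str, set_names: tuple[str, ...] = _SCALE_SET_NAMES
) -> list[float]:
    """Per-component mean over residues for each scale family, roster order."""
    _validate(seq)
    out = []
    for name in set_names:
        for comp in load_scale_set(name):
            out.append(sum(comp.values[a] for a in seq) / len(seq))
    return out


def _scale_set_component_names(
    set_names: tuple[str, ...] = _SCALE_SET_NAMES,
) -> list[str]:
    return [c.name for name in set_names for c in load_scale_set(name)]


#: Frozen descriptor roster order (31 names).
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    [
        "length",
        "molecular_weight",
        "net_charge_ph7",
        "isoelectric_point",
        "aliphatic_index",
        "boman_index",
        "instability_index",
        "hydrophobicity_mean",
        "hydrophobic_moment_alpha",
        "hydrophobic_moment_beta",
    ]
    + [f"kidera.KF{i}" for i in range(1, 11)]
    + [f"cruciani.PP{i}" for i in range(1, 4)]
    + [f"zscales.Z{i}" for i in range(1, 6)]
    + [f"mswhim.MSWHIM{i}" for i in range(1, 4)]
)


def compute_descriptors(seq: str) -> np.ndarray:
    """Compute the fixed 31-descriptor vector for a validated sequence.

    Length-1 sequences get an instability index of 0 (with a warning)
    rather than an error, so assembly of datasets containing very short
    peptides never aborts.
    """
    _validate(seq)
    if len(seq) >= 2:
        instab = instability_index(seq)
    else:
        warnings.warn(
            "instability index undefined for length-1 sequence; reporting 0",
            stacklevel=2,
        )
        instab = 0.0
    vec = [
        float(len(seq)),
        molecular_weight(seq),
        net_charge(seq, 7.0),
        isoelectric_point(seq),
        aliphatic_index(seq),
        boman_index(seq),
        instab,
        hydrophobicity_mean(seq),
        hydrophobic_moment(seq, 100.0),
        hydrophobic_moment(seq, 160.0),
    ] + scale_set_means(seq)
    out = np.asarray(vec, dtype=float)
    assert out.shape == (len(DESCRIPTOR_NAMES),)
    return out
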