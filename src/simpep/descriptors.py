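"""Physicochemical peptide representations and scalar annotations.

Two five-component per-residue descriptor systems are provided — the Sandberg
z-scales and the Tian topological T-scales, both standard in peptide QSAR. A
peptide of length ``l`` yields an ``l x 5`` matrix which is mean-pooled into a
single 5-vector. Scalar annotations cover average (or monoisotopic) molecular
mass and Henderson-Hasselbalch net charge at a given pH with an EMBOSS-style
pKa set; all tables ship as JSON package data with citations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from simpep.peptide_io import Peptide


class DescriptorError(Exception):
    """A residue has no entry in the requested table, or invalid input."""


def _load_json(resource: str) -> dict:
    text = resources.files("simpep.data").joinpath(resource).read_text(encoding="utf-8")
    return json.loads(text)


@lru_cache(maxsize=None)
def _scales() -> dict:
    return _load_json("descriptor_scales.json")


@lru_cache(maxsize=None)
def _physchem() -> dict:
    return _load_json("physchem.json")


@dataclass(frozen=True)
class DescriptorTable:
    """A named per-residue descriptor table with 5 components per residue."""

    name: str
    rows: dict

    def row(self, residue: str) -> np.ndarray:
        try:
            return np.asarray(self.rows[residue], dtype=float)
        except KeyError:
            raise DescriptorError(
                f"residue {residue!r} has no entry in descriptor table {self.name!r}"
            ) from None


@lru_cache(maxsize=None)
def get_descriptor_table(name: str) -> DescriptorTable:
    """Fetch a packaged descriptor table by name (``zscale`` or ``tscale``)."""
    scales = _scales()
    key = name.lower().replace("-", "").replace("_", "")
    if key not in scales or key.startswith("_"):
        available = sorted(k for k in scales if not k.startswith("_"))
        raise DescriptorError(f"unknown descriptor table {name!r}; available: {available}")
    return DescriptorTable(key, scales[key])


def _as_sequence(peptide) -> str:
    return peptide.sequence if isinstance(peptide, Peptide) else str(peptide)


def descriptor_vector(peptide, table) -> np.ndarray:
    """Mean-pooled descriptor representation of a peptide.

    The ``l x 5`` per-residue matrix is averaged across residues, so a
    length-1 peptide returns its residue's row exactly and a sequence
    concatenated with itself maps to the same vector.
    """
    if isinstance(table, str):
        table = get_descriptor_table(table)
    seq = _as_sequence(peptide)
    if not seq:
        raise DescriptorError("cannot compute descriptors of an empty sequence")
    matrix = np.stack([table.row(ch) for ch in seq])
    return matrix.mean(axis=0)


def average_mass(peptide, monoisotopic: bool = False) -> float:
    """Molecular mass of a peptide in Da.

    Sum of residue masses plus one water (18.01528 Da average). Average
    isotope-abundance-weighted masses by default; ``monoisotopic=True``
    switches the residue and water tables.
    """
    data = _physchem()
    table = data["monoisotopic_mass"] if monoisotopic else data["average_mass"]
    water = data["water_monoisotopic"] if monoisotopic else data["water_average"]
    seq = _as_sequence(peptide)
    if not seq:
        raise DescriptorError("cannot compute the mass of an empty sequence")
    total = water
    for ch in seq:
        try:
            total += table[ch]
        except KeyError:
            raise DescriptorError(f"residue {ch!r} has no mass entry") from None
    return total


@dataclass(frozen=True)
class PhyschemRecord:
    """Scalar physicochemistry for one peptide at a stated pH."""

    sequence: str
    average_mass: float
    ph: float
    net_charge: float
    rounded_charge: int


def net_charge(peptide, ph: float = 7.0) -> PhyschemRecord:
    """Henderson-Hasselbalch net charge at ``ph``.

    Positive contributions from the free N-terminus and K/R/H side chains,
    negative from the free C-terminus and D/E/C/Y side chains; each group
    contributes its protonated/deprotonated fraction
    ``1 / (1 + 10^(±(pH − pKa)))``. ``rounded_charge`` is the nearest integer.
    """
    if not 0.0 <= ph <= 14.0:
        raise DescriptorError(f"pH {ph} outside the valid range [0, 14]")
    data = _physchem()
    pka = data["pka"]
    seq = _as_sequence(peptide)
    if not seq:
        raise DescriptorError("cannot compute the charge of an empty sequence")
    for ch in seq:
        if ch not in data["average_mass"]:
            raise DescriptorError(f"residue {ch!r} is outside the canonical alphabet")

    def positive(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def negative(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = positive(pka["n_terminus"]) + negative(pka["c_terminus"])
    for ch in seq:
        if ch in data["positive_side_chains"]:
            charge += positive(pka[ch])
        elif ch in data["negative_side_chains"]:
            charge += negative(pka[ch])
    return PhyschemRecord(
        sequence=seq,
        average_mass=average_mass(seq),
        ph=ph,
        net_charge=charge,
        rounded_charge=int(round(charge)),
    )
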