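"""Amino-acid descriptor tables and class partitions.

All knowledge-based features describing the chemistry of a substitution draw
from this module: molar side-chain volumes, a hydrophobicity index, rotamer
counts as a flexibility proxy, and five categorical partitions of the twenty
standard amino acids (chemical nature, size, polarity, hydrogen-bonding role,
hydropathy).

The numeric tables are literature constants shipped with the package:

* molar volumes from the Zamyatnin amino-acid volume compilation (A^3);
* the Moon-Fleming side-chain hydrophobicity scale (kcal/mol);
* favoured side-chain rotamer counts from the penultimate rotamer library
  (glycine and alanine have no chi angles and count as 1 by convention).

Every table can be overridden from a flat key/value text file so alternative
scales can be tested without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The twenty standard amino acids, alphabetical by one-letter code."""

# Zamyatnin residue volumes, A^3
MOLAR_VOLUME: Dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Moon-Fleming whole-protein side-chain transfer free energies, kcal/mol.
# More positive = more hydrophilic; alanine is the reference point.
HYDROPHOBIC_INDEX: Dict[str, float] = {
    "A": 0.00, "C": -0.24, "D": 1.23, "E": 2.02, "F": -1.71,
    "G": 1.15, "H": 0.99, "I": -1.12, "K": 0.99, "L": -1.25,
    "M": -0.67, "N": 0.42, "P": 0.45, "Q": 0.58, "R": 1.81,
    "S": 0.46, "T": 0.25, "V": -0.46, "W": -2.09, "Y": -0.71,
}

# Favoured rotamer counts (penultimate rotamer library); G/A = 1 (no chi).
ROTAMER_COUNT: Dict[str, int] = {
    "A": 1, "C": 3, "D": 5, "E": 8, "F": 4,
    "G": 1, "H": 8, "I": 7, "K": 27, "L": 5,
    "M": 13, "N": 7, "P": 2, "Q": 9, "R": 34,
    "S": 3, "T": 3, "V": 3, "W": 7, "Y": 6,
}

# Categorical partitions of the 20 amino acids. Class membership strings are
# the definition; the dict order is irrelevant (encoders sort class names).
CHEMICAL_CLASSES: Dict[str, str] = {
    "aliphatic": "AGILPV",
    "aromatic": "FWY",
    "sulfur": "CM",
    "hydroxyl": "ST",
    "basic": "RHK",
    "acidic": "DE",
    "amide": "NQ",
}

SIZE_CLASSES: Dict[str, str] = {
    "small": "GASCDPNT",
    "medium": "QEHV",
    "large": "RILKMFWY",
}

POLARITY_CLASSES: Dict[str, str] = {
    "polar": "RNDQEHKSTY",
    "nonpolar": "ACGILMFPWV",
}

HBOND_CLASSES: Dict[str, str] = {
    "donor": "RKW",
    "acceptor": "DE",
    "both": "NQHSTY",
    "none": "ACGILMFPV",
}

HYDROPATHY_CLASSES: Dict[str, str] = {
    "hydrophobic": "ACILMFWV",
    "neutral": "GHPSTY",
    "hydrophilic": "RNDQEK",
}

PARTITIONS: Dict[str, Dict[str, str]] = {
    "chemical": CHEMICAL_CLASSES,
    "size": SIZE_CLASSES,
    "polarity": POLARITY_CLASSES,
    "hbond": HBOND_CLASSES,
    "hydropathy": HYDROPATHY_CLASSES,
}


class DescriptorLookupError(KeyError):
    """Raised when an amino-acid code or partition scheme is unknown."""


def _check_aa(aa: str) -> str:
    if aa not in MOLAR_VOLUME:
        raise DescriptorLookupError(f"unknown amino-acid code {aa!r}")
    return aa


@dataclass
class AADescriptorTable:
    """Per-amino-acid numeric descriptors, overridable as a unit.

    Attributes
    ----------
    molar_volume, hydrophobic_index, rotamer_count
        Mappings from one-letter code to the descriptor value. Defaults are
        the shipped literature constants.
    """

    molar_volume: Mapping[str, float] = field(default_factory=lambda: dict(MOLAR_VOLUME))
    hydrophobic_index: Mapping[str, float] = field(default_factory=lambda: dict(HYDROPHOBIC_INDEX))
    rotamer_count: Mapping[str, float] = field(default_factory=lambda: dict(ROTAMER_COUNT))

    def __post_init__(self) -> None:
        for name, table in (
            ("molar_volume", self.molar_volume),
            ("hydrophobic_index", self.hydrophobic_index),
            ("rotamer_count", self.rotamer_count),
        ):
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise ValueError(f"{name} table lacks entries for {sorted(missing)}")

    @classmethod
    def with_overrides(
        cls,
        molar_volume: Path | str | None = None,
        hydrophobic_index: Path | str | None = None,
        rotamer_count: Path | str | None = None,
    ) -> "AADescriptorTable":
        """Build a table applying flat key/value override files where given.

        Each file holds whitespace-separated ``<one-letter code> <value>``
        lines; ``#`` starts a comment.
        """
        def load(path, base):
            merged = dict(base)
            merged.update(read_override_file(path))
            return merged

        return cls(
            molar_volume=load(molar_volume, MOLAR_VOLUME) if molar_volume else dict(MOLAR_VOLUME),
            hydrophobic_index=load(hydrophobic_index, HYDROPHOBIC_INDEX)
            if hydrophobic_index else dict(HYDROPHOBIC_INDEX),
            rotamer_count=load(rotamer_count, ROTAMER_COUNT)
            if rotamer_count else dict(ROTAMER_COUNT),
        )


def read_override_file(path: Path | str) -> Dict[str, float]:
    """Read a flat ``aa value`` override table; returns {code: value}."""
    out: Dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        code, value = line.split()
        out[_check_aa(code)] = float(value)
    return out


DEFAULT_TABLE = AADescriptorTable()


def net_volume(wt: str, mut: str, table: AADescriptorTable = DEFAULT_TABLE) -> float:
    """Signed molar-volume change volume(mut) - volume(wt), A^3."""
    return table.molar_volume[_check_aa(mut)] - table.molar_volume[_check_aa(wt)]


def net_hydrophobicity(wt: str, mut: str, table: AADescriptorTable = DEFAULT_TABLE) -> float:
    """Signed hydrophobicity-index change HI(mut) - HI(wt)."""
    return table.hydrophobic_index[_check_aa(mut)] - table.hydrophobic_index[_check_aa(wt)]


def net_flexibility(wt: str, mut: str, table: AADescriptorTable = DEFAULT_TABLE) -> float:
    """Signed change in favoured rotamer count, mutant minus wild type."""
    return table.rotamer_count[_check_aa(mut)] - table.rotamer_count[_check_aa(wt)]


def class_of(aa: str, scheme: str) -> str:
    """Class label of ``aa`` under one of the five partition schemes.

    ``scheme`` is one of ``chemical``, ``size``, ``polarity``, ``hbond``,
    ``hydropathy``.
    """
    _check_aa(aa)
    try:
        partition = PARTITIONS[scheme]
    except KeyError:
        raise DescriptorLookupError(f"unknown partition scheme {scheme!r}") from None
    for label, members in partition.items():
        if aa in members:
            return label
    raise DescriptorLookupError(f"{aa!r} unclassified under {scheme!r}")  # pragma: no cover
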