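"""PDB structure parsing and residue-level geometry queries.

Reads protein-protein complex structures from PDB files into a lightweight
internal model (chains -> residues -> heavy-atom coordinates) together with
the crystallographic metadata the featurizer consumes (resolution, data
collection temperature, crystallization pH). Geometry queries cover the
sequence neighbourhood of a mutation site, interior missing-residue
detection, and nearest cross-chain residues.

Conventions:

* residue-residue distance is the minimum heavy-atom-to-heavy-atom distance;
* alternate conformers are reduced to the highest-occupancy one;
* selenomethionine and other modified residues with a standard parent are
  mapped to the parent one-letter code, anything else is excluded;
* chain termini are not "missing residues" -- only interior numbering gaps,
  or residues declared unobserved in REMARK 465, count as gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import gemmi
import numpy as np

from .descriptors import AMINO_ACIDS

GAP = "-"
"""Sentinel for a sequence-window slot with no observed residue."""

NONE_RESIDUE = "."
"""Sentinel padding an inter-chain neighbour list shorter than k."""

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Fallbacks used when a PDB file carries no REMARK metadata (imputed flags
# are set so downstream consumers can tell).
DEFAULT_TEMPERATURE_K = 298.0
DEFAULT_PH = 7.0
DEFAULT_RESOLUTION_A = 2.5


class StructureError(ValueError):
    """The file parsed but does not describe a usable complex."""


class PDBParseError(ValueError):
    """The file could not be read as PDB text."""


class SiteMissingError(KeyError):
    """The requested (chain, residue number) does not exist in the structure."""


class MutationMismatchError(ValueError):
    """The wild-type code of a mutation does not match the structure."""


@dataclass(frozen=True)
class MutationSpec:
    """A single candidate point mutation.

    ``chain_id`` and ``residue_number`` follow the numbering of the PDB file;
    ``wt_aa``/``mut_aa`` are one-letter codes and must differ.
    """

    chain_id: str
    residue_number: int
    wt_aa: str
    mut_aa: str
    icode: str = ""

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS or self.mut_aa not in AMINO_ACIDS:
            raise ValueError(f"non-standard amino acid in {self}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"wild-type and mutant residues are identical in {self}")

    def reversed(self) -> "MutationSpec":
        """The hypothetical reverse substitution at the same site."""
        return MutationSpec(self.chain_id, self.residue_number,
                            self.mut_aa, self.wt_aa, self.icode)

    def __str__(self) -> str:  # e.g. "A:42 G>W"
        return f"{self.chain_id}:{self.residue_number}{self.icode} {self.wt_aa}>{self.mut_aa}"


@dataclass
class Residue:
    """One observed amino-acid residue with its heavy-atom coordinates (A)."""

    number: int
    icode: str
    aa: str
    atoms: Dict[str, np.ndarray]

    @property
    def has_ca(self) -> bool:
        return "CA" in self.atoms

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of heavy-atom coordinates."""
        return np.array(list(self.atoms.values()), dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue]

    def index_of(self, number: int, icode: str = "") -> int:
        for i, res in enumerate(self.residues):
            if res.number == number and res.icode == icode:
                return i
        raise SiteMissingError(f"residue {number}{icode} not in chain {self.chain_id}")

    def sequence(self) -> str:
        return "".join(res.aa for res in self.residues)


@dataclass
class StructureMetadata:
    """Crystallographic metadata; ``None`` marks a genuinely absent value."""

    resolution: Optional[float] = None
    crystal_temperature: Optional[float] = None
    crystal_ph: Optional[float] = None

    def effective(self) -> Tuple[Tuple[float, bool], Tuple[float, bool], Tuple[float, bool]]:
        """(value, imputed) triples for resolution, temperature, pH.

        Missing fields fall back to 2.5 A / 298 K / pH 7.0 with the imputed
        flag raised, so prediction never fails on a minimal PDB file.
        """
        return (
            (self.resolution if self.resolution is not None else DEFAULT_RESOLUTION_A,
             self.resolution is None),
            (self.crystal_temperature if self.crystal_temperature is not None
             else DEFAULT_TEMPERATURE_K, self.crystal_temperature is None),
            (self.crystal_ph if self.crystal_ph is not None else DEFAULT_PH,
             self.crystal_ph is None),
        )


@dataclass
class ComplexStructure:
    """A parsed multi-chain complex.

    ``missing_residues`` holds (chain_id, residue_number) pairs declared
    unobserved in REMARK 465.
    """

    complex_id: str
    chains: List[Chain]
    metadata: StructureMetadata
    missing_residues: Set[Tuple[str, int]] = field(default_factory=set)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise SiteMissingError(f"no chain {chain_id!r} in {self.complex_id}")

    def site(self, mut: MutationSpec) -> Residue:
        """Resolve and validate the mutation site against the structure."""
        ch = self.chain(mut.chain_id)
        res = ch.residues[ch.index_of(mut.residue_number, mut.icode)]
        if res.aa != mut.wt_aa:
            raise MutationMismatchError(
                f"structure has {res.aa} at {mut.chain_id}:{mut.residue_number}"
                f"{mut.icode}, mutation says {mut.wt_aa}")
        return res


_RE_RESOLUTION = re.compile(r"REMARK   2 RESOLUTION\.\s+(\d+(?:\.\d+)?)\s+ANGSTROM")
_RE_TEMPERATURE = re.compile(r"REMARK 200.*TEMPERATURE\s+\(KELVIN\)\s*:\s*(\d+(?:\.\d+)?)")
_RE_PH = re.compile(r"REMARK 280.*\bPH\s*:?\s*(\d+(?:\.\d+)?)")
_RE_MISSING = re.compile(r"REMARK 465\s+(?:\d+\s+)?([A-Z]{3})\s+(\S)\s+(-?\d+)\s*$")


def _parse_remarks(remarks: Sequence[str]) -> Tuple[StructureMetadata, Set[Tuple[str, int]]]:
    meta = StructureMetadata()
    missing: Set[Tuple[str, int]] = set()
    for line in remarks:
        if meta.resolution is None:
            m = _RE_RESOLUTION.search(line)
            if m:
                meta.resolution = float(m.group(1))
                continue
        if meta.crystal_temperature is None:
            m = _RE_TEMPERATURE.search(line)
            if m:
                meta.crystal_temperature = float(m.group(1))
                continue
        if meta.crystal_ph is None:
            m = _RE_PH.search(line)
            if m:
                ph = float(m.group(1))
                if 0.0 <= ph <= 14.0:
                    meta.crystal_ph = ph
                continue
        if line.startswith("REMARK 465"):
            m = _RE_MISSING.search(line)
            if m and m.group(1) in THREE_TO_ONE or (m and m.group(1) == "MSE"):
                missing.add((m.group(2), int(m.group(3))))
    return meta, missing


def _one_letter(resname: str) -> Optional[str]:
    """Map a residue name to its standard one-letter code, or None.

    Modified residues (MSE etc.) resolve to their parent standard residue via
    gemmi's chemical-component table.
    """
    if resname in THREE_TO_ONE:
        return THREE_TO_ONE[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code in AMINO_ACIDS else None


def parse_pdb(path: Path | str, complex_id: Optional[str] = None) -> ComplexStructure:
    """Parse a PDB file into a :class:`ComplexStructure`.

    Keeps heavy atoms of standard (or standard-mappable) amino-acid residues
    only; waters and other HETATM ligands are dropped. For alternate
    conformations the highest-occupancy atom wins. Requires at least two
    chains carrying at least one usable residue each.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"no coordinate model found in {path}")

    metadata, missing = _parse_remarks(st.raw_remarks)
    if metadata.resolution is None and st.resolution > 0:
        metadata.resolution = round(float(st.resolution), 3)

    chains: List[Chain] = []
    model = st[0]
    for gch in model:
        residues: List[Residue] = []
        for gres in gch:
            aa = _one_letter(gres.name)
            if aa is None:
                continue
            atoms: Dict[str, np.ndarray] = {}
            best_occ: Dict[str, float] = {}
            for atom in gres:
                if atom.element.is_hydrogen:
                    continue
                if atom.name in atoms and atom.occ <= best_occ[atom.name]:
                    continue
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                best_occ[atom.name] = atom.occ
            if not atoms:
                continue
            residues.append(Residue(gres.seqid.num, (gres.seqid.icode or " ").strip(),
                                    aa, atoms))
        if residues:
            residues.sort(key=lambda r: (r.number, r.icode))
            chains.append(Chain(gch.name, residues))

    if len(chains) < 2:
        raise StructureError(
            f"{path.name}: a complex needs >= 2 amino-acid chains, found {len(chains)}")
    return ComplexStructure(complex_id or path.stem, chains, metadata, missing)


def write_pdb(struct: ComplexStructure, path: Path | str | None = None) -> str:
    """Serialize a structure back to PDB text (REMARK metadata included)."""
    st = gemmi.Structure()
    st.name = struct.complex_id
    model = gemmi.Model("1")
    for ch in struct.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = ONE_TO_THREE[res.aa]
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[:1])
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()

    remarks = []
    md = struct.metadata
    if md.resolution is not None:
        remarks.append(f"REMARK   2 RESOLUTION.    {md.resolution:.2f} ANGSTROMS.")
    if md.crystal_temperature is not None:
        remarks.append("REMARK 200  TEMPERATURE           (KELVIN) : "
                       f"{md.crystal_temperature:g}")
    if md.crystal_ph is not None:
        remarks.append(f"REMARK 280  CRYSTALLIZATION CONDITIONS: PH {md.crystal_ph:.2f}")
    for chain_id, number in sorted(struct.missing_residues):
        remarks.append(f"REMARK 465     ALA {chain_id} {number:5d}")
    text = "\n".join(remarks) + ("\n" if remarks else "") + st.make_pdb_string()
    if path is not None:
        Path(path).write_text(text)
    return text


def _expanded_slots(chain: Chain) -> Tuple[List[Optional[Residue]], int]:
    """Chain residues expanded with ``None`` slots at interior numbering gaps.

    Returns (slots, site-index offset helper is not needed; slots only).
    Residues sharing a number through insertion codes occupy adjacent slots
    without implied gaps.
    """
    slots: List[Optional[Residue]] = []
    prev: Optional[Residue] = None
    for res in chain.residues:
        if prev is not None and not res.icode and not prev.icode:
            skipped = res.number - prev.number - 1
            if skipped > 0:
                slots.extend([None] * skipped)
        slots.append(res)
        prev = res
    return slots, 0


def sequence_window(struct: ComplexStructure, mut: MutationSpec,
                    half_width: int = 5) -> List[str]:
    """One-letter codes of the ``2*half_width`` sequence neighbours of a site.

    Ordered left to right along the chain, excluding the mutation site
    itself. Slots past a chain terminus or at an interior numbering gap hold
    the :data:`GAP` sentinel.
    """
    struct.site(mut)
    chain = struct.chain(mut.chain_id)
    slots, _ = _expanded_slots(chain)
    site_idx = next(i for i, s in enumerate(slots)
                    if s is not None and s.number == mut.residue_number
                    and s.icode == mut.icode)
    window: List[str] = []
    for off in list(range(-half_width, 0)) + list(range(1, half_width + 1)):
        i = site_idx + off
        if 0 <= i < len(slots) and slots[i] is not None:
            window.append(slots[i].aa)
        else:
            window.append(GAP)
    return window


def has_local_gap(struct: ComplexStructure, mut: MutationSpec,
                  half_width: int = 5) -> bool:
    """True iff unobserved residues fall within +/- ``half_width`` of the site.

    Interior numbering gaps always count. Slots beyond the modelled terminus
    count only when the corresponding residue number is declared missing in
    REMARK 465 (i.e. the real chain extends there but was not resolved);
    a genuine chain terminus is not a missing residue.
    """
    struct.site(mut)
    chain = struct.chain(mut.chain_id)
    slots, _ = _expanded_slots(chain)
    site_idx = next(i for i, s in enumerate(slots)
                    if s is not None and s.number == mut.residue_number
                    and s.icode == mut.icode)
    first_num = chain.residues[0].number
    last_num = chain.residues[-1].number
    for off in list(range(-half_width, 0)) + list(range(1, half_width + 1)):
        i = site_idx + off
        if 0 <= i < len(slots):
            if slots[i] is None:
                return True
        else:
            overrun = i - (len(slots) - 1) if i >= len(slots) else i  # negative on left
            number = last_num + overrun if i >= len(slots) else first_num + overrun
            if (mut.chain_id, number) in struct.missing_residues:
                return True
    return False


def residue_min_distance(a: Residue, b: Residue) -> float:
    """Minimum heavy-atom to heavy-atom distance between two residues, A."""
    ca, cb = a.coords(), b.coords()
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    return float(d.min())


def interchain_neighbors(struct: ComplexStructure, mut: MutationSpec,
                         k: int = 10, cutoff: float = 10.0) -> List[str]:
    """One-letter codes of the k nearest cross-chain residues within cutoff.

    Candidates are residues on chains other than the mutated one whose
    minimum heavy-atom distance to the site residue is <= ``cutoff``; the
    result is sorted by ascending distance (ties broken by chain id then
    residue number) and padded with :data:`NONE_RESIDUE` to length k.
    """
    site = struct.site(mut)
    hits: List[Tuple[float, str, int, str, str]] = []
    for ch in struct.chains:
        if ch.chain_id == mut.chain_id:
            continue
        for res in ch.residues:
            d = residue_min_distance(site, res)
            if d <= cutoff:
                hits.append((d, ch.chain_id, res.number, res.icode, res.aa))
    hits.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    codes = [aa for _, _, _, _, aa in hits[:k]]
    return codes + [NONE_RESIDUE] * (k - len(codes))


def is_interface_residue(struct: ComplexStructure, mut: MutationSpec,
                         cutoff: float = 5.0) -> bool:
    """True iff any heavy atom of the site lies within ``cutoff`` of another chain."""
    site = struct.site(mut)
    for ch in struct.chains:
        if ch.chain_id == mut.chain_id:
            continue
        for res in ch.residues:
            if residue_min_distance(site, res) <= cutoff and cutoff > 0:
                return True
    return False
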