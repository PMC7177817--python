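"""Programmatic generation of test complexes, affinity tables and labeled data.

Everything the package consumes from the outside world -- multi-chain PDB
files with REMARK metadata, SKEMPI-dialect affinity tables, batch mutation
lists, labeled feature matrices -- can be generated here with a seed, so the
whole package builds and tests without downloading a single file.

Fixture complexes are idealized: residues sit on an extended backbone with
fixed spacing, each residue carrying N/CA/C/O plus one side-chain
pseudo-atom, and chains are placed far apart unless a contact is requested.
Requested inter-chain contacts are realized as minimum heavy-atom distances
to within 0.01 A. Companion ground-truth tables (all-pairs minimum
distances, expected curation outcomes) are computed here with plain
arithmetic, independent of the modules they exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .curation import R_KCAL
from .featurizer import FEATURE_SCHEMA

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CA_SPACING = 3.8          # A between consecutive CA atoms along a chain
CHAIN_SEPARATION = 60.0   # A between chain baselines unless a contact is planted

# side-chain pseudo-atom length per residue (A from CA, roughly size-ordered)
_SIDECHAIN_LEN = {aa: 1.0 + 0.01 * i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class Contact:
    """Request: place (chain, residue) at ``distance`` A (min heavy-atom)
    from (target_chain, target_residue)."""

    chain: str
    residue: int
    target_chain: str
    target_residue: int
    distance: float


@dataclass
class FixtureSpec:
    """Recipe for one synthetic complex."""

    n_chains: int = 2
    residues_per_chain: int = 12
    sequences: Optional[List[str]] = None   # one per chain; random if None
    contacts: List[Contact] = field(default_factory=list)
    resolution: Optional[float] = 1.8
    temperature: Optional[float] = 298.0
    ph: Optional[float] = 7.0
    missing_residues: List[Tuple[str, int]] = field(default_factory=list)
    declare_missing: bool = True    # list omitted residues in REMARK 465
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.contacts:
            if c.distance < 1.0:
                raise ValueError("requested contact distances must be >= 1.0 A")


def _chain_ids(n: int) -> List[str]:
    return [chr(ord("A") + i) for i in range(n)]


def _residue_atoms(aa: str, ca: np.ndarray, updir: np.ndarray) -> Dict[str, np.ndarray]:
    """Idealized heavy atoms of one residue around its CA position."""
    atoms = {
        "N": ca + np.array([-1.45, 0.0, 0.0]),
        "CA": ca.copy(),
        "C": ca + np.array([1.52, 0.0, 0.0]),
        "O": ca + np.array([1.95, 1.05, 0.0]),
    }
    if aa != "G":
        atoms["CB"] = ca + _SIDECHAIN_LEN[aa] * updir
    return atoms


@dataclass
class SyntheticComplex:
    """A generated complex: PDB text plus independent ground truth."""

    pdb_text: str
    sequences: Dict[str, str]
    atoms: Dict[Tuple[str, int], Dict[str, np.ndarray]]   # (chain, resnum) -> atoms
    distance_table: pd.DataFrame   # all inter-residue minimum distances


def _min_dist(a: Dict[str, np.ndarray], b: Dict[str, np.ndarray]) -> float:
    pa = np.array(list(a.values()))
    pb = np.array(list(b.values()))
    return float(np.linalg.norm(pa[:, None] - pb[None, :], axis=-1).min())


def make_complex(spec: FixtureSpec) -> SyntheticComplex:
    """Generate a complex per spec; deterministic in the seed.

    Chains run along x, stacked ``CHAIN_SEPARATION`` apart in z. A contact
    request translates the whole requested residue toward its target until
    the minimum heavy-atom distance matches to within 0.01 A. Residues
    listed in ``missing_residues`` are omitted from the coordinates (and
    declared in REMARK 465 when ``declare_missing``), producing numbering
    gaps.
    """
    rng = np.random.default_rng(spec.seed)
    chain_ids = _chain_ids(spec.n_chains)
    if spec.sequences is None:
        sequences = {cid: "".join(rng.choice(list(AMINO_ACIDS), spec.residues_per_chain))
                     for cid in chain_ids}
    else:
        if len(spec.sequences) != spec.n_chains:
            raise ValueError("need one sequence per chain")
        sequences = dict(zip(chain_ids, spec.sequences))

    atoms: Dict[Tuple[str, int], Dict[str, np.ndarray]] = {}
    for ci, cid in enumerate(chain_ids):
        z = ci * CHAIN_SEPARATION
        updir = np.array([0.0, 1.0, 0.0])
        for ri, aa in enumerate(sequences[cid]):
            resnum = ri + 1
            ca = np.array([ri * CA_SPACING, 0.0, z])
            atoms[(cid, resnum)] = _residue_atoms(aa, ca, updir)

    # realize requested contacts by translating the planted residue
    for c in spec.contacts:
        key, tkey = (c.chain, c.residue), (c.target_chain, c.target_residue)
        if key not in atoms or tkey not in atoms:
            raise ValueError(f"contact references missing residue: {c}")
        planted, target = atoms[key], atoms[tkey]
        t_center = np.mean(list(target.values()), axis=0)
        # start just "above" the target in y
        offset = t_center + np.array([0.0, c.distance + 3.0, 0.0]) \
            - np.mean(list(planted.values()), axis=0)
        planted = {n: p + offset for n, p in planted.items()}
        for _ in range(50):
            d = _min_dist(planted, target)
            if abs(d - c.distance) < 0.005:
                break
            pa = np.array(list(planted.values()))
            pb = np.array(list(target.values()))
            dm = np.linalg.norm(pa[:, None] - pb[None, :], axis=-1)
            i, j = np.unravel_index(dm.argmin(), dm.shape)
            direction = (pa[i] - pb[j]) / dm[i, j]
            planted = {n: p + (c.distance - d) * direction for n, p in planted.items()}
        else:  # pragma: no cover
            raise ValueError(f"could not realize contact {c}")
        atoms[key] = planted

    missing = set(spec.missing_residues)
    for key in missing:
        if key not in atoms:
            raise ValueError(f"cannot remove non-existent residue {key}")
        del atoms[key]

    # ground-truth all-pairs minimum distances (inter-chain pairs)
    rows = []
    keys = sorted(atoms)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            if ka[0] == kb[0]:
                continue
            rows.append({"chain_i": ka[0], "res_i": ka[1],
                         "chain_j": kb[0], "res_j": kb[1],
                         "aa_i": sequences[ka[0]][ka[1] - 1],
                         "aa_j": sequences[kb[0]][kb[1] - 1],
                         "min_dist": _min_dist(atoms[ka], atoms[kb])})
    distance_table = pd.DataFrame(rows)

    pdb_text = _render_pdb(spec, sequences, atoms, sorted(missing))
    return SyntheticComplex(pdb_text, sequences, atoms, distance_table)


def _render_pdb(spec: FixtureSpec, sequences: Dict[str, str],
                atoms: Dict[Tuple[str, int], Dict[str, np.ndarray]],
                missing: List[Tuple[str, int]]) -> str:
    lines: List[str] = []
    if spec.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {spec.resolution:.2f} ANGSTROMS.")
    if spec.temperature is not None:
        lines.append("REMARK 200  TEMPERATURE           (KELVIN) : "
                     f"{spec.temperature:g}")
    if spec.ph is not None:
        lines.append(f"REMARK 280  CRYSTALLIZATION CONDITIONS: PH {spec.ph:.2f}")
    if missing and spec.declare_missing:
        lines.append("REMARK 465   M RES C SSSEQI")
        for cid, resnum in missing:
            aa = sequences[cid][resnum - 1]
            lines.append(f"REMARK 465     {ONE_TO_THREE[aa]} {cid} {resnum:5d}")
    serial = 1
    for cid in sorted(sequences):
        for resnum in range(1, len(sequences[cid]) + 1):
            key = (cid, resnum)
            if key not in atoms:
                continue
            aa = sequences[cid][resnum - 1]
            res3 = ONE_TO_THREE[aa]
            for name, xyz in atoms[key].items():
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s}{res3:>4s} {cid}{resnum:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {name[0]:>2s}")
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# affinity tables


@dataclass
class SyntheticAffinityTable:
    """SKEMPI-dialect CSV text plus the expected curation outcome."""

    csv_text: str
    pdb_texts: Dict[str, str]              # complex_id -> PDB text
    expected: pd.DataFrame                 # one row per surviving mutation
    expected_stage_counts: List[int]       # [input, single, after-sd, after-gap]


def make_affinity_table(n: int = 6, duplicates: float = 0.2,
                        sd_profile: Sequence[float] = (0.28, 1.41),
                        seed: int = 0, n_gap_records: int = 0,
                        temperature: float = 298.0) -> SyntheticAffinityTable:
    """Generate an affinity table with controlled curation outcomes.

    ``n`` base single mutations are drawn on synthetic complexes. A
    ``duplicates`` fraction of them (at least one per entry of
    ``sd_profile`` when positive) get a second measurement whose ddG offset
    realizes the requested sample standard deviation -- values straddling
    the 1.0 kcal/mol cutoff exercise both keep and drop branches.
    ``n_gap_records`` mutations are placed next to an interior numbering gap
    so the structure filter removes them. The companion ``expected`` table
    states, from arithmetic alone, which mutations survive and with what
    mean ddG.
    """
    if n < 1:
        raise ValueError("need n >= 1 records")
    rng = np.random.default_rng(seed)

    # one gap-free complex and (if needed) one with an interior gap at 7
    plain = make_complex(FixtureSpec(
        n_chains=2, residues_per_chain=12,
        sequences=["ACDEFGHIKLMN", "QRSTVWYACDEF"],
        contacts=[Contact("B", 3, "A", 6, 4.0)], seed=seed))
    pdb_texts = {"CPX1": plain.pdb_text}
    gappy = None
    if n_gap_records > 0:
        gappy = make_complex(FixtureSpec(
            n_chains=2, residues_per_chain=12,
            sequences=["ACDEFGHIKLMN", "QRSTVWYACDEF"],
            contacts=[Contact("B", 3, "A", 6, 4.0)],
            missing_residues=[("A", 7)], seed=seed + 1))
        pdb_texts["CPX2"] = gappy.pdb_text

    n_dup = max(1, round(n * duplicates)) if duplicates > 0 and sd_profile else 0
    n_dup = min(n_dup, n, len(sd_profile)) if n_dup else 0

    seq_a = "ACDEFGHIKLMN"
    sites = [i for i in range(1, 13) if i != 7]  # usable residue numbers on chain A
    rows: List[Dict] = []
    expected_rows: List[Dict] = []
    kd_wt = 1e-9
    n_input = 0

    def kd_mut_for(ddg: float) -> float:
        return kd_wt * math.exp(ddg / (R_KCAL * temperature))

    for i in range(n):
        use_gap = i >= n - n_gap_records
        complex_id = "CPX2" if use_gap else "CPX1"
        pos = 6 if use_gap else sites[i % len(sites)]
        wt = seq_a[pos - 1]
        mut = rng.choice([a for a in AMINO_ACIDS if a != wt])
        base_ddg = float(np.round(rng.uniform(-2.0, 3.0), 2))
        mut_str = f"{wt}A{pos}{mut}"
        rows.append({"#Pdb": f"{complex_id}_A_B", "Mutation(s)_cleaned": mut_str,
                     "Affinity_wt_parsed": kd_wt,
                     "Affinity_mut_parsed": kd_mut_for(base_ddg),
                     "Temperature": temperature, "Method": "SPR"})
        n_input += 1
        survives = not use_gap
        mean_ddg = base_ddg
        kept_after_sd = True
        if i < n_dup:
            # second measurement at base + sd*sqrt(2) gives sample SD = sd_profile[i]
            offset = sd_profile[i] * math.sqrt(2.0)
            rows.append({"#Pdb": f"{complex_id}_A_B", "Mutation(s)_cleaned": mut_str,
                         "Affinity_wt_parsed": kd_wt,
                         "Affinity_mut_parsed": kd_mut_for(base_ddg + offset),
                         "Temperature": temperature, "Method": "ITC"})
            n_input += 1
            kept_after_sd = sd_profile[i] < 1.0
            survives = survives and kept_after_sd
            mean_ddg = base_ddg + offset / 2.0
        expected_rows.append({
            "complex_id": complex_id, "chain": "A", "pos": pos,
            "wt": wt, "mut": mut,
            "n_measurements": 2 if i < n_dup else 1,
            "kept_after_sd": kept_after_sd,
            "survives": survives,
            "expected_ddg": mean_ddg if survives else np.nan,
        })

    csv_text = pd.DataFrame(rows).to_csv(sep=";", index=False)
    expected = pd.DataFrame(expected_rows)
    n_single = n_input  # every generated record is a single mutation
    n_after_sd = int(expected["kept_after_sd"].sum())
    n_after_gap = int(expected["survives"].sum())
    return SyntheticAffinityTable(csv_text, pdb_texts, expected,
                                  [n_input, n_single, n_after_sd, n_after_gap])


def make_mutation_list(muts: Sequence[Tuple[str, int, str, str]]) -> str:
    """Render a batch mutation list (``chain pos wt mut`` per line)."""
    return "\n".join(f"{c} {p} {w} {m}" for c, p, w, m in muts) + "\n"


# ---------------------------------------------------------------------------
# labeled datasets for model testing


@dataclass
class SyntheticLabelSpec:
    """Generative model for targets over named features.

    Exactly one of the two branches applies: linear regression targets
    (``weights`` over named numeric features plus Gaussian noise of standard
    deviation ``noise_sd``) or a binary rule (label 1 iff ``planted_feature``
    exceeds ``threshold``, flipped with probability ``flip_probability``).
    """

    weights: Optional[Dict[str, float]] = None
    noise_sd: float = 0.0
    planted_feature: Optional[str] = None
    threshold: float = 0.0
    flip_probability: float = 0.0

    def __post_init__(self) -> None:
        if (self.weights is None) == (self.planted_feature is None):
            raise ValueError("specify exactly one of weights / planted_feature")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.flip_probability < 0.5:
            raise ValueError("flip_probability must lie in [0, 0.5)")


_NUMERIC_RANGES = {
    "crystal_temperature": (95.0, 320.0),
    "crystal_ph": (4.0, 9.0),
    "resolution": (1.0, 3.5),
    "net_volume": (-170.0, 170.0),
    "net_hydrophobicity": (-4.2, 4.2),
    "net_flexibility": (-33.0, 33.0),
}
_LABEL_SPACES = {
    "mutation_type": 380, "wt_chemical_class": 7, "mut_chemical_class": 7,
    "size_pair": 9, "polarity_pair": 4, "hbond_pair": 16, "hydropathy_pair": 9,
}


def make_feature_matrix(n: int, seed: int = 0,
                        schema: Sequence[str] = tuple(FEATURE_SCHEMA)) -> pd.DataFrame:
    """Random feature matrix over the standard schema's value ranges.

    Continuous features draw uniformly from plausible physical ranges;
    label-encoded features draw uniform integers from their label space
    (residue-slot features include the sentinel value 20).
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for name in schema:
        if name in _NUMERIC_RANGES:
            lo, hi = _NUMERIC_RANGES[name]
            cols[name] = rng.uniform(lo, hi, n)
        elif name in _LABEL_SPACES:
            cols[name] = rng.integers(0, _LABEL_SPACES[name], n).astype(float)
        else:  # sequence-window / neighbour residue slots, sentinel included
            cols[name] = rng.integers(0, 21, n).astype(float)
    return pd.DataFrame(cols)


def make_labeled_dataset(features: pd.DataFrame, spec: SyntheticLabelSpec,
                         seed: int = 0) -> Tuple[np.ndarray, Dict]:
    """Targets for a feature matrix under a known generative model.

    Linear branch: y = sum_f w_f * z_f + N(0, noise_sd^2) with z_f the
    column standardized over this matrix (so stated weights are per standard
    deviation of signal). Binary branch: y = [x_planted > threshold], each
    label flipped independently with ``flip_probability``. Returns the
    targets and the exact ground-truth parameters for recovery checks.
    """
    rng = np.random.default_rng(seed)
    if spec.weights is not None:
        y = np.zeros(len(features))
        for name, w in spec.weights.items():
            if name not in features.columns:
                raise KeyError(f"unknown feature {name!r}")
            col = features[name].to_numpy(dtype=float)
            sd = col.std()
            z = (col - col.mean()) / (sd if sd > 0 else 1.0)
            y += w * z
        noise = rng.normal(0.0, spec.noise_sd, len(features)) if spec.noise_sd > 0 \
            else np.zeros(len(features))
        y = y + noise
        truth = {"weights": dict(spec.weights), "noise_sd": spec.noise_sd,
                 "noise": noise}
        return y, truth
    if spec.planted_feature not in features.columns:
        raise KeyError(f"unknown feature {spec.planted_feature!r}")
    clean = (features[spec.planted_feature].to_numpy(dtype=float)
             > spec.threshold).astype(int)
    flips = rng.random(len(features)) < spec.flip_probability
    y = np.where(flips, 1 - clean, clean)
    truth = {"planted_feature": spec.planted_feature, "threshold": spec.threshold,
             "flip_probability": spec.flip_probability, "clean_labels": clean,
             "flips": flips}
    return y, truth
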