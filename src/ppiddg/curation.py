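"""Dataset curation: from an affinity table to a training-ready ddG dataset.

The pipeline mirrors how binding-affinity databases in the SKEMPI v2.0
tradition are purged before model training:

1. keep single point mutations only;
2. convert wild-type/mutant dissociation constants to a binding free energy
   change, ddG = R*T*(ln Kd_mut - ln Kd_wt) in kcal/mol (positive =
   destabilizing), group replicate measurements of the same mutation and
   keep the group mean when the sample standard deviation is below
   1.0 kcal/mol, dropping the whole group otherwise;
3. drop mutations whose sequence neighbourhood (five residues either side)
   contains unobserved residues in the structure.

A curated dataset can additionally be augmented with hypothetical reverse
mutations (mutant -> wild type, ddG negated), which balances the sign
distribution at the cost of mirroring, not adding, experimental information.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .structure_io import ComplexStructure, MutationSpec, has_local_gap

R_KCAL = 0.0019872
"""Gas constant, kcal/(mol K)."""


class CurationError(ValueError):
    pass


@dataclass
class CurationConfig:
    """Constants of the curation pipeline."""

    gas_constant: float = R_KCAL
    default_temperature: float = 298.0
    sd_cutoff: float = 1.0          # kcal/mol, replicate-group filter
    window_half_width: int = 5      # residues, local-gap filter

    def __post_init__(self) -> None:
        if min(self.gas_constant, self.default_temperature,
               self.sd_cutoff, self.window_half_width) <= 0:
            raise ValueError("curation constants must be positive")


@dataclass
class AffinityRecord:
    """One experimental affinity measurement for a mutant complex."""

    pdb_id: str
    mutations: List[MutationSpec]
    affinity_wt: float     # Kd, molar
    affinity_mut: float    # Kd, molar
    method: str = ""
    temperature: Optional[float] = None

    def is_single(self) -> bool:
        return len(self.mutations) == 1


@dataclass
class CuratedRecord:
    complex_id: str
    mutation: MutationSpec
    ddg: float                     # kcal/mol
    n_measurements: int = 1
    sd_measurements: float = 0.0
    is_reverse: bool = False


@dataclass
class CuratedDataset:
    records: List[CuratedRecord]
    has_reverse: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def ddgs(self) -> np.ndarray:
        return np.array([r.ddg for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "complex_id": r.complex_id,
            "chain": r.mutation.chain_id,
            "pos": r.mutation.residue_number,
            "icode": r.mutation.icode,
            "wt": r.mutation.wt_aa,
            "mut": r.mutation.mut_aa,
            "ddg": r.ddg,
            "n": r.n_measurements,
            "sd": r.sd_measurements,
            "is_reverse": r.is_reverse,
        } for r in self.records]
        return pd.DataFrame(rows)

    def to_tsv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Path | str) -> "CuratedDataset":
        df = pd.read_csv(path, sep="\t", keep_default_na=False,
                         dtype={"icode": str})
        records = [
            CuratedRecord(
                row.complex_id,
                MutationSpec(row.chain, int(row.pos), row.wt, row.mut,
                             str(row.icode).strip()),
                float(row.ddg), int(row.n), float(row.sd), bool(row.is_reverse))
            for row in df.itertuples()
        ]
        return cls(records, has_reverse=any(r.is_reverse for r in records))


@dataclass
class CurationLog:
    """Stage-by-stage survivor counts and per-record drop reasons."""

    n_input: int = 0
    n_single: int = 0
    n_after_sd: int = 0
    n_after_gap: int = 0
    dropped: List[Tuple[str, str]] = field(default_factory=list)  # (key, reason)

    def stage_counts(self) -> List[int]:
        return [self.n_input, self.n_single, self.n_after_sd, self.n_after_gap]


def ddg_from_affinities(rec: AffinityRecord, cfg: CurationConfig = CurationConfig()) -> float:
    """Binding free energy change of a mutation from Kd values, kcal/mol.

    ddG = dG_mut - dG_wt with dG = R*T*ln(Kd); temperature comes from the
    record when present, otherwise the configured default (298 K). Positive
    values mean weakened binding (destabilizing).
    """
    if rec.affinity_wt <= 0 or rec.affinity_mut <= 0:
        raise CurationError(f"nonpositive Kd in record for {rec.pdb_id}")
    temp = rec.temperature if rec.temperature is not None else cfg.default_temperature
    return cfg.gas_constant * temp * (math.log(rec.affinity_mut) - math.log(rec.affinity_wt))


def _group_key(rec: AffinityRecord) -> Tuple[str, str, int, str, str, str]:
    m = rec.mutations[0]
    return (rec.pdb_id, m.chain_id, m.residue_number, m.icode, m.wt_aa, m.mut_aa)


StructureAccessor = Callable[[str], ComplexStructure]


def curate(records: Sequence[AffinityRecord],
           structures: Optional[StructureAccessor],
           cfg: CurationConfig = CurationConfig()) -> Tuple[CuratedDataset, CurationLog]:
    """Run the three-stage curation pipeline.

    ``structures`` maps a pdb_id to its parsed structure for the local-gap
    filter; pass ``None`` to skip stage 3 (e.g. when structures are not
    resolvable, every structure-less record is dropped with a logged reason
    only if an accessor was supplied and failed).
    """
    log = CurationLog(n_input=len(records))

    singles = [r for r in records if r.is_single()]
    log.n_single = len(singles)
    for r in records:
        if not r.is_single():
            log.dropped.append((r.pdb_id, "multiple mutations"))

    # replicate grouping on ddG
    groups: Dict[Tuple, List[AffinityRecord]] = {}
    for r in singles:
        groups.setdefault(_group_key(r), []).append(r)

    merged: List[CuratedRecord] = []
    for key, grp in groups.items():
        ddgs = np.array([ddg_from_affinities(r, cfg) for r in grp])
        sd = float(np.std(ddgs, ddof=1)) if len(ddgs) > 1 else 0.0
        if len(ddgs) > 1 and sd >= cfg.sd_cutoff:
            log.dropped.append((str(key), f"replicate sd {sd:.3f} >= {cfg.sd_cutoff}"))
            continue
        merged.append(CuratedRecord(grp[0].pdb_id, grp[0].mutations[0],
                                    float(np.mean(ddgs)), len(ddgs), sd))
    log.n_after_sd = len(merged)

    final: List[CuratedRecord] = []
    for rec in merged:
        if structures is None:
            final.append(rec)
            continue
        try:
            struct = structures(rec.complex_id)
        except Exception as exc:  # unresolvable structure: drop, not fatal
            log.dropped.append((rec.complex_id, f"structure unresolvable: {exc}"))
            continue
        try:
            gap = has_local_gap(struct, rec.mutation,
                                half_width=cfg.window_half_width)
        except Exception as exc:
            log.dropped.append((f"{rec.complex_id} {rec.mutation}",
                                f"site not usable: {exc}"))
            continue
        if gap:
            log.dropped.append((f"{rec.complex_id} {rec.mutation}",
                                "missing residues near mutation site"))
        else:
            final.append(rec)
    log.n_after_gap = len(final)

    return CuratedDataset(final), log


def augment_reverse(ds: CuratedDataset) -> CuratedDataset:
    """Add the hypothetical reverse mutation of every record (ddG negated).

    By the state-function property of the binding free energy, the
    mutant -> wild-type substitution has exactly the negated ddG. The output
    is twice the input size; augmenting an already-augmented dataset is an
    error.
    """
    if ds.has_reverse or any(r.is_reverse for r in ds.records):
        raise CurationError("dataset already contains reverse mutations")
    out = list(ds.records)
    for r in ds.records:
        out.append(CuratedRecord(r.complex_id, r.mutation.reversed(), -r.ddg,
                                 r.n_measurements, r.sd_measurements,
                                 is_reverse=True))
    return CuratedDataset(out, has_reverse=True)


# ---------------------------------------------------------------------------
# readers / writers

_MUT_RE = re.compile(r"^([A-Z])([A-Za-z0-9])(\d+)([A-Z]?)([A-Z])$")


def parse_mutation_string(s: str) -> MutationSpec:
    """Parse a compact SKEMPI-style mutation string, e.g. ``RC182A``.

    Format: wild-type one-letter code, chain id, residue number, optional
    insertion code, mutant one-letter code.
    """
    m = _MUT_RE.match(s.strip())
    if not m:
        raise CurationError(f"cannot parse mutation string {s!r}")
    wt, chain, pos, icode, mut = m.groups()
    return MutationSpec(chain, int(pos), wt, mut, icode)


def read_skempi_csv(path_or_buf: Path | str | io.StringIO) -> List[AffinityRecord]:
    """Read a SKEMPI v2.0-style semicolon-separated affinity table.

    Requires the columns ``#Pdb`` (``PDBID_chains_chains``),
    ``Mutation(s)_cleaned`` (comma-separated compact mutation strings),
    ``Affinity_wt_parsed`` and ``Affinity_mut_parsed`` (Kd, molar);
    ``Temperature`` and ``Method`` are used when present, any further
    columns are ignored. Rows with non-numeric affinities are skipped.
    """
    df = pd.read_csv(path_or_buf, sep=";")
    required = ["#Pdb", "Mutation(s)_cleaned", "Affinity_wt_parsed", "Affinity_mut_parsed"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CurationError(f"affinity table lacks required columns {missing}")

    records: List[AffinityRecord] = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        kd_wt = pd.to_numeric(d["Affinity_wt_parsed"], errors="coerce")
        kd_mut = pd.to_numeric(d["Affinity_mut_parsed"], errors="coerce")
        if pd.isna(kd_wt) or pd.isna(kd_mut):
            continue
        pdb_id = str(d["#Pdb"]).split("_")[0]
        try:
            muts = [parse_mutation_string(tok)
                    for tok in str(d["Mutation(s)_cleaned"]).split(",")]
        except (CurationError, ValueError):
            continue
        temp = None
        if "Temperature" in d and pd.notna(d["Temperature"]):
            m = re.search(r"\d+(?:\.\d+)?", str(d["Temperature"]))
            if m:
                temp = float(m.group(0))
        records.append(AffinityRecord(pdb_id, muts, float(kd_wt), float(kd_mut),
                                      method=str(d.get("Method", "")),
                                      temperature=temp))
    return records


def read_mutation_list(path: Path | str) -> List[MutationSpec]:
    """Read a batch mutation list: whitespace-separated ``chain pos wt mut`` lines."""
    muts: List[MutationSpec] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise CurationError(f"line {lineno}: expected 'chain pos wt mut', got {raw!r}")
        chain, pos, wt, mut = parts
        muts.append(MutationSpec(chain, int(pos), wt.upper(), mut.upper()))
    return muts
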