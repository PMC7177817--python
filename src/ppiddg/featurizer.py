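"""Assembly of the 33-dimensional feature vector for one (structure, mutation).

The encoding is knowledge-based only: three crystallographic metadata values,
three signed descriptor deltas (volume, hydrophobicity, flexibility), seven
label-encoded categorical features describing the substitution (mutation
type, wild-type and mutant chemical class, and the size/polarity/
hydrogen-bond/hydropathy class pairs), ten sequence-neighbour residue labels
and ten nearest cross-chain residue labels.

Label encodings are canonical, not fitted: categories are ordered
alphabetically (amino acids by one-letter code, class names alphabetically),
so the integer a category maps to is reproducible across runs and machines
without storing any fit state. Sequence-window and neighbour slots share one
residue alphabet of 20 labels (0-19); the GAP / no-neighbour sentinels take
the first reserved value above it (20).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import descriptors as desc
from . import structure_io as sio
from .descriptors import AADescriptorTable, AMINO_ACIDS, DEFAULT_TABLE
from .structure_io import ComplexStructure, MutationSpec

SENTINEL_LABEL = 20
"""Shared integer label for GAP (sequence window) and NONE (neighbour list)."""

PAIR_SCHEMES = ("size", "polarity", "hbond", "hydropathy")


class EncodingError(KeyError):
    """An unknown category or scheme was presented for encoding."""


def _sorted_classes(scheme: str) -> List[str]:
    return sorted(desc.PARTITIONS[scheme])


# Canonical category orderings, built once at import.
_MUTATION_TYPES: List[Tuple[str, str]] = [
    (w, m) for w, m in product(AMINO_ACIDS, AMINO_ACIDS) if w != m
]
_MUTATION_TYPE_INDEX: Dict[Tuple[str, str], int] = {
    pair: i for i, pair in enumerate(_MUTATION_TYPES)
}


def label_space_size(scheme: str) -> int:
    """Number of integer labels a scheme can emit.

    ``mutation_type`` spans the 380 ordered amino-acid pairs; ``residue``
    spans 20 amino acids plus holds one sentinel above them; a pair scheme
    over c classes spans c*c labels; ``chemical`` as a single-residue scheme
    spans its 7 classes.
    """
    if scheme == "mutation_type":
        return len(_MUTATION_TYPES)
    if scheme == "residue":
        return len(AMINO_ACIDS)
    if scheme in desc.PARTITIONS:
        return len(desc.PARTITIONS[scheme])
    raise EncodingError(f"unknown scheme {scheme!r}")


def pair_label_space_size(scheme: str) -> int:
    """Number of (wild-type class, mutant class) pair labels for a scheme."""
    n = len(desc.PARTITIONS[scheme])
    return n * n


def encode_residue(aa: str) -> int:
    """Label of one residue code; GAP/NONE sentinels map to 20."""
    if aa in (sio.GAP, sio.NONE_RESIDUE):
        return SENTINEL_LABEL
    idx = AMINO_ACIDS.find(aa)
    if idx < 0:
        raise EncodingError(f"unknown residue code {aa!r}")
    return idx


def encode_class(scheme: str, aa: str) -> int:
    """Label of a single residue's class under a partition scheme."""
    classes = _sorted_classes(scheme)
    return classes.index(desc.class_of(aa, scheme))


def encode_pair(scheme: str, wt: str, mut: str) -> int:
    """Label of the ordered (wild type, mutant) category under a scheme.

    For ``mutation_type`` the category is the ordered amino-acid pair itself
    (wt != mut, 380 labels); for a partition scheme it is the ordered pair of
    class labels, indexed in the alphabetical product of the scheme's classes.
    """
    if scheme == "mutation_type":
        try:
            return _MUTATION_TYPE_INDEX[(wt, mut)]
        except KeyError:
            raise EncodingError(f"invalid mutation type {wt!r}->{mut!r}") from None
    if scheme not in desc.PARTITIONS:
        raise EncodingError(f"unknown scheme {scheme!r}")
    classes = _sorted_classes(scheme)
    i = classes.index(desc.class_of(wt, scheme))
    j = classes.index(desc.class_of(mut, scheme))
    return i * len(classes) + j


def feature_schema(half_width: int = 5, k_neighbors: int = 10) -> List[str]:
    """Ordered names of the feature vector entries (33 with defaults)."""
    names = [
        "crystal_temperature",
        "crystal_ph",
        "resolution",
        "net_volume",
        "net_hydrophobicity",
        "net_flexibility",
        "mutation_type",
        "wt_chemical_class",
        "mut_chemical_class",
        "size_pair",
        "polarity_pair",
        "hbond_pair",
        "hydropathy_pair",
    ]
    names += [f"seq_m{i}" for i in range(half_width, 0, -1)]
    names += [f"seq_p{i}" for i in range(1, half_width + 1)]
    names += [f"neighbor_{i:02d}" for i in range(1, k_neighbors + 1)]
    return names


FEATURE_SCHEMA: List[str] = feature_schema()
N_FEATURES: int = len(FEATURE_SCHEMA)


@dataclass
class FeatureVector:
    """The ordered numeric encoding of one (structure, mutation) pair."""

    values: np.ndarray
    schema: List[str] = field(default_factory=lambda: list(FEATURE_SCHEMA))
    provenance_flags: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schema),):
            raise ValueError(
                f"feature vector length {self.values.shape} does not match "
                f"schema length {len(self.schema)}")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.schema, self.values.tolist()))


def featurize(struct: ComplexStructure, mut: MutationSpec,
              tables: AADescriptorTable = DEFAULT_TABLE,
              half_width: int = 5, k_neighbors: int = 10) -> FeatureVector:
    """Build the feature vector for a validated mutation in a complex.

    Raises :class:`~ppiddg.structure_io.MutationMismatchError` when the
    wild-type code disagrees with the structure and
    :class:`~ppiddg.structure_io.SiteMissingError` when the site does not
    exist. Metadata absent from the PDB file is imputed (298 K, pH 7.0,
    2.5 A) and flagged in ``provenance_flags``.
    """
    struct.site(mut)  # validates chain/site/wt
    (resolution, res_imp), (temperature, t_imp), (ph, ph_imp) = \
        struct.metadata.effective()

    values: List[float] = [
        temperature,
        ph,
        resolution,
        desc.net_volume(mut.wt_aa, mut.mut_aa, tables),
        desc.net_hydrophobicity(mut.wt_aa, mut.mut_aa, tables),
        desc.net_flexibility(mut.wt_aa, mut.mut_aa, tables),
        float(encode_pair("mutation_type", mut.wt_aa, mut.mut_aa)),
        float(encode_class("chemical", mut.wt_aa)),
        float(encode_class("chemical", mut.mut_aa)),
        float(encode_pair("size", mut.wt_aa, mut.mut_aa)),
        float(encode_pair("polarity", mut.wt_aa, mut.mut_aa)),
        float(encode_pair("hbond", mut.wt_aa, mut.mut_aa)),
        float(encode_pair("hydropathy", mut.wt_aa, mut.mut_aa)),
    ]
    window = sio.sequence_window(struct, mut, half_width=half_width)
    values.extend(float(encode_residue(aa)) for aa in window)
    neighbors = sio.interchain_neighbors(struct, mut, k=k_neighbors)
    values.extend(float(encode_residue(aa)) for aa in neighbors)

    return FeatureVector(
        np.array(values, dtype=float),
        schema=feature_schema(half_width, k_neighbors),
        provenance_flags={
            "resolution_imputed": res_imp,
            "temperature_imputed": t_imp,
            "ph_imputed": ph_imp,
        },
    )


def featurize_batch(struct: ComplexStructure, muts: Sequence[MutationSpec],
                    tables: AADescriptorTable = DEFAULT_TABLE) -> "np.ndarray":
    """Stack feature vectors for several mutations of one complex (n, 33)."""
    return np.vstack([featurize(struct, m, tables).values for m in muts])
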