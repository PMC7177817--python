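"""Shared fixtures: small synthetic complexes parsed through the package."""

import pathlib

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ppiddg.structure_io import parse_pdb
from ppiddg.synthetic_fixtures import Contact, FixtureSpec, make_complex

SEQ_A = "ACDEFGHIKLMN"
SEQ_B = "QRSTVWYACDEF"


@pytest.fixture(scope="session")
def basic_spec():
    """Two 12-residue chains with chain-B Ser3 planted 3.0 A from A:Gly6."""
    return FixtureSpec(sequences=[SEQ_A, SEQ_B],
                       contacts=[Contact("B", 3, "A", 6, 3.0)],
                       resolution=1.8, temperature=298.0, ph=7.0, seed=11)


@pytest.fixture(scope="session")
def basic_complex(basic_spec):
    return make_complex(basic_spec)


@pytest.fixture(scope="session")
def basic_structure(basic_complex, tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "basic.pdb"
    path.write_text(basic_complex.pdb_text)
    return parse_pdb(path, complex_id="basic")


@pytest.fixture(scope="session")
def gapped_structure(tmp_path_factory):
    """Same sequences but residue A:7 unobserved (declared in REMARK 465)."""
    cx = make_complex(FixtureSpec(sequences=[SEQ_A, SEQ_B],
                                  contacts=[Contact("B", 3, "A", 6, 3.0)],
                                  missing_residues=[("A", 7)], seed=11))
    path = tmp_path_factory.mktemp("pdb") / "gapped.pdb"
    path.write_text(cx.pdb_text)
    return parse_pdb(path, complex_id="gapped")


def write_structure(tmp_path: pathlib.Path, spec: FixtureSpec, name="cpx"):
    cx = make_complex(spec)
    path = tmp_path / f"{name}.pdb"
    path.write_text(cx.pdb_text)
    return cx, parse_pdb(path, complex_id=name)
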