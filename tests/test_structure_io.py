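"""PDB parsing, metadata extraction and residue-geometry queries."""

import numpy as np
import pytest

from ppiddg.structure_io import (GAP, NONE_RESIDUE, MutationMismatchError,
                                 MutationSpec, SiteMissingError,
                                 StructureError, has_local_gap,
                                 interchain_neighbors, is_interface_residue,
                                 parse_pdb, sequence_window, write_pdb)
from ppiddg.synthetic_fixtures import Contact, FixtureSpec, make_complex

from conftest import SEQ_A, write_structure


def test_parse_reads_back_embedded_metadata(basic_structure):
    md = basic_structure.metadata
    assert md.resolution == pytest.approx(1.80)
    assert md.crystal_temperature == pytest.approx(298.0)
    assert md.crystal_ph == pytest.approx(7.0)


def test_absent_metadata_is_missing_not_zero(tmp_path):
    _, st = write_structure(tmp_path, FixtureSpec(
        sequences=[SEQ_A, "QRSTVWYACDEF"], resolution=None, temperature=None,
        ph=None, seed=1))
    assert st.metadata.crystal_temperature is None
    assert st.metadata.crystal_ph is None
    (res, res_imp), (temp, t_imp), (ph, ph_imp) = st.metadata.effective()
    assert (temp, ph) == (298.0, 7.0) and t_imp and ph_imp


def test_parse_counts_chains_and_residues(basic_structure):
    assert len(basic_structure.chains) == 2
    assert sum(len(c.residues) for c in basic_structure.chains) == 24
    assert basic_structure.chain("A").sequence() == SEQ_A


def test_single_chain_rejected(tmp_path):
    cx = make_complex(FixtureSpec(n_chains=2, sequences=[SEQ_A, "QRSTVWYACDEF"], seed=2))
    # strip chain B to force a single-chain file
    lines = [l for l in cx.pdb_text.splitlines() if " B" not in l[:22]]
    path = tmp_path / "single.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(StructureError):
        parse_pdb(path)


def test_wt_mismatch_and_missing_site_raise(basic_structure):
    with pytest.raises(MutationMismatchError):
        basic_structure.site(MutationSpec("A", 6, "A", "W"))  # site is G
    with pytest.raises(SiteMissingError):
        basic_structure.site(MutationSpec("A", 99, "G", "W"))


class TestSequenceWindow:
    def test_interior_site(self, basic_structure):
        window = sequence_window(basic_structure, MutationSpec("A", 6, "G", "W"))
        assert window == list("ACDEF") + list("HIKLM")

    def test_n_terminal_site_pads_with_gap(self, basic_structure):
        window = sequence_window(basic_structure, MutationSpec("A", 1, "A", "W"))
        assert window[:5] == [GAP] * 5
        assert window[5:] == list("CDEFG")

    def test_numbering_gap_yields_gap_slot(self, gapped_structure):
        window = sequence_window(gapped_structure, MutationSpec("A", 6, "G", "W"))
        assert window == list("ACDEF") + [GAP] + list("IKL")[:3] + ["M"]

    def test_window_reverses_with_chain(self, tmp_path):
        """Reversing residue order along the chain reverses the window."""
        fwd = make_complex(FixtureSpec(sequences=[SEQ_A, "QRSTVWYACDEF"], seed=3))
        rev = make_complex(FixtureSpec(sequences=[SEQ_A[::-1], "QRSTVWYACDEF"], seed=3))
        for cx, name in ((fwd, "fwd"), (rev, "rev")):
            (tmp_path / f"{name}.pdb").write_text(cx.pdb_text)
        st_f = parse_pdb(tmp_path / "fwd.pdb")
        st_r = parse_pdb(tmp_path / "rev.pdb")
        w_f = sequence_window(st_f, MutationSpec("A", 6, SEQ_A[5], "W"))
        w_r = sequence_window(st_r, MutationSpec("A", 7, SEQ_A[5], "W"))
        assert w_r == w_f[::-1]


class TestLocalGap:
    def test_contiguous_numbering_is_clean(self, basic_structure):
        assert not has_local_gap(basic_structure, MutationSpec("A", 6, "G", "W"))

    def test_interior_gap_detected(self, gapped_structure):
        assert has_local_gap(gapped_structure, MutationSpec("A", 6, "G", "W"))
        # 5 residues to the right of site 2 is the gap at 7
        assert has_local_gap(gapped_structure, MutationSpec("A", 2, "C", "W"))

    def test_terminus_is_not_a_gap(self, basic_structure):
        assert not has_local_gap(basic_structure, MutationSpec("A", 2, "C", "W"))

    def test_gap_outside_window_ignored(self, gapped_structure):
        # site 12 is 5+ residues from the gap at 7: slots are 7..11 exclusive of 7? no: 7..11 include nothing missing beyond 7
        assert not has_local_gap(gapped_structure, MutationSpec("A", 12, "N", "W"), half_width=4)

    def test_remark465_extends_past_terminus(self, tmp_path):
        # chain modelled from residue 3 onward; 1-2 declared unobserved
        cx = make_complex(FixtureSpec(
            sequences=[SEQ_A, "QRSTVWYACDEF"],
            missing_residues=[("A", 1), ("A", 2)], seed=4))
        path = tmp_path / "nterm.pdb"
        path.write_text(cx.pdb_text)
        st = parse_pdb(path)
        assert has_local_gap(st, MutationSpec("A", 4, "E", "W"))


class TestInterchainNeighbors:
    def test_planted_contact_is_first(self, basic_structure, basic_complex):
        codes = interchain_neighbors(basic_structure, MutationSpec("A", 6, "G", "W"))
        assert codes[0] == "S"  # B:3 in QRSTVWYACDEF
        assert codes.count(NONE_RESIDUE) == 9

    def test_no_contact_gives_all_padding(self, basic_structure):
        codes = interchain_neighbors(basic_structure, MutationSpec("A", 12, "N", "W"))
        assert codes == [NONE_RESIDUE] * 10

    def test_matches_bruteforce_on_ground_truth(self, basic_structure, basic_complex):
        truth = basic_complex.distance_table
        sub = truth[(truth.chain_i == "A") & (truth.res_i == 6) &
                    (truth.min_dist <= 10.0)].sort_values(
                        ["min_dist", "chain_j", "res_j"])
        expected = list(sub.aa_j)[:10]
        expected += [NONE_RESIDUE] * (10 - len(expected))
        got = interchain_neighbors(basic_structure, MutationSpec("A", 6, "G", "W"))
        assert got == expected

    def test_truncates_to_k_closest(self, tmp_path):
        contacts = [Contact("B", i, "A", 6, 3.0 + 0.5 * i) for i in range(1, 13)]
        cx, st = write_structure(tmp_path, FixtureSpec(
            residues_per_chain=12, sequences=[SEQ_A, "QRSTVWYACDEF"],
            contacts=contacts, seed=5), name="crowd")
        got = interchain_neighbors(st, MutationSpec("A", 6, "G", "W"), k=10)
        truth = cx.distance_table
        sub = truth[(truth.chain_i == "A") & (truth.res_i == 6) &
                    (truth.min_dist <= 10.0)].sort_values(
                        ["min_dist", "chain_j", "res_j"])
        assert got == list(sub.aa_j)[:10]
        assert NONE_RESIDUE not in got


class TestInterface:
    def test_contact_within_cutoff(self, basic_structure):
        assert is_interface_residue(basic_structure, MutationSpec("A", 6, "G", "W"))

    def test_distant_residue_not_interface(self, basic_structure):
        assert not is_interface_residue(basic_structure, MutationSpec("A", 12, "N", "W"))

    def test_zero_cutoff_never_matches(self, basic_structure):
        assert not is_interface_residue(basic_structure, MutationSpec("A", 6, "G", "W"),
                                        cutoff=0.0)


def test_parse_write_parse_roundtrip(basic_structure):
    text = write_pdb(basic_structure)
    import tempfile, pathlib
    with tempfile.TemporaryDirectory() as d:
        path = pathlib.Path(d) / "rt.pdb"
        path.write_text(text)
        st2 = parse_pdb(path)
    assert [c.chain_id for c in st2.chains] == [c.chain_id for c in basic_structure.chains]
    for c1, c2 in zip(basic_structure.chains, st2.chains):
        assert c1.sequence() == c2.sequence()
        for r1, r2 in zip(c1.residues, c2.residues):
            assert set(r1.atoms) == set(r2.atoms)
            for name in r1.atoms:
                assert np.allclose(r1.atoms[name], r2.atoms[name], atol=1.5e-3)
    assert st2.metadata.resolution == pytest.approx(basic_structure.metadata.resolution)


def test_altloc_keeps_highest_occupancy(tmp_path):
    pdb = (
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.30  0.00           C\n"
        "ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C\n"
        "ATOM      4  N   GLY B   1       0.000   0.000  60.000  1.00  0.00           N\n"
        "ATOM      5  CA  GLY B   1       1.000   0.000  60.000  1.00  0.00           C\n"
        "END\n")
    path = tmp_path / "altloc.pdb"
    path.write_text(pdb)
    st = parse_pdb(path)
    ca = st.chain("A").residues[0].atoms["CA"]
    assert ca[0] == pytest.approx(2.0)


def test_mse_maps_to_methionine(tmp_path):
    pdb = (
        "ATOM      1  CA  MSE A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  CA  GLY B   1       0.000   0.000  60.000  1.00  0.00           C\n"
        "END\n")
    path = tmp_path / "mse.pdb"
    path.write_text(pdb)
    st = parse_pdb(path)
    assert st.chain("A").sequence() == "MA"


def test_mutation_spec_validation():
    with pytest.raises(ValueError):
        MutationSpec("A", 1, "G", "G")
    with pytest.raises(ValueError):
        MutationSpec("A", 1, "X", "G")
    m = MutationSpec("A", 1, "G", "W")
    assert m.reversed() == MutationSpec("A", 1, "W", "G")
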