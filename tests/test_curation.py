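"""Affinity-to-ddG conversion and the three-stage curation pipeline."""

import io
import math

import numpy as np
import pytest

from ppiddg import curation as cur
from ppiddg.curation import (AffinityRecord, CurationConfig, CurationError,
                             CuratedDataset, CuratedRecord, augment_reverse,
                             curate, ddg_from_affinities,
                             parse_mutation_string, read_mutation_list,
                             read_skempi_csv)
from ppiddg.structure_io import MutationSpec, parse_pdb
from ppiddg.synthetic_fixtures import make_affinity_table


def rec(kd_wt, kd_mut, temp=298.0, pdb="CPX1", mut="GA6W"):
    return AffinityRecord(pdb, [parse_mutation_string(mut)], kd_wt, kd_mut,
                          temperature=temp)


class TestDdgConversion:
    def test_equal_affinities_give_zero(self):
        assert ddg_from_affinities(rec(1e-9, 1e-9)) == pytest.approx(0.0)

    def test_thousandfold_weakening(self):
        # Kd 1 nM -> 1 uM at 298 K: ddG = R*T*ln(1000) ~ +4.09 kcal/mol
        ddg = ddg_from_affinities(rec(1e-9, 1e-6))
        assert ddg == pytest.approx(0.0019872 * 298.0 * math.log(1000), rel=1e-12)
        assert ddg == pytest.approx(4.09, abs=0.01)

    def test_swap_negates(self):
        assert ddg_from_affinities(rec(1e-9, 3e-7)) == \
            pytest.approx(-ddg_from_affinities(rec(3e-7, 1e-9)))

    def test_record_temperature_used(self):
        warm = ddg_from_affinities(rec(1e-9, 1e-6, temp=310.0))
        cool = ddg_from_affinities(rec(1e-9, 1e-6, temp=298.0))
        assert warm / cool == pytest.approx(310.0 / 298.0)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(CurationError):
            ddg_from_affinities(rec(0.0, 1e-6))


def _structures_from(tab, tmp_path):
    structs = {}
    for cid, text in tab.pdb_texts.items():
        p = tmp_path / f"{cid}.pdb"
        p.write_text(text)
        structs[cid] = parse_pdb(p, complex_id=cid)
    return structs


class TestPipeline:
    def test_toy_table_stage_counts_match_expectation(self, tmp_path):
        """6 measurements of 5 mutations; the duplicate pair (sd 0.28) merges
        to its mean, giving 5 survivors."""
        tab = make_affinity_table(n=5, duplicates=0.2, sd_profile=(0.28,), seed=3)
        assert tab.expected_stage_counts == [6, 6, 5, 5]
        structs = _structures_from(tab, tmp_path)
        records = read_skempi_csv(io.StringIO(tab.csv_text))
        ds, log = curate(records, lambda cid: structs[cid])
        assert log.stage_counts() == tab.expected_stage_counts
        assert len(ds) == 5
        merged = [r for r in ds.records if r.n_measurements == 2]
        assert len(merged) == 1
        exp = tab.expected[tab.expected.n_measurements == 2].iloc[0]
        assert merged[0].ddg == pytest.approx(exp.expected_ddg, abs=1e-9)
        assert merged[0].sd_measurements == pytest.approx(0.28, abs=1e-9)

    def test_high_sd_group_dropped(self, tmp_path):
        tab = make_affinity_table(n=6, duplicates=0.35, sd_profile=(0.28, 1.41),
                                  seed=5)
        structs = _structures_from(tab, tmp_path)
        ds, log = curate(read_skempi_csv(io.StringIO(tab.csv_text)),
                         lambda cid: structs[cid])
        assert log.stage_counts() == tab.expected_stage_counts
        # the sd=1.41 group is gone entirely
        dropped = tab.expected[~tab.expected.kept_after_sd]
        assert len(dropped) == 1
        keys = {(r.complex_id, r.mutation.residue_number) for r in ds.records}
        assert (dropped.iloc[0].complex_id, dropped.iloc[0].pos) not in keys

    def test_local_gap_records_dropped(self, tmp_path):
        tab = make_affinity_table(n=6, duplicates=0.0, sd_profile=(),
                                  seed=7, n_gap_records=2)
        structs = _structures_from(tab, tmp_path)
        ds, log = curate(read_skempi_csv(io.StringIO(tab.csv_text)),
                         lambda cid: structs[cid])
        assert log.stage_counts() == tab.expected_stage_counts
        assert log.n_after_sd - log.n_after_gap == 2
        assert all(r.complex_id != "CPX2" for r in ds.records)

    def test_multi_mutation_records_filtered_first(self, tmp_path):
        tab = make_affinity_table(n=4, duplicates=0.0, sd_profile=(), seed=9)
        records = read_skempi_csv(io.StringIO(tab.csv_text))
        double = AffinityRecord("CPX1", [parse_mutation_string("GA6W"),
                                         parse_mutation_string("AA1C")],
                                1e-9, 1e-8)
        structs = _structures_from(tab, tmp_path)
        ds, log = curate(records + [double], lambda cid: structs[cid])
        assert log.n_input == log.n_single + 1
        assert len(ds) == 4

    def test_unresolvable_structure_drops_record_not_pipeline(self, tmp_path):
        tab = make_affinity_table(n=3, duplicates=0.0, sd_profile=(), seed=11)
        structs = _structures_from(tab, tmp_path)

        def accessor(cid):
            raise FileNotFoundError(cid)

        ds, log = curate(read_skempi_csv(io.StringIO(tab.csv_text)), accessor)
        assert len(ds) == 0
        assert any("unresolvable" in reason for _, reason in log.dropped)

    def test_stage_counts_monotone(self, tmp_path):
        tab = make_affinity_table(n=8, duplicates=0.3, sd_profile=(0.5, 1.6),
                                  seed=13, n_gap_records=1)
        structs = _structures_from(tab, tmp_path)
        _, log = curate(read_skempi_csv(io.StringIO(tab.csv_text)),
                        lambda cid: structs[cid])
        counts = log.stage_counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_curation_idempotent(self, tmp_path):
        """Re-curating records synthesized from a curated dataset changes nothing."""
        tab = make_affinity_table(n=6, duplicates=0.3, sd_profile=(0.4, 1.2),
                                  seed=15, n_gap_records=1)
        structs = _structures_from(tab, tmp_path)
        ds, _ = curate(read_skempi_csv(io.StringIO(tab.csv_text)),
                       lambda cid: structs[cid])
        cfg = CurationConfig()
        again = [
            AffinityRecord(r.complex_id, [r.mutation], 1e-9,
                           1e-9 * math.exp(r.ddg / (cfg.gas_constant * cfg.default_temperature)))
            for r in ds.records
        ]
        ds2, _ = curate(again, lambda cid: structs[cid])
        assert len(ds2) == len(ds)
        for a, b in zip(sorted(ds.records, key=lambda r: str(r.mutation)),
                        sorted(ds2.records, key=lambda r: str(r.mutation))):
            assert a.ddg == pytest.approx(b.ddg, abs=1e-9)


class TestReverseAugmentation:
    def _dataset(self):
        muts = [MutationSpec("A", i, "G", "W") for i in range(1, 6)]
        ddgs = [1.0, -0.5, 2.0, 0.25, -1.75]
        return CuratedDataset([CuratedRecord("CPX1", m, d)
                               for m, d in zip(muts, ddgs)])

    def test_doubles_and_symmetrizes(self):
        ds = augment_reverse(self._dataset())
        assert len(ds) == 10
        assert sum(r.ddg for r in ds.records) == pytest.approx(0.0)
        assert sum(1 for r in ds.records if r.ddg > 0) == \
            sum(1 for r in ds.records if r.ddg < 0)

    def test_reverse_records_flip_mutation(self):
        ds = augment_reverse(self._dataset())
        fwd = [r for r in ds.records if not r.is_reverse]
        rev = [r for r in ds.records if r.is_reverse]
        for f, r in zip(fwd, rev):
            assert r.mutation == f.mutation.reversed()
            assert r.ddg == -f.ddg

    def test_double_augmentation_rejected(self):
        ds = augment_reverse(self._dataset())
        with pytest.raises(CurationError):
            augment_reverse(ds)


class TestReadersWriters:
    def test_mutation_string_roundtrip(self):
        m = parse_mutation_string("RC182A")
        assert (m.wt_aa, m.chain_id, m.residue_number, m.mut_aa) == ("R", "C", 182, "A")
        with pytest.raises(CurationError):
            parse_mutation_string("garbage")

    def test_skempi_reader_skips_nonnumeric_affinities(self):
        csv = ("#Pdb;Mutation(s)_cleaned;Affinity_mut_parsed;Affinity_wt_parsed;"
               "Temperature;Method;Notes\n"
               "1ABC_A_B;GA6W;1e-6;1e-9;298;SPR;ok\n"
               "1ABC_A_B;AA1C;n.b.;1e-9;298;SPR;out of range\n")
        records = read_skempi_csv(io.StringIO(csv))
        assert len(records) == 1
        assert records[0].pdb_id == "1ABC"

    def test_missing_required_column_raises(self):
        with pytest.raises(CurationError):
            read_skempi_csv(io.StringIO("a;b\n1;2\n"))

    def test_tsv_roundtrip(self, tmp_path):
        ds = augment_reverse(TestReverseAugmentation()._dataset())
        path = tmp_path / "ds.tsv"
        ds.to_tsv(path)
        back = CuratedDataset.from_tsv(path)
        assert len(back) == len(ds)
        assert back.has_reverse
        assert [r.ddg for r in back.records] == pytest.approx(
            [r.ddg for r in ds.records])

    def test_mutation_list_reader(self, tmp_path):
        path = tmp_path / "List_Mutations.txt"
        path.write_text("A 6 G W\nB 3 S A   # comment\n\n")
        muts = read_mutation_list(path)
        assert muts == [MutationSpec("A", 6, "G", "W"), MutationSpec("B", 3, "S", "A")]
        path.write_text("A 6 G\n")
        with pytest.raises(CurationError):
            read_mutation_list(path)
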