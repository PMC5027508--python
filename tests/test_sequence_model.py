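"""Nomenclature, adenine position, coordinates and run-length parsing."""
from __future__ import annotations

import logging
from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csb2scan.sequence_model import (
    CoordinateError,
    CoordinateSystem,
    GTractVariant,
    NomenclatureError,
    SequenceRecord,
    TPEntry,
    TPTable,
    adenine_position,
    light_strand_name,
    parse_nomenclature,
    reverse_complement,
    reverse_complement_name,
    run_length_decode,
    run_length_encode,
    transcript_end_position,
    transcript_length_for_end,
)

PACKAGED_TP = Path(__file__).parent.parent / "src" / "csb2scan" / "data" / "tp_table.tsv"

variants = st.one_of(
    st.builds(
        GTractVariant,
        first_run=st.integers(1, 20),
        interrupt=st.sampled_from(["A", "C", "T"]),
        second_run=st.integers(1, 20),
    ),
    st.builds(GTractVariant, first_run=st.integers(1, 30)),
)


class TestNomenclature:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("G5AG7", GTractVariant(5, "A", 7)),
            ("G13", GTractVariant(13)),
            ("G9TG6", GTractVariant(9, "T", 6)),
            ("G1AG1", GTractVariant(1, "A", 1)),
            ("G12CG12", GTractVariant(12, "C", 12)),
        ],
    )
    def test_parse_examples(self, name, expected):
        v = parse_nomenclature(name)
        assert v == expected
        assert v.name == name  # canonical rendering round-trips

    @pytest.mark.parametrize(
        "bad", ["GAG", "G0AG5", "G5AG0", "G5XG5", "G5GG5", "C7TC5x", "", "5AG7", "G"]
    )
    def test_parse_rejects_malformed(self, bad):
        with pytest.raises(NomenclatureError):
            parse_nomenclature(bad)

    def test_parse_error_names_offending_token(self):
        with pytest.raises(NomenclatureError, match="X"):
            parse_nomenclature("G5XG5")
        with pytest.raises(NomenclatureError, match="zero"):
            parse_nomenclature("G0AG5")

    @settings(max_examples=200, derandomize=True)
    @given(variants)
    def test_parse_render_bijection(self, v):
        assert parse_nomenclature(v.name) == v

    def test_totals_and_tract_length(self):
        assert parse_nomenclature("G5AG7").total_guanines == 12
        assert parse_nomenclature("G6AG9").total_guanines == 15
        assert parse_nomenclature("G5AG7").tract_length == 13
        assert parse_nomenclature("G13").tract_length == 13

    def test_tract_sequence(self):
        assert parse_nomenclature("G2AG3").tract_sequence == "GGAGGG"
        assert parse_nomenclature("G4").tract_sequence == "GGGG"


class TestLightStrandName:
    def test_examples(self):
        assert light_strand_name(parse_nomenclature("G5AG7")) == "C7TC5"
        assert light_strand_name(parse_nomenclature("G13")) == "C13"
        assert light_strand_name(parse_nomenclature("G9CG6")) == "C6GC9"

    @settings(max_examples=200, derandomize=True)
    @given(variants)
    def test_involution(self, v):
        name = v.name
        assert reverse_complement_name(reverse_complement_name(name)) == name

    @settings(max_examples=100, derandomize=True)
    @given(variants)
    def test_matches_character_level_reverse_complement(self, v):
        """Oracle: reverse-complement the literal tract and re-derive the name."""
        rc = reverse_complement(v.tract_sequence)
        runs = run_length_encode(rc)
        if len(runs) == 1:
            oracle = f"{runs[0][0]}{runs[0][1]}"
        else:
            (b1, r1), (mid, _), (b2, r2) = runs
            oracle = f"{b1}{r1}{mid}{b2}{r2}"
        assert light_strand_name(v) == oracle


class TestAdeninePosition:
    @pytest.mark.parametrize(
        "name, pos",
        [
            ("G9AG6", +2),   # first run 3 longer: rounded away from zero
            ("G7AG7", 0),    # equal runs
            ("G6AG7", -1),
            ("G5AG7", -1),
            ("G6AG8", -1),
            ("G6AG9", -2),
            ("G7AG6", +1),
            ("G1AG12", -6),
        ],
    )
    def test_examples(self, name, pos):
        assert adenine_position(parse_nomenclature(name)) == pos

    def test_continuous_is_domain_error(self):
        with pytest.raises(ValueError):
            adenine_position(parse_nomenclature("G13"))

    def test_antisymmetry_and_parity_over_grid(self):
        for m in range(1, 13):
            for n in range(1, 13):
                p = adenine_position(GTractVariant(m, "A", n))
                q = adenine_position(GTractVariant(n, "A", m))
                assert p == -q
                assert abs(p) <= (m + n + 1) // 2
                if p == 0:
                    assert (m + n) % 2 == 0 and m == n


class TestRunLengthEncoding:
    def test_examples(self):
        assert run_length_encode("GGGAGG") == [("G", 3), ("A", 1), ("G", 2)]
        assert run_length_encode("") == []

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGTN", max_size=50))
    def test_round_trip_and_maximality(self, seq):
        runs = run_length_encode(seq)
        assert run_length_decode(runs) == seq
        for (b1, c1), (b2, c2) in zip(runs, runs[1:]):
            assert b1 != b2 and c1 >= 1 and c2 >= 1


class TestTranscriptCoordinates:
    def test_end_position_arithmetic(self):
        assert transcript_end_position(407, 125) == 283
        assert transcript_end_position(407, 1) == 407
        assert transcript_end_position(300, 300) == 1

    def test_below_origin_is_error(self):
        with pytest.raises(CoordinateError):
            transcript_end_position(100, 101)

    def test_insertion_shifts_length_to_fixed_residue(self):
        base = transcript_length_for_end(407, 284, insertion_len=0)
        ins = transcript_length_for_end(407, 284, insertion_len=3)
        assert ins - base == 3

    def test_insertion_shifts_end_for_fixed_length(self):
        assert (
            transcript_end_position(407, 125, insertion_len=3)
            - transcript_end_position(407, 125, insertion_len=0)
            == 3
        )

    def test_coordinate_system_containment(self):
        cs = CoordinateSystem()
        assert cs.tract_interval_rcrs == (303, 315)
        with pytest.raises(CoordinateError):
            CoordinateSystem(tract_interval_rcrs=(294, 325), anchor_region_rcrs=(294, 325))

    def test_rcrs_slice_round_trip(self):
        sl = CoordinateSystem.rcrs_to_slice((303, 315))
        assert (sl.start, sl.stop) == (302, 315)
        assert CoordinateSystem.slice_to_rcrs(sl) == (303, 315)


class TestSequenceRecord:
    def test_iupac_codes_mapped_to_n(self, caplog):
        with caplog.at_level(logging.WARNING):
            rec = SequenceRecord("r1", "", "ACGTRYSWacgt")
        assert rec.residues == "ACGTNNNNACGT"
        assert "mapping non-ACGTN" in caplog.text

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("r1", "", "")

    def test_reverse_complement(self):
        rec = SequenceRecord("r1", "", "AACGT")
        assert rec.reverse_complement().residues == "ACGTT"


class TestTPTable:
    def test_packaged_fixture_loads_with_provenance(self):
        table = TPTable.from_tsv(PACKAGED_TP)
        assert table["G7AG6"].mean_tp == 17.0
        assert table["G3AG9"].mean_tp == 11.0
        assert table["G>A"].mean_tp == 9.0
        for name, entry in table.items():
            assert 0.0 <= entry.mean_tp <= 100.0
            assert entry.provenance

    def test_out_of_range_tp_rejected(self):
        with pytest.raises(ValueError):
            TPEntry(mean_tp=120.0)

    def test_tsv_round_trip(self, tmp_path):
        table = TPTable.from_mapping({"G5AG7": 17.0, "G13": 30.0}, provenance="synthetic")
        path = tmp_path / "tp.tsv"
        table.to_tsv(path)
        again = TPTable.from_tsv(path)
        assert again["G13"].mean_tp == 30.0
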