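import numpy as np
import pandas as pd
import pytest

from tazstruct import (
    ExonMap,
    build_helix,
    map_numbering,
    parse_hgvs_p,
    read_exon_map,
    read_mutation_table,
    read_structure,
    write_structure,
)
from tazstruct.core_io import EmptyStructureError, MutationRecord


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.458   2.000   3.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_minimal_single_residue(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        st = read_structure(p)
        assert len(st) == 1
        res = st.residues[0]
        assert res.aa == "A" and res.number == 1
        np.testing.assert_allclose(res.atom("N").coord, [1.0, 2.0, 3.0])

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        st = read_structure(p)
        ca = st.residues[0].atom("CA")
        assert ca.coord[0] == pytest.approx(1.458)

    def test_no_atom_records_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_structure(p)

    def test_roundtrip_preserves_coordinates(self, tmp_path, helix):
        p = tmp_path / "helix.pdb"
        write_structure(helix, p)
        back = read_structure(p)
        assert back.sequence() == helix.sequence()
        for r1, r2 in zip(helix.residues, back.residues):
            for a in r1.atoms:
                np.testing.assert_allclose(
                    a.coord, r2.atom(a.name).coord, atol=1.5e-3
                )


class TestExonMap:
    def test_exon5_span(self, tmp_path):
        p = tmp_path / "em.tsv"
        p.write_text("exon_id\tstart\tend\n5\t125\t154\n")
        em = read_exon_map(p)
        assert em.range_of("5") == (125, 154)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "em.tsv"
        p.write_text("exon_id\tstart\tend\n")
        assert len(read_exon_map(p)) == 0

    def test_unsorted_rows_sorted(self, tmp_path):
        p = tmp_path / "em.tsv"
        p.write_text("exon_id\tstart\tend\n3\t96\t100\n2\t40\t95\n")
        em = read_exon_map(p)
        assert em.exon_ids() == ["2", "3"]

    @pytest.mark.parametrize(
        "rows",
        [
            [("2", 40, 95), ("3", 90, 100)],   # overlap
            [("2", 95, 40)],                   # start > end
        ],
    )
    def test_invalid_ranges_rejected(self, rows):
        with pytest.raises(ValueError):
            ExonMap(entries=rows)


class TestMutationTable:
    def test_packaged_row_and_position_counts(self, fixtures):
        assert len(fixtures.mutation_records) == 39
        assert len({r.position for r in fixtures.mutation_records}) == 33

    def test_empty_table(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("hgvs_p\texon\n")
        assert read_mutation_table(p) == []

    def test_malformed_row_names_index(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("hgvs_p\texon\np.Gly197Arg\t8\np.Xyz12Ala\t1\n")
        with pytest.raises(ValueError, match="row 1"):
            read_mutation_table(p)

    def test_identity_substitution_rejected(self):
        with pytest.raises(ValueError):
            MutationRecord("G", 10, "G")


class TestParseHgvs:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("p.Gly197Arg", ("G", 197, "R")),
            ("p.His69Gln", ("H", 69, "Q")),
            ("p.Asn40Asp", ("N", 40, "D")),
        ],
    )
    def test_valid(self, text, expected):
        rec = parse_hgvs_p(text)
        assert (rec.ref_aa, rec.position, rec.alt_aa) == expected

    @pytest.mark.parametrize("text", ["p.Xyz12Ala", "Gly197Arg", "p.Gly19xArg"])
    def test_invalid(self, text):
        with pytest.raises(ValueError):
            parse_hgvs_p(text)


class TestMapNumbering:
    def test_above_exon5_shifts_by_length(self, fixtures):
        assert map_numbering(155, "FL->D5", fixtures.exon_map) == 125

    def test_below_exon5_identity(self, fixtures):
        assert map_numbering(124, "FL->D5", fixtures.exon_map) == 124

    def test_inside_exon5_undefined(self, fixtures):
        assert map_numbering(130, "FL->D5", fixtures.exon_map) is None

    def test_roundtrip_identity_on_defined_positions(self, fixtures):
        em = fixtures.exon_map
        for pos in range(1, 300):
            d5 = map_numbering(pos, "FL->D5", em)
            if d5 is not None:
                assert map_numbering(d5, "D5->FL", em) == pos

    def test_position_below_one_rejected(self, fixtures):
        with pytest.raises(ValueError):
            map_numbering(0, "FL->D5", fixtures.exon_map)
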