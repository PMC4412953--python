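import numpy as np
import pytest

from tazstruct import (
    SequenceRecord,
    annotate_mutation,
    assign_secondary_structure,
    basic_patch,
    build_helix,
    compute_sasa,
    effect_flags,
    find_hx4d,
    propose_effect,
    relative_accessibility,
)
from tazstruct.core_io import MutationRecord
from tazstruct.membrane_charge import PatchSet
from tazstruct.mut_classify import classify_location, normalize_location
from tazstruct.surface_core import AccessibilityProfile


class TestFindHx4d:
    def test_constructed_motif(self):
        hits = find_hx4d(SequenceRecord(id="s", seq="AHAAAADAA"))
        assert hits == [(2, 7)]

    def test_no_motif(self):
        assert find_hx4d(SequenceRecord(id="s", seq="AAAA")) == []

    def test_numbering_offset_respected(self):
        seq = SequenceRecord(id="s", seq="HAAAAD", numbering_offset=68)
        assert find_hx4d(seq) == [(69, 74)]

    def test_motif_spacing_invariant(self):
        for hit in find_hx4d(SequenceRecord(id="s", seq="HAAAADHAAAAD")):
            assert hit.asp_position - hit.his_position == 5


class TestSecondaryStructure:
    def test_ideal_helix_all_h_inside(self):
        st = build_helix("L" * 12)
        ss = assign_secondary_structure(st)
        labels = [ss.label_of(r.key) for r in st.residues]
        assert set(labels[1:-1]) == {"H"}

    def test_ideal_strand_all_e_inside(self):
        st = build_helix("A" * 10, phi=-120, psi=130)
        ss = assign_secondary_structure(st)
        labels = [ss.label_of(r.key) for r in st.residues]
        assert set(labels[1:-1]) == {"E"}

    def test_short_helical_run_demoted_to_coil(self):
        # 4-residue chain: only 2 interior residues have both torsions
        st = build_helix("LLLL")
        ss = assign_secondary_structure(st)
        assert all(ss.label_of(r.key) == "C" for r in st.residues)


class TestClassifyLocation:
    def _setup(self):
        helix = build_helix("AAARAARAARAAAAAAAA")
        profile = relative_accessibility(helix, compute_sasa(helix))
        patches = basic_patch(helix, profile, min_size=3)
        return helix, profile, patches

    def test_catalytic_precedence_over_cleft(self):
        helix, profile, patches = self._setup()
        rec = MutationRecord("A", 5, "V")
        call = classify_location(rec, {5}, {5}, patches, profile, helix)
        assert call.location == "catalytic"

    def test_buried_non_cleft(self):
        helix, _, patches = self._setup()
        keys = [r.key for r in helix.residues]
        buried_profile = AccessibilityProfile(
            keys, np.zeros(len(keys)), np.zeros(len(keys))
        )
        call = classify_location(
            MutationRecord("A", 12, "V"), set(), set(), patches,
            buried_profile, helix,
        )
        assert call.location == "buried"

    def test_exposed_near_patch_is_surface(self):
        helix, profile, patches = self._setup()
        call = classify_location(
            MutationRecord("A", 5, "V"), set(), set(), patches, profile, helix
        )
        assert call.location == "surface" and not call.distal

    def test_exposed_far_from_patch_flagged_distal(self):
        helix, profile, _ = self._setup()
        call = classify_location(
            MutationRecord("A", 5, "V"), set(), set(), PatchSet(), profile, helix
        )
        assert call.location == "surface" and call.distal

    def test_missing_position_raises(self):
        helix, profile, patches = self._setup()
        with pytest.raises(KeyError, match="999"):
            classify_location(
                MutationRecord("A", 999, "V"), set(), set(), patches, profile, helix
            )


class TestEffectFlags:
    @pytest.mark.parametrize(
        "hgvs,location,elec,stab",
        [
            ("p.His69Gln", "Catalytic site", True, False),
            ("p.Arg94Gly", "Surface", True, False),    # Gly rule gated to cleft/buried
            ("p.Thr43Pro", "Buried", False, True),
            ("p.Ile54Asn", "Surface", False, True),    # hydrophobic→polar on surface
            ("p.Arg57Leu", "Surface", True, False),    # reverse not flagged
            ("p.Leu169His", "Cleft", True, False),     # |ΔV|=13.5 below threshold
            ("p.Phe104Val", "Cleft", False, True),     # |ΔV|=49.9 above threshold
            ("p.His214Arg", "Buried", True, True),
        ],
    )
    def test_rule_set_on_representative_rows(self, hgvs, location, elec, stab):
        from tazstruct import parse_hgvs_p
        e, s, rules = effect_flags(parse_hgvs_p(hgvs), location)
        assert (e, s) == (elec, stab)
        assert (rules != []) == (e or s)

    def test_pure_function(self):
        rec = MutationRecord("G", 197, "R")
        assert effect_flags(rec, "cleft") == effect_flags(rec, "cleft")


class TestProposeEffect:
    @pytest.mark.parametrize(
        "location,effect",
        [
            ("catalytic", "Catalytic activity"),
            ("cleft", "Substrate binding"),
            ("surface", "Membrane association"),
            ("buried", "Destabilization"),
        ],
    )
    def test_location_determines_effect(self, location, effect):
        assert propose_effect(location) == effect

    def test_unknown_location_rejected(self):
        with pytest.raises(ValueError):
            normalize_location("somewhere")


class TestTable2Reproduction:
    def test_all_39_rows_reproduced(self, fixtures):
        """Flags and proposed effects recomputed from the substitution
        chemistry and printed location classes match the curated table."""
        df = fixtures.mutations
        for (_, row), rec in zip(df.iterrows(), fixtures.mutation_records):
            ann = annotate_mutation(rec, row["location"])
            assert ann.electrostatic == (row["electrostatic"] == "X"), row["hgvs_p"]
            assert ann.stability == (row["stability"] == "X"), row["hgvs_p"]
            assert ann.effect == row["effect"], row["hgvs_p"]
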