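import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tazstruct import (
    build_helix,
    compute_sasa,
    core_hydrophobic_stats,
    relative_accessibility,
    residue_contacts,
    structural_core,
)
from tazstruct.core_io import AtomRecord, ResidueView, Structure
from tazstruct.surface_core import AccessibilityProfile, ContactGraph, UnknownElementError

from conftest import atom_pair_structure, rigid_transform, single_atom_structure


class TestComputeSasa:
    def test_single_carbon_matches_analytic_sphere(self):
        area = compute_sasa(single_atom_structure())[0]
        analytic = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(analytic, rel=0.02)

    def test_distant_atoms_additive(self):
        st = atom_pair_structure(100.0)
        single = 4 * np.pi * 3.1 ** 2
        assert compute_sasa(st).sum() == pytest.approx(2 * single, rel=0.02)

    def test_overlapping_pair_matches_high_density_reference(self):
        st = atom_pair_structure(2.0)
        coarse = compute_sasa(st, n_sphere_points=960).sum()
        fine = compute_sasa(st, n_sphere_points=10000).sum()
        assert coarse == pytest.approx(fine, rel=0.03)

    def test_rigid_motion_invariance(self, helix):
        base = compute_sasa(helix)
        rng = np.random.default_rng(11)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = rigid_transform(helix, rot, rng.uniform(-30, 30, 3))
        assert np.abs(compute_sasa(moved) - base).max() <= 0.1

    def test_probe_radius_monotone_on_single_atom(self):
        st = single_atom_structure()
        areas = [compute_sasa(st, probe_radius=p)[0] for p in (1.0, 1.4, 2.0)]
        assert areas == sorted(areas)

    def test_unknown_element_strict_raises(self):
        st = single_atom_structure(element="Zz")
        with pytest.raises(UnknownElementError):
            compute_sasa(st, strict_elements=True)
        assert compute_sasa(st, strict_elements=False)[0] > 0


class TestRelativeAccessibility:
    def test_burial_strictly_below_threshold(self, helix):
        keys = [r.key for r in helix.residues]
        profile = AccessibilityProfile(
            residue_keys=keys,
            absolute=np.zeros(len(keys)),
            relative=np.array([0.09, 0.10, 0.11] + [0.5] * (len(keys) - 3)),
        )
        assert profile.buried[0]
        assert not profile.buried[1]  # exactly at threshold: exposed
        assert not profile.buried[2]

    def test_burial_monotone_in_threshold(self, helix, helix_profile):
        loose = AccessibilityProfile(
            helix_profile.residue_keys, helix_profile.absolute,
            helix_profile.relative, threshold=0.3,
        )
        assert set(np.nonzero(helix_profile.buried)[0]) <= set(
            np.nonzero(loose.buried)[0]
        )

    def test_extended_central_ala_near_reference_maximum(self):
        st = build_helix("GGAGG", phi=-120, psi=130, extend_sidechains=False)
        profile = relative_accessibility(st, compute_sasa(st))
        assert 0.8 <= profile.relative[2] <= 1.1

    def test_missing_residue_type_raises(self, helix):
        with pytest.raises(KeyError):
            relative_accessibility(helix, compute_sasa(helix), max_asa_table={"A": 100.0})


class TestResidueContacts:
    @pytest.mark.parametrize("sep,expected", [(4.4, 1), (4.6, 0)])
    def test_cutoff_boundary(self, sep, expected):
        st = atom_pair_structure(sep)
        assert len(residue_contacts(st, cutoff=4.5).pairs) == expected

    def test_matches_brute_force_on_helix(self, helix):
        contacts = residue_contacts(helix, cutoff=4.5)
        brute = set()
        for i, r1 in enumerate(helix.residues):
            for r2 in helix.residues[i + 1:]:
                d = np.sqrt(
                    ((r1.heavy_coords()[:, None, :] -
                      r2.heavy_coords()[None, :, :]) ** 2).sum(-1)
                ).min()
                if d <= 4.5:
                    brute.add(frozenset((r1.key, r2.key)))
        assert contacts.pairs == brute

    def test_nonpositive_cutoff_rejected(self, helix):
        with pytest.raises(ValueError):
            residue_contacts(helix, cutoff=0.0)


class TestStructuralCore:
    def test_empty_when_nothing_buried(self, helix, helix_profile):
        exposed = AccessibilityProfile(
            helix_profile.residue_keys, helix_profile.absolute,
            np.ones(len(helix_profile)),
        )
        core = structural_core(exposed, residue_contacts(helix))
        assert core.components == []

    def test_isolated_buried_residue_discarded(self):
        keys = [("A", 1, ""), ("A", 2, "")]
        profile = AccessibilityProfile(
            residue_keys=keys, absolute=np.zeros(2), relative=np.array([0.0, 0.5])
        )
        contacts = ContactGraph(pairs={frozenset(keys)}, cutoff=4.5)
        assert structural_core(profile, contacts).components == []

    def test_bundle_core_covers_interior_face(self, bundle):
        st, interior = bundle
        profile = relative_accessibility(st, compute_sasa(st))
        core = structural_core(profile, residue_contacts(st))
        assert core.components, "bundle must have a structural core"
        largest = core.components[0]
        assert len(largest & interior) / len(interior) >= 0.8

    def test_core_members_are_buried(self, bundle):
        st, _ = bundle
        profile = relative_accessibility(st, compute_sasa(st))
        core = structural_core(profile, residue_contacts(st))
        assert core.all_residues() <= profile.buried_keys()


class TestCoreHydrophobicStats:
    def test_all_leu_core_fully_hydrophobic(self, bundle):
        st, _ = bundle
        profile = relative_accessibility(st, compute_sasa(st))
        core = structural_core(profile, residue_contacts(st))
        per_comp, total = core_hydrophobic_stats(core, st)
        assert total == sum(len(c) for c in core.components)
        assert per_comp == [len(c) for c in core.components]

    def test_polar_residues_not_counted(self, bundle):
        st, _ = bundle
        profile = relative_accessibility(st, compute_sasa(st))
        core = structural_core(profile, residue_contacts(st))
        _, total = core_hydrophobic_stats(core, st, hydrophobic_set={"S"})
        assert total == 0
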