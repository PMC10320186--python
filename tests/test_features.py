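"""Complementary features: substitution deltas, solvent accessibility,
depth, secondary structure, contacts, and the feature scaler."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from mutstab.constants import VDW_RADII
from mutstab.features import (
    ContactCounts,
    FeatureScaler,
    contact_counts,
    delta_contacts,
    normalise_features,
    relative_sasa,
    residue_depth,
    secondary_structure,
    substitution_features,
    substitution_feature_names,
)
from mutstab.fixtures import make_peptide, make_shell, make_two_residue_contact
from mutstab.sasa import PROBE_RADIUS, atom_sasa
from mutstab.structure import Atom, Residue, Structure, build_mutant, parse_mutation_set

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestSubstitutionFeatures:
    def test_delta_block_antisymmetry(self):
        rng = np.random.default_rng(0)
        n_delta = 5  # physicochemical scales; matrix scores follow
        for _ in range(20):
            a, b = rng.choice(list(AA), size=2, replace=False)
            fwd = substitution_features(a, b)
            rev = substitution_features(b, a)
            assert np.allclose(fwd[:n_delta], -rev[:n_delta])

    def test_identity_gives_zero_deltas(self):
        v = substitution_features("A", "A")
        assert np.allclose(v[:5], 0.0)

    def test_trp_to_gly_hydrophobicity_matches_table(self):
        # Kyte-Doolittle: G -0.4, W -0.9 -> delta +0.5
        names = substitution_feature_names()
        v = substitution_features("W", "G")
        assert v[names.index("d_hydrophobicity")] == pytest.approx(-0.4 - (-0.9))

    def test_matrix_scores_are_symmetric_lookups(self):
        names = substitution_feature_names()
        i = names.index("blosum62")
        assert substitution_features("W", "G")[i] == substitution_features("G", "W")[i]


def cap_occluded_fraction(r1, r2, d):
    """Analytic fraction of sphere 1 (radius r1) covered by the spherical
    cap cut out by sphere 2 (radius r2) at centre distance d."""
    cos_theta = (r1**2 + d**2 - r2**2) / (2 * r1 * d)
    return (1.0 - cos_theta) / 2.0


class TestSasa:
    def test_isolated_residue_is_fully_exposed(self):
        s = make_peptide(2)
        single = Structure("iso", [s.residues[0]])
        # a lone residue cannot be occluded below its reference maximum
        assert relative_sasa(single, single.residues[0]) == pytest.approx(1.0)

    def test_caged_atom_has_zero_accessibility(self):
        cage = make_shell(3.0, n_points=400)
        atoms = [Atom("CA", "C", np.zeros(3))]
        cage_res = Residue("B", 1, "", "GLY",
                           [Atom("N", "N", c) for c in cage])
        # hand-built structure: centre GLY 'CA' inside a dense nitrogen cage
        centre = Residue("A", 1, "", "GLY", atoms)
        s = Structure("cage", [centre, cage_res])
        areas = atom_sasa(s)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_sphere_system_matches_analytic_cap(self):
        d = 2.5
        s = Structure("two", [
            Residue("A", 1, "", "GLY", [Atom("CA", "C", np.zeros(3))]),
            Residue("A", 2, "", "GLY", [Atom("CA", "C", np.array([d, 0.0, 0.0]))]),
        ])
        areas = atom_sasa(s, n_points=10000)
        r_exp = VDW_RADII["C"] + PROBE_RADIUS
        frac = 1.0 - cap_occluded_fraction(r_exp, r_exp, d)
        expected = 4 * np.pi * r_exp**2 * frac
        assert areas[0] == pytest.approx(expected, rel=0.02)
        # the default sampling agrees with the refined oracle within 2%
        coarse = atom_sasa(s)[0]
        assert coarse == pytest.approx(areas[0], rel=0.02)


class TestResidueDepth:
    def test_exposed_residue_sits_at_its_own_surface(self):
        s = make_peptide(2)
        single = Structure("iso", [s.residues[0]])
        depth = residue_depth(single, single.residues[0])
        assert depth <= max(VDW_RADII.values()) + 2 * PROBE_RADIUS

    def test_caged_atom_depth_matches_shell_geometry(self):
        radius = 5.0
        cage = make_shell(radius, n_points=500)
        centre = Residue("A", 1, "", "GLY", [Atom("CA", "C", np.zeros(3))])
        shell = Residue("B", 1, "", "GLY", [Atom("N", "N", c) for c in cage])
        s = Structure("cage", [centre, shell])
        depth = residue_depth(s, centre)
        # accessible surface is the cage's outside: radius + r_N + probe
        expected = radius + VDW_RADII["N"] + PROBE_RADIUS
        assert depth == pytest.approx(expected, rel=0.05)

    def test_rigid_transform_invariance(self):
        s = make_peptide(3)
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        moved = Structure(s.structure_id, [
            Residue(r.chain_id, r.seq_number, r.insertion_code, r.res_name,
                    [Atom(a.name, a.element, a.coords @ rot.T + 5.0) for a in r.atoms])
            for r in s.residues
        ])
        d1 = residue_depth(s, s.residues[1])
        d2 = residue_depth(moved, moved.residues[1])
        assert d1 == pytest.approx(d2, abs=1e-6)


class TestSecondaryStructure:
    def test_ideal_helix_interior(self):
        h = make_peptide(6)  # phi -57, psi -47
        assert secondary_structure(h, h.residues[2]).tolist() == [1, 0, 0]

    def test_ideal_strand_interior(self):
        s = make_peptide(6, phi=-120.0, psi=120.0)
        assert secondary_structure(s, s.residues[2]).tolist() == [0, 1, 0]

    def test_termini_are_coil(self):
        h = make_peptide(4)
        assert secondary_structure(h, h.residues[0]).tolist() == [0, 0, 1]
        assert secondary_structure(h, h.residues[-1]).tolist() == [0, 0, 1]


def oracle_contacts(s, r, typing):
    """Brute-force pair enumeration mirroring the stated distance rules."""
    from mutstab.features import (
        AROMATIC_CUTOFF, ENVIRONMENT_CUTOFF, HBOND_CUTOFF,
        HYDROPHOBIC_CUTOFF, IONIC_CUTOFF,
    )
    own = [(a.coords, typing.label_atom(r.res_name, a.name))
           for a in r.atoms if a.is_heavy]
    env = [(a.coords, typing.label_atom(o.res_name, a.name))
           for o in s.residues if o.key != r.key for a in o.atoms if a.is_heavy]
    hb = hp = io = ar = 0
    near_polar = near_hydro = 0
    for cb, lb in env:
        dmin = np.inf
        for ca, la in own:
            d = np.linalg.norm(ca - cb)
            dmin = min(dmin, d)
            if d <= HBOND_CUTOFF and (("HDonor" in la and "HAcceptor" in lb)
                                      or ("HAcceptor" in la and "HDonor" in lb)):
                hb += 1
            if d <= HYDROPHOBIC_CUTOFF and "Hydrophobic" in la and "Hydrophobic" in lb:
                hp += 1
            if d <= IONIC_CUTOFF and (("Positive" in la and "Negative" in lb)
                                      or ("Negative" in la and "Positive" in lb)):
                io += 1
            if d <= AROMATIC_CUTOFF and "Aromatic" in la and "Aromatic" in lb:
                ar += 1
        if dmin <= ENVIRONMENT_CUTOFF:
            if lb & {"HDonor", "HAcceptor", "Positive", "Negative"}:
                near_polar += 1
            if "Hydrophobic" in lb:
                near_hydro += 1
    return ContactCounts(hb, hp, io, ar, near_polar, near_hydro)


class TestContacts:
    def test_isolated_residue_has_no_contacts(self, typing):
        s = make_peptide(2)
        iso = Structure("iso", [s.residues[0]])
        assert contact_counts(iso, iso.residues[0], typing) == ContactCounts()

    def test_salt_bridge_fixture_matches_oracle(self, typing):
        s = make_two_residue_contact("LYS", "ASP", ("NZ", "OD1"), 2.9)
        got = contact_counts(s, s.residues[0], typing)
        assert got == oracle_contacts(s, s.residues[0], typing)
        assert got.hbond >= 1
        assert got.ionic >= 1

    def test_helix_interior_matches_oracle(self, helix, typing):
        r = helix.get_residue("A", 5)
        assert contact_counts(helix, r, typing) == oracle_contacts(helix, r, typing)

    def test_identity_delta_is_zero(self, helix, typing):
        ms = parse_mutation_set("A A5G")
        mut = build_mutant(helix, ms)
        assert delta_contacts(mut, mut, ms.reversed(), typing) == ContactCounts()

    def test_swapping_structures_negates_delta(self, helix, typing):
        ms = parse_mutation_set("A A5F")
        mut = build_mutant(helix, ms)
        d1 = delta_contacts(helix, mut, ms, typing)
        d2 = delta_contacts(mut, helix, ms.reversed(), typing)
        assert d1.as_array().tolist() == (-d2.as_array()).tolist()

    def test_phe_to_ala_removes_aromatic_stacking(self, typing):
        """Two stacked PHE residues; mutating one to ALA loses every
        aromatic contact the oracle counts in the wild type."""
        s = make_two_residue_contact("PHE", "PHE", ("CZ", "CZ"), 4.0)
        # restrict to chain A site: mutate A:1 PHE -> ALA
        ms = parse_mutation_set("A F1A")
        mut = build_mutant(s, ms)
        wt_counts = oracle_contacts(s, s.residues[0], typing)
        assert wt_counts.aromatic > 0
        d = delta_contacts(s, mut, ms, typing)
        assert d.aromatic == -wt_counts.aromatic


class TestNormalise:
    def test_z_score_closed_form(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        normed, scaler = normalise_features(table)
        assert np.allclose(normed["x"], [-1.224744871, 0.0, 1.224744871])
        assert scaler.std[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_column_maps_to_zeros(self):
        table = pd.DataFrame({"x": [5.0, 5.0, 5.0], "y": [1.0, 2.0, 4.0]})
        normed, _ = normalise_features(table)
        assert (normed["x"] == 0.0).all()

    def test_scaler_roundtrips_through_json_bit_identically(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.standard_normal((10, 4)), columns=list("abcd"))
        normed, scaler = normalise_features(table)
        restored = FeatureScaler.from_json(scaler.to_json())
        assert restored.transform(table).equals(normed)

    def test_non_numeric_column_raises(self):
        with pytest.raises((ValueError, TypeError)):
            normalise_features(pd.DataFrame({"x": ["a", "b"]}))

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            normalise_features(pd.DataFrame({"x": []}))
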