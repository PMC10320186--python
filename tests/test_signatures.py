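"""Cutoff-scanning signatures against a brute-force triple-loop oracle,
plus geometric and combinatorial invariants."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mutstab.fixtures import make_atom_cloud, make_peptide
from mutstab.pharmacophores import PAIR_CATEGORIES
from mutstab.signatures import (
    SignatureConfig,
    compute_signature,
    environment_atoms,
    signature_features,
)
from mutstab.structure import build_mutant, parse_mutation_set

CAT_INDEX = {}
for idx, (a, b) in enumerate(PAIR_CATEGORIES):
    CAT_INDEX[(a, b)] = idx
    CAT_INDEX[(b, a)] = idx


def oracle_signature(coords, label_sets, cfg):
    """Direct triple loop over pairs, label combinations and cutoffs."""
    cutoffs = cfg.cutoffs
    counts = np.zeros((len(PAIR_CATEGORIES), len(cutoffs)), dtype=np.int64)
    n = len(label_sets)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            cats = {CAT_INDEX[(la, lb)] for la in label_sets[i] for lb in label_sets[j]}
            for b, c in enumerate(cutoffs):
                if cfg.cumulative:
                    hit = d <= c + 1e-9
                else:
                    lower = cutoffs[b - 1] if b > 0 else -np.inf
                    hit = lower + 1e-9 < d <= c + 1e-9
                if hit:
                    for cat in cats:
                        counts[cat, b] += 1
    return counts


class TestComputeSignature:
    def test_single_hydrophobic_pair(self):
        cfg = SignatureConfig()
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        labels = [frozenset({"Hydrophobic"})] * 2
        sig = compute_signature(coords, labels, cfg)
        row = CAT_INDEX[("Hydrophobic", "Hydrophobic")]
        assert sig[row].tolist() == [0, 1, 1, 1, 1]
        other = np.delete(sig, row, axis=0)
        assert other.sum() == 0

    def test_empty_collection_gives_zero_signature(self):
        cfg = SignatureConfig()
        sig = compute_signature(np.empty((0, 3)), [], cfg)
        assert sig.shape == (36, 5)
        assert sig.sum() == 0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("cumulative", [True, False])
    def test_matches_triple_loop_oracle(self, seed, cumulative):
        cfg = SignatureConfig(cumulative=cumulative)
        coords, labels = make_atom_cloud(40, seed=seed)
        assert np.array_equal(compute_signature(coords, labels, cfg),
                              oracle_signature(coords, labels, cfg))

    def test_cumulative_counts_are_monotone(self):
        cfg = SignatureConfig()
        coords, labels = make_atom_cloud(50, seed=99)
        sig = compute_signature(coords, labels, cfg)
        assert (np.diff(sig, axis=1) >= 0).all()

    def test_permutation_invariance(self):
        cfg = SignatureConfig()
        coords, labels = make_atom_cloud(30, seed=3)
        perm = np.random.default_rng(0).permutation(len(labels))
        sig1 = compute_signature(coords, labels, cfg)
        sig2 = compute_signature(coords[perm], [labels[i] for i in perm], cfg)
        assert np.array_equal(sig1, sig2)

    def test_rigid_transform_invariance(self):
        cfg = SignatureConfig()
        coords, labels = make_atom_cloud(30, seed=4)
        rot = Rotation.from_euler("xyz", [0.3, -1.2, 2.2]).as_matrix()
        moved = coords @ rot.T + np.array([10.0, -5.0, 3.0])
        assert np.array_equal(compute_signature(coords, labels, cfg),
                              compute_signature(moved, labels, cfg))


class TestEnvironmentAtoms:
    def test_infinite_radius_includes_all_heavy_atoms(self, helix, typing):
        ms = parse_mutation_set("A A3G")
        cfg = SignatureConfig(env_radius=1e6, d_max=10.0)
        coords, labels = environment_atoms(helix, ms, cfg, typing)
        n_heavy = sum(sum(a.is_heavy for a in r.atoms) for r in helix.residues)
        assert len(labels) == n_heavy

    def test_zero_radius_keeps_only_the_mutated_residue(self, helix, typing):
        ms = parse_mutation_set("A A3G")
        with pytest.warns(UserWarning):
            cfg = SignatureConfig(env_radius=0.0)
        coords, labels = environment_atoms(helix, ms, cfg, typing)
        assert len(labels) == len(helix.get_residue("A", 3).atoms)

    def test_matches_brute_force_residue_scan(self, helix, typing):
        ms = parse_mutation_set("A A3G")
        cfg = SignatureConfig(env_radius=6.0, d_max=6.0, d_step=2.0)
        coords, labels = environment_atoms(helix, ms, cfg, typing)
        site = helix.get_residue("A", 3).heavy_coords()
        expected = 0
        for r in helix.residues:
            rc = r.heavy_coords()
            dmin = np.linalg.norm(rc[:, None, :] - site[None, :, :], axis=2).min()
            if dmin <= 6.0 or r.key == ("A", 3, ""):
                expected += len(rc)
        assert len(labels) == expected


class TestSignatureFeatures:
    def test_identity_mutant_gives_zero_difference(self, helix, typing, sig_cfg):
        ms = parse_mutation_set("A A5G")
        mut = build_mutant(helix, ms)
        # compare the mutant against itself through the reversed orientation
        sw, sm, sd = signature_features(mut, mut, ms.reversed(), typing, sig_cfg)
        # identical structures, identical environments: difference is zero
        assert np.array_equal(sw, sm)
        assert sd.sum() == 0

    def test_swapping_structures_negates_difference(self, helix, typing, sig_cfg):
        ms = parse_mutation_set("A A5G")
        mut = build_mutant(helix, ms)
        _, _, d_fwd = signature_features(helix, mut, ms, typing, sig_cfg)
        _, _, d_rev = signature_features(mut, helix, ms.reversed(), typing, sig_cfg)
        assert np.array_equal(d_fwd, -d_rev)

    def test_ala_to_gly_difference_reflects_removed_cb(self, helix, typing, sig_cfg):
        """The A->G mutant differs only by the lost CB; recompute the mutant
        signature with the oracle on the wild-type cloud minus that atom."""
        ms = parse_mutation_set("A A5G")
        mut = build_mutant(helix, ms)
        sig_wt, sig_mut, _ = signature_features(helix, mut, ms, typing, sig_cfg)
        coords, labels = environment_atoms(helix, ms, sig_cfg, typing)
        cb = helix.get_residue("A", 5).atom("CB").coords
        keep = [i for i in range(len(labels))
                if not np.allclose(coords[i], cb)]
        expected = oracle_signature(coords[keep], [labels[i] for i in keep], sig_cfg)
        assert np.array_equal(sig_mut, expected)
        assert (sig_mut <= sig_wt).all()
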