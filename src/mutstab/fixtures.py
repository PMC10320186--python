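"""Deterministic synthetic inputs: ideal-geometry peptides, typed atom
clouds, geometric probes, and labelled feature tables with a known
feature-to-ddG relationship.

These generators stand in for experimental structures and curated stability
tables so the full pipeline is exercisable offline. They are first-class,
tested code: every fixture is bit-reproducible from its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AA1_TO_3
from .geometry import build_cb, build_sidechain, place_atom
from .pharmacophores import PHARMACOPHORES
from .structure import Atom, Residue, Structure

__all__ = [
    "make_peptide",
    "make_atom_cloud",
    "make_shell",
    "make_two_residue_contact",
    "make_labelled_dataset",
    "LabelledDataset",
]

# ideal backbone internal coordinates
_N_CA, _CA_C, _C_N, _C_O = 1.46, 1.52, 1.33, 1.23
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.0, 116.2, 121.7, 120.5


def make_peptide(n_residues: int, phi: float = -57.0, psi: float = -47.0,
                 sequence: str | None = None, chain_id: str = "A",
                 structure_id: str = "fixture") -> Structure:
    """Build an ideal-geometry peptide with uniform backbone torsions.

    Defaults build an alpha-helix (phi=-57, psi=-47); (-120, 120) gives an
    extended beta-strand. ``sequence`` is a 1-letter string (default
    poly-alanine); side chains are placed from the idealised templates.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    omega = 180.0

    # seed residue: N at origin, CA on x, C in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANG_N_CA_C)
    c0 = ca0 + _CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    bb: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_residues):
        prev = bb[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], _C_N, _ANG_CA_C_N, psi)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, _N_CA, _ANG_C_N_CA, omega)
        c_i = place_atom(prev["C"], n_i, ca_i, _CA_C, _ANG_N_CA_C, phi)
        bb.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O needs the next residue's N; last residue uses the psi torsion
    for i, frame in enumerate(bb):
        frame["O"] = place_atom(frame["N"], frame["CA"], frame["C"],
                                _C_O, _ANG_CA_C_O, psi + 180.0)

    residues = []
    for i, frame in enumerate(bb):
        res3 = AA1_TO_3[sequence[i]]
        atoms = [Atom(n, n[0], frame[n]) for n in ("N", "CA", "C", "O")]
        if res3 != "GLY":
            cb = build_cb(frame["N"], frame["CA"], frame["C"])
            atoms.append(Atom("CB", "C", cb))
            coords = {**{k: frame[k] for k in ("N", "CA", "C", "O")}, "CB": cb}
            atoms.extend(Atom(nm, nm[0], pos) for nm, pos in build_sidechain(coords, res3))
        residues.append(Residue(chain_id, i + 1, "", res3, atoms))
    return Structure(structure_id, residues)


def make_atom_cloud(n_atoms: int, seed: int, box: float = 12.0,
                    max_labels: int = 2) -> tuple[np.ndarray, list[frozenset]]:
    """Random coordinates in a cube with random pharmacophore label sets
    (1..max_labels labels per atom). Returns (coords, label_sets)."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n_atoms, 3))
    labels = []
    for _ in range(n_atoms):
        k = int(rng.integers(1, max_labels + 1))
        picked = rng.choice(len(PHARMACOPHORES), size=k, replace=False)
        labels.append(frozenset(PHARMACOPHORES[i] for i in picked))
    return coords, labels


def make_shell(radius: float, n_points: int = 200) -> np.ndarray:
    """Golden-spiral points on a sphere of the given radius (a closed cage
    around the origin, for burial/depth probes)."""
    i = np.arange(n_points)
    phi_g = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi_g * i
    return radius * np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def make_two_residue_contact(res_a: str = "LYS", res_b: str = "ASP",
                             pair: tuple[str, str] = ("NZ", "OD1"),
                             distance: float = 2.9) -> Structure:
    """Two idealised residues on separate chains, rigidly placed so that the
    named atom pair sits at the requested distance (a salt-bridge probe)."""

    def ideal_residue(res3: str, chain: str, number: int) -> Residue:
        n = np.zeros(3)
        ca = np.array([_N_CA, 0.0, 0.0])
        ang = np.radians(180.0 - _ANG_N_CA_C)
        c = ca + _CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
        o = place_atom(n, ca, c, _C_O, _ANG_CA_C_O, 133.0)
        atoms = [Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c), Atom("O", "O", o)]
        if res3 != "GLY":
            cb = build_cb(n, ca, c)
            atoms.append(Atom("CB", "C", cb))
            coords = {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}
            atoms.extend(Atom(nm, nm[0], pos) for nm, pos in build_sidechain(coords, res3))
        return Residue(chain, number, "", res3, atoms)

    ra = ideal_residue(res_a, "A", 1)
    rb = ideal_residue(res_b, "B", 1)
    a_pos = ra.atom(pair[0]).coords
    b_pos = rb.atom(pair[1]).coords
    # translate chain B so that pair[1] lands at a_pos + (distance, 0, 0)
    shift = a_pos + np.array([distance, 0.0, 0.0]) - b_pos
    rb = Residue(rb.chain_id, rb.seq_number, rb.insertion_code, rb.res_name,
                 [Atom(a.name, a.element, a.coords + shift) for a in rb.atoms])
    return Structure("contact_fixture", [ra, rb])


@dataclass
class LabelledDataset:
    """Synthetic feature table emulating the forward/reverse paired layout
    the siamese model consumes.

    ``X_fwd``/``X_rev`` are (n, d) with the first ``n_sig_channels*n_bins``
    columns playing the role of signature features and the rest playing
    complementary features. Delta-type columns flip sign between the two
    orientations, so labels are exactly anti-symmetric by construction.
    """

    X_fwd: np.ndarray
    X_rev: np.ndarray
    y: np.ndarray
    n_sig_channels: int
    n_bins: int
    delta_mask: np.ndarray  # boolean per column
    coeffs: np.ndarray

    @property
    def n_comp(self) -> int:
        return self.X_fwd.shape[1] - self.n_sig_channels * self.n_bins

    def stacked(self) -> np.ndarray:
        """Concatenate forward and reverse halves: (n, 2d), the estimator's X."""
        return np.hstack([self.X_fwd, self.X_rev])

    def augmented(self) -> tuple[np.ndarray, np.ndarray]:
        """Forward plus reverse-orientation records (2n rows), labels negated
        on the reverse half — the synthetic analogue of reverse augmentation."""
        X = np.vstack([self.stacked(), np.hstack([self.X_rev, self.X_fwd])])
        y = np.concatenate([self.y, -self.y])
        return X, y


def make_labelled_dataset(n: int, coeffs=None, noise_sd: float = 0.1,
                          seed: int = 0, n_sig_channels: int = 36,
                          n_bins: int = 5, n_comp: int = 10,
                          nonlinear: bool = False) -> LabelledDataset:
    """Draw seeded standard-normal features and labels y = coeffs . x + noise.

    ``coeffs`` indexes into the delta-type columns only (default: 3 columns
    with weights [1.5, -1.0, 0.5]), so the generated labels negate exactly
    under the orientation swap. ``nonlinear`` adds a pairwise product of a
    delta-type and an orientation-invariant column (labels stay
    anti-symmetric) to exercise the non-linear network path.
    """
    rng = np.random.default_rng(seed)
    d = n_sig_channels * n_bins + n_comp
    X = rng.standard_normal((n, d))
    # delta-type columns: the whole signature block plus the first half of
    # the complementary block
    delta_mask = np.zeros(d, dtype=bool)
    delta_mask[: n_sig_channels * n_bins] = True
    delta_mask[n_sig_channels * n_bins : n_sig_channels * n_bins + n_comp // 2] = True
    delta_idx = np.flatnonzero(delta_mask)

    if coeffs is None:
        coeffs = {0: 1.5, 1: -1.0, 2: 0.5}
    coeff_vec = np.zeros(d)
    for k, v in dict(coeffs).items():
        coeff_vec[delta_idx[k]] = v

    y = X @ coeff_vec
    if nonlinear:
        invariant_idx = np.flatnonzero(~delta_mask)
        y = y + X[:, delta_idx[0]] * X[:, invariant_idx[0]]
    y = y + rng.normal(0.0, noise_sd, size=n)

    X_rev = X.copy()
    X_rev[:, delta_mask] *= -1.0
    return LabelledDataset(X, X_rev, y, n_sig_channels, n_bins, delta_mask, coeff_vec)
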