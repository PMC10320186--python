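"""Internal-coordinate geometry: torsion measurement, NeRF atom placement,
and idealised side-chain templates for fixed-backbone mutant building.

Side chains are described as Z-matrix rows (atom, three reference atoms,
bond length, bond angle, torsion) and materialised by the natural-extension
reference frame construction. All chi torsions default to the extended
trans conformer; ring geometries are approximate ideal values. The scheme
is deliberately deterministic: the same inputs always give bit-identical
coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "SIDECHAIN_TEMPLATES",
    "build_sidechain",
    "build_cb",
    "HEAVY_ATOM_NAMES",
]


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion a-b-c-d in degrees, IUPAC convention."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D with |C-D| = bond, angle(B,C,D) = angle and torsion
    (A,B,C,D) = dihedral (NeRF construction)."""
    angle = np.radians(angle_deg)
    tors = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(tors),
        -bond * np.sin(angle) * np.sin(tors),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Z-matrix rows: (atom, (ref_a, ref_b, ref_c), bond, angle, torsion) with the
# torsion measured over ref_a-ref_b-ref_c-atom. References must already exist
# (backbone N/CA/C plus previously placed side-chain atoms).
_T = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 110.5, 180.0)],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 110.5, 180.0)],
    "THR": [("OG1", ("N", "CA", "CB"), 1.43, 109.5, 180.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, -60.0)],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.52, 110.5, 180.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, -60.0)],
    "LEU": [("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
            ("CD1", ("CA", "CB", "CG"), 1.52, 110.5, 180.0),
            ("CD2", ("CA", "CB", "CG"), 1.52, 110.5, 60.0)],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.52, 110.5, 180.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, -60.0),
            ("CD1", ("CA", "CB", "CG1"), 1.52, 113.0, 180.0)],
    "MET": [("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
            ("SD", ("CA", "CB", "CG"), 1.81, 112.7, 180.0),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.8, 180.0)],
    "ASP": [("CG", ("N", "CA", "CB"), 1.52, 112.6, 180.0),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.5, 0.0),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.5, 180.0)],
    "ASN": [("CG", ("N", "CA", "CB"), 1.52, 112.6, 180.0),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, 0.0),
            ("ND2", ("CA", "CB", "CG"), 1.33, 116.5, 180.0)],
    "GLU": [("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.5, 0.0),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.5, 180.0)],
    "GLN": [("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, 0.0),
            ("NE2", ("CB", "CG", "CD"), 1.33, 116.5, 180.0)],
    "LYS": [("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, 180.0),
            ("CE", ("CB", "CG", "CD"), 1.52, 111.3, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.47, 111.9, 180.0)],
    "ARG": [("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, 180.0),
            ("NE", ("CB", "CG", "CD"), 1.47, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, 180.0),
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.50, 113.8, 180.0),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, -90.0),
            ("CD2", ("CA", "CB", "CG"), 1.36, 131.0, 90.0),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 109.2, 180.0),
            ("NE2", ("CG", "ND1", "CE1"), 1.34, 108.2, 0.0)],
    "PHE": [("CG", ("N", "CA", "CB"), 1.50, 113.8, 180.0),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, -90.0),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.50, 113.8, 180.0),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, -90.0),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0)],
    "TRP": [("CG", ("N", "CA", "CB"), 1.50, 113.8, 180.0),
            ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, -90.0),
            ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.41, 107.2, 180.0),
            ("CE3", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.8, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0)],
    "PRO": [("CG", ("N", "CA", "CB"), 1.50, 104.5, 30.0),
            ("CD", ("CA", "CB", "CG"), 1.50, 105.5, -35.0)],
}

SIDECHAIN_TEMPLATES: dict[str, list] = _T

HEAVY_ATOM_NAMES: dict[str, tuple[str, ...]] = {
    res: ("N", "CA", "C", "O") + (() if res == "GLY" else ("CB",))
    + tuple(row[0] for row in rows)
    for res, rows in _T.items()
}


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta from backbone N/CA/C (L-configuration)."""
    return place_atom(n, c, ca, 1.53, 110.6, -122.6)


def build_sidechain(coords: dict[str, np.ndarray], res_name: str) -> list[tuple[str, np.ndarray]]:
    """Materialise idealised side-chain atoms beyond CB for ``res_name``.

    ``coords`` must contain N, CA, CB (CB ignored for GLY). Returns
    (atom_name, position) in template order.
    """
    if res_name not in SIDECHAIN_TEMPLATES:
        raise KeyError(f"no side-chain template for residue {res_name!r}")
    local = dict(coords)
    placed: list[tuple[str, np.ndarray]] = []
    for name, (ra, rb, rc), bond, ang, tors in SIDECHAIN_TEMPLATES[res_name]:
        pos = place_atom(local[ra], local[rb], local[rc], bond, ang, tors)
        local[name] = pos
        placed.append((name, pos))
    return placed
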