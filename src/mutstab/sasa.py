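"""Shrake-Rupley solvent accessibility and a surface-point residue depth.

Both quantities share one construction: every heavy atom is wrapped in a
sphere of radius r_vdw + probe carrying ``n_points`` golden-spiral test
points; a point is accessible when no other atom's expanded sphere covers
it. SASA integrates the accessible fraction over each atom's sphere;
residue depth is the mean distance from a residue's heavy atoms to the
nearest accessible point anywhere on the molecular surface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .constants import MAX_SASA, VDW_RADII
from .structure import Residue, Structure

__all__ = ["sphere_points", "atom_sasa", "accessible_surface_points",
           "relative_sasa", "residue_depth"]

PROBE_RADIUS = 1.4  # water probe, Angstrom
N_SPHERE_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """Golden-spiral quasi-uniform points on the unit sphere."""
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = golden * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _heavy_atoms(s: Structure):
    coords, radii, owner = [], [], []
    for ridx, r in enumerate(s.residues):
        for a in r.atoms:
            if a.is_heavy:
                coords.append(a.coords)
                radii.append(VDW_RADII.get(a.element, 1.70))
                owner.append(ridx)
    return (np.asarray(coords).reshape(-1, 3), np.asarray(radii),
            np.asarray(owner, dtype=int))


def _accessibility(coords: np.ndarray, radii: np.ndarray,
                   probe: float, n_points: int):
    """Per-atom accessible masks of the test-point spheres."""
    unit = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    masks = []
    rmax = expanded.max()
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], expanded[i] + rmax)
                 if j != i]
        accessible = np.ones(n_points, dtype=bool)
        if neigh:
            d = np.linalg.norm(pts[:, None, :] - coords[neigh][None, :, :], axis=2)
            accessible = (d >= expanded[neigh][None, :] - 1e-9).all(axis=1)
        masks.append(accessible)
    return unit, expanded, masks


def atom_sasa(s: Structure, probe: float = PROBE_RADIUS,
              n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """Accessible surface area per heavy atom (A^2), in structure atom order."""
    coords, radii, _ = _heavy_atoms(s)
    _, expanded, masks = _accessibility(coords, radii, probe, n_points)
    frac = np.array([m.mean() for m in masks])
    return 4.0 * np.pi * expanded**2 * frac


def accessible_surface_points(s: Structure, probe: float = PROBE_RADIUS,
                              n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """All accessible test points of the structure (the sampled solvent-
    accessible surface), as an (m, 3) array."""
    coords, radii, _ = _heavy_atoms(s)
    unit, expanded, masks = _accessibility(coords, radii, probe, n_points)
    pts = [coords[i] + expanded[i] * unit[m] for i, m in enumerate(masks) if m.any()]
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def relative_sasa(s: Structure, r: Residue, probe: float = PROBE_RADIUS,
                  n_points: int = N_SPHERE_POINTS) -> float:
    """Residue SASA over its reference maximum, clipped to [0, 1]."""
    coords, radii, owner = _heavy_atoms(s)
    _, expanded, masks = _accessibility(coords, radii, probe, n_points)
    ridx = s.residues.index(r)
    area = sum(
        4.0 * np.pi * expanded[i] ** 2 * masks[i].mean()
        for i in range(len(coords)) if owner[i] == ridx
    )
    return float(np.clip(area / MAX_SASA[r.res_name], 0.0, 1.0))


def residue_depth(s: Structure, r: Residue, probe: float = PROBE_RADIUS,
                  n_points: int = N_SPHERE_POINTS) -> float:
    """Mean distance of the residue's heavy atoms to the nearest accessible
    surface point (A). Fully exposed residues sit within about a probe
    diameter of their own surface."""
    surface = accessible_surface_points(s, probe, n_points)
    if surface.shape[0] == 0:
        raise ValueError("structure has no accessible surface points")
    tree = cKDTree(surface)
    atom_coords = r.heavy_coords()
    d, _ = tree.query(atom_coords)
    return float(np.mean(d))
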