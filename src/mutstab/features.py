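"""Complementary sequence- and structure-based features.

Sequence side: deltas of curated physicochemical scales (mutant minus wild
type) plus BLOSUM/PAM substitution scores. Structure side: relative solvent
accessibility, residue depth, a torsion-window secondary-structure class,
and simplified atomic contact counts (distance + pharmacophore rules) with
their changes upon mutation. Multi-mutant aggregation: deltas are summed
over sites, site descriptors averaged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields as dc_fields
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist
from sklearn.preprocessing import StandardScaler

from .constants import AA1_TO_3
from .geometry import dihedral
from .pharmacophores import AtomTyping
from .sasa import relative_sasa, residue_depth
from .structure import MutationSet, Residue, Structure, resolve_mutation

logger = logging.getLogger(__name__)

__all__ = [
    "substitution_features",
    "substitution_feature_names",
    "secondary_structure",
    "ContactCounts",
    "contact_counts",
    "delta_contacts",
    "complementary_vector",
    "complementary_feature_names",
    "FeatureScaler",
    "normalise_features",
    "relative_sasa",
    "residue_depth",
]

# contact rule thresholds (A), config-exposed via keyword arguments
HBOND_CUTOFF = 3.5
HYDROPHOBIC_CUTOFF = 4.5
IONIC_CUTOFF = 4.0
AROMATIC_CUTOFF = 5.0
ENVIRONMENT_CUTOFF = 5.0

_POLAR = frozenset({"HDonor", "HAcceptor", "Positive", "Negative"})


@lru_cache(maxsize=1)
def _aaindex_table() -> pd.DataFrame:
    src = resources.files("mutstab.data").joinpath("aaindex_subset.tsv")
    with src.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col=0)


@lru_cache(maxsize=1)
def _matrices():
    # PAM70 stands in for PAM120 (nearest distance shipped with Biopython)
    return {name: substitution_matrices.load(name)
            for name in ("BLOSUM62", "PAM30", "PAM70", "PAM250")}


def substitution_feature_names() -> list[str]:
    props = [f"d_{p}" for p in _aaindex_table().index]
    return props + ["blosum62", "pam30", "pam70", "pam250"]


def substitution_features(wt_res: str, mut_res: str) -> np.ndarray:
    """Physicochemical deltas (mut - wt) plus substitution-matrix scores.

    The delta block is exactly antisymmetric under wt/mut exchange; the
    matrix scores are symmetric lookups.
    """
    table = _aaindex_table()
    deltas = (table[mut_res] - table[wt_res]).to_numpy(dtype=float)
    mats = _matrices()
    scores = [float(mats[m][wt_res][mut_res])
              for m in ("BLOSUM62", "PAM30", "PAM70", "PAM250")]
    return np.concatenate([deltas, scores])


def _chain_neighbours(s: Structure, r: Residue):
    idx = s.residues.index(r)
    prev_r = s.residues[idx - 1] if idx > 0 else None
    next_r = s.residues[idx + 1] if idx + 1 < len(s.residues) else None
    if prev_r is not None and prev_r.chain_id != r.chain_id:
        prev_r = None
    if next_r is not None and next_r.chain_id != r.chain_id:
        next_r = None
    return prev_r, next_r


def secondary_structure(s: Structure, r: Residue) -> np.ndarray:
    """Three-state one-hot (helix, strand, coil) from backbone phi/psi.

    Helix: phi in [-90, -30] and psi in [-77, -17]; strand: phi in
    [-150, -90] and psi in [90, 180] or [-180, -170]; all else (including
    chain termini and residues with missing backbone atoms) coil.
    """
    coil = np.array([0.0, 0.0, 1.0])
    prev_r, next_r = _chain_neighbours(s, r)
    if prev_r is None or next_r is None:
        return coil
    try:
        phi = dihedral(prev_r.atom("C").coords, r.atom("N").coords,
                       r.atom("CA").coords, r.atom("C").coords)
        psi = dihedral(r.atom("N").coords, r.atom("CA").coords,
                       r.atom("C").coords, next_r.atom("N").coords)
    except KeyError:
        logger.warning("missing backbone atoms at %s; classified coil", r.key)
        return coil
    if -90.0 <= phi <= -30.0 and -77.0 <= psi <= -17.0:
        return np.array([1.0, 0.0, 0.0])
    if -150.0 <= phi <= -90.0 and (90.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0):
        return np.array([0.0, 1.0, 0.0])
    return coil


@dataclass(frozen=True)
class ContactCounts:
    hbond: int = 0
    hydrophobic: int = 0
    ionic: int = 0
    aromatic: int = 0
    total_polar_atoms: int = 0
    total_hydrophobic_atoms: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)], dtype=float)

    def __sub__(self, other: "ContactCounts") -> "ContactCounts":
        return ContactCounts(*(int(a - b) for a, b in
                               zip(self.as_array(), other.as_array())))

    def __add__(self, other: "ContactCounts") -> "ContactCounts":
        return ContactCounts(*(int(a + b) for a, b in
                               zip(self.as_array(), other.as_array())))

    @staticmethod
    def field_names() -> list[str]:
        return [f.name for f in dc_fields(ContactCounts)]


def contact_counts(s: Structure, r: Residue, typing: AtomTyping) -> ContactCounts:
    """Count interactions between residue ``r`` and all other residues.

    Pair rules (heavy atoms, distance d): hydrogen bond if one atom is a
    donor and the other an acceptor at d <= 3.5; hydrophobic if both
    hydrophobic at d <= 4.5; ionic if opposite formal charges at d <= 4.0;
    aromatic if both aromatic at d <= 5.0. The two ``total_*`` fields count
    environment atoms within 5.0 A carrying polar / hydrophobic labels.
    """
    own, own_labels = [], []
    for a in r.atoms:
        if a.is_heavy:
            own.append(a.coords)
            own_labels.append(typing.label_atom(r.res_name, a.name))
    env, env_labels = [], []
    for other in s.residues:
        if other.key == r.key:
            continue
        for a in other.atoms:
            if a.is_heavy:
                env.append(a.coords)
                env_labels.append(typing.label_atom(other.res_name, a.name))
    if not own or not env:
        return ContactCounts()

    d = cdist(np.asarray(own), np.asarray(env))
    hbond = hydrophobic = ionic = aromatic = 0
    for i, la in enumerate(own_labels):
        for j, lb in enumerate(env_labels):
            dij = d[i, j]
            if dij <= HBOND_CUTOFF and (
                ("HDonor" in la and "HAcceptor" in lb)
                or ("HAcceptor" in la and "HDonor" in lb)
            ):
                hbond += 1
            if dij <= HYDROPHOBIC_CUTOFF and "Hydrophobic" in la and "Hydrophobic" in lb:
                hydrophobic += 1
            if dij <= IONIC_CUTOFF and (
                ("Positive" in la and "Negative" in lb)
                or ("Negative" in la and "Positive" in lb)
            ):
                ionic += 1
            if dij <= AROMATIC_CUTOFF and "Aromatic" in la and "Aromatic" in lb:
                aromatic += 1
    near = d.min(axis=0) <= ENVIRONMENT_CUTOFF
    polar_atoms = sum(1 for j, lb in enumerate(env_labels) if near[j] and (lb & _POLAR))
    hydro_atoms = sum(1 for j, lb in enumerate(env_labels) if near[j] and "Hydrophobic" in lb)
    return ContactCounts(hbond, hydrophobic, ionic, aromatic, polar_atoms, hydro_atoms)


def delta_contacts(wt: Structure, mut: Structure, ms: MutationSet,
                   typing: AtomTyping) -> ContactCounts:
    """Change in contact counts upon mutation, summed over mutated sites."""
    total = ContactCounts()
    for m in ms:
        r_wt = wt.get_residue(*m.site)
        r_mut = mut.get_residue(*m.site)
        total = total + (contact_counts(mut, r_mut, typing)
                         - contact_counts(wt, r_wt, typing))
    return total


def complementary_feature_names() -> list[str]:
    names = list(substitution_feature_names())
    names += ["rel_sasa_wt", "residue_depth_wt", "ss_helix", "ss_strand", "ss_coil"]
    names += [f"wt_{n}" for n in ContactCounts.field_names()]
    names += [f"mut_{n}" for n in ContactCounts.field_names()]
    names += [f"delta_{n}" for n in ContactCounts.field_names()]
    return names


def complementary_vector(wt: Structure, mut: Structure, ms: MutationSet,
                         typing: AtomTyping, sasa_points: int = 240) -> np.ndarray:
    """Full complementary feature vector for one mutation set (one
    orientation). Deltas (substitution scales, contact changes) are summed
    over sites; site descriptors (SASA, depth, secondary structure, raw
    contact counts) are averaged. ``sasa_points`` trades surface-sampling
    resolution for speed and applies to both SASA and depth."""
    subs = np.zeros(len(substitution_feature_names()))
    site_desc = []
    delta = ContactCounts()
    for m in ms:
        subs += substitution_features(m.wt_res, m.mut_res)
        r_wt = resolve_mutation(wt, m)
        r_mut = mut.get_residue(*m.site)
        rsa = relative_sasa(wt, r_wt, n_points=sasa_points)
        depth = residue_depth(wt, r_wt, n_points=sasa_points)
        ss = secondary_structure(wt, r_wt)
        c_wt = contact_counts(wt, r_wt, typing)
        c_mut = contact_counts(mut, r_mut, typing)
        delta = delta + (c_mut - c_wt)
        site_desc.append(np.concatenate([[rsa, depth], ss,
                                         c_wt.as_array(), c_mut.as_array()]))
    mean_desc = np.mean(site_desc, axis=0)
    return np.concatenate([subs, mean_desc, delta.as_array()])


@dataclass
class FeatureScaler:
    """Per-column z-scaling fitted on training rows only.

    Population standard deviation; zero-variance columns map to zeros.
    Persistable as JSON so held-out rows are transformed with the stored
    training statistics verbatim.
    """

    columns: list[str]
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "FeatureScaler":
        if table.empty:
            raise ValueError("cannot fit a scaler on an empty table")
        values = table.to_numpy(dtype=float)  # raises on non-numeric columns
        sk = StandardScaler().fit(values)
        std = np.sqrt(sk.var_)
        return cls(list(table.columns), sk.mean_.copy(), std)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if list(table.columns) != self.columns:
            raise ValueError("column mismatch between scaler and table")
        values = table.to_numpy(dtype=float)
        safe_std = np.where(self.std == 0.0, 1.0, self.std)
        out = (values - self.mean) / safe_std
        out[:, self.std == 0.0] = 0.0
        return pd.DataFrame(out, index=table.index, columns=self.columns)

    def to_json(self) -> str:
        return json.dumps({"columns": self.columns,
                           "mean": self.mean.tolist(),
                           "std": self.std.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "FeatureScaler":
        d = json.loads(text)
        return cls(d["columns"], np.asarray(d["mean"]), np.asarray(d["std"]))


def normalise_features(table: pd.DataFrame) -> tuple[pd.DataFrame, FeatureScaler]:
    """Z-score every column on the given (training) rows; returns the
    normalised table and the fitted scaler for later reuse."""
    scaler = FeatureScaler.fit(table)
    return scaler.transform(table), scaler
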