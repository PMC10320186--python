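"""Cutoff-scanning graph signatures of a mutation-site environment.

The local environment is the set of residues with any heavy atom within
``env_radius`` of the mutated residue(s). Its signature is a matrix of
pharmacophore-pair counts: for every unordered atom pair and every distance
cutoff in a sweep, each distinct unordered label-pair category the two
atoms span is counted once. Cumulative counting (the default) makes row
``b`` the number of pairs at distance <= cutoff ``b``, so counts are
non-decreasing across the sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .pharmacophores import PAIR_CATEGORIES, PHARMACOPHORES, AtomTyping
from .structure import MutationSet, Structure

__all__ = [
    "SignatureConfig",
    "environment_atoms",
    "compute_signature",
    "signature_features",
    "signature_column_names",
]

_LABEL_INDEX = {lab: i for i, lab in enumerate(PHARMACOPHORES)}
_CAT_INDEX = {}
for idx, (a, b) in enumerate(PAIR_CATEGORIES):
    _CAT_INDEX[(a, b)] = idx
    _CAT_INDEX[(b, a)] = idx

_EDGE_TOL = 1e-9  # tolerance when a distance sits exactly on a bin edge


@dataclass(frozen=True)
class SignatureConfig:
    env_radius: float = 10.0
    d_min: float = 0.0
    d_max: float = 10.0
    d_step: float = 2.0
    cumulative: bool = True

    def __post_init__(self):
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")
        if self.d_step <= 0:
            raise ValueError("d_step must be positive")
        if self.env_radius < self.d_max:
            warnings.warn(
                "env_radius < d_max: distance bins beyond the environment "
                "radius will be under-populated", stacklevel=2,
            )

    @property
    def cutoffs(self) -> np.ndarray:
        return np.arange(self.d_min + self.d_step, self.d_max + self.d_step / 2, self.d_step)

    @property
    def n_bins(self) -> int:
        return len(self.cutoffs)


def _typed_atoms(s: Structure, typing: AtomTyping):
    coords, labels, res_index = [], [], []
    for ridx, r in enumerate(s.residues):
        for a in r.atoms:
            if not a.is_heavy:
                continue
            coords.append(a.coords)
            labels.append(typing.label_atom(r.res_name, a.name))
            res_index.append(ridx)
    return np.asarray(coords).reshape(-1, 3), labels, np.asarray(res_index, dtype=int)


def environment_atoms(s: Structure, ms: MutationSet, cfg: SignatureConfig,
                      typing: AtomTyping) -> tuple[np.ndarray, list[frozenset]]:
    """Heavy atoms of all residues with >= 1 heavy atom within ``env_radius``
    of any heavy atom of a mutated residue (mutated residues included).

    Returns (coords, label_sets) ready for :func:`compute_signature`.
    """
    site_residues = [s.get_residue(*m.site) for m in ms]
    site_keys = {r.key for r in site_residues}
    site_coords = np.vstack([r.heavy_coords() for r in site_residues])

    coords, labels, res_index = _typed_atoms(s, typing)
    if coords.shape[0] == 0:
        return coords, labels

    dmin_per_atom = cdist(coords, site_coords).min(axis=1)
    keep_res = set()
    for ridx, r in enumerate(s.residues):
        if r.key in site_keys:
            keep_res.add(ridx)
    for ridx in np.unique(res_index[dmin_per_atom <= cfg.env_radius + _EDGE_TOL]):
        keep_res.add(int(ridx))
    mask = np.isin(res_index, sorted(keep_res))
    return coords[mask], [lab for lab, m in zip(labels, mask) if m]


def compute_signature(coords: np.ndarray, label_sets: list[frozenset],
                      cfg: SignatureConfig) -> np.ndarray:
    """Count pharmacophore-pair occurrences per distance bin.

    Returns an integer array of shape (36 categories, n_bins). Atom order
    never matters; rigid transforms leave the result unchanged (up to the
    bin-edge tolerance).
    """
    cutoffs = cfg.cutoffs
    nbins = len(cutoffs)
    counts = np.zeros((len(PAIR_CATEGORIES), nbins), dtype=np.int64)
    n = coords.shape[0]
    if n < 2:
        return counts

    # group atoms by identical label set; category sets are fixed per group pair
    unique_sets: list[frozenset] = []
    set_index: dict[frozenset, int] = {}
    group_of = np.empty(n, dtype=int)
    for i, ls in enumerate(label_sets):
        if ls not in set_index:
            set_index[ls] = len(unique_sets)
            unique_sets.append(ls)
        group_of[i] = set_index[ls]
    members = [np.flatnonzero(group_of == g) for g in range(len(unique_sets))]

    def cats_for(sa: frozenset, sb: frozenset) -> np.ndarray:
        return np.unique([_CAT_INDEX[(la, lb)] for la in sa for lb in sb])

    for ga in range(len(unique_sets)):
        for gb in range(ga, len(unique_sets)):
            ia, ib = members[ga], members[gb]
            if ga == gb:
                if len(ia) < 2:
                    continue
                d = cdist(coords[ia], coords[ia])
                dvals = d[np.triu_indices(len(ia), k=1)]
            else:
                dvals = cdist(coords[ia], coords[ib]).ravel()
            # first bin whose cutoff is >= d (closed upper edge, with tolerance)
            first_bin = np.searchsorted(cutoffs, dvals - _EDGE_TOL, side="left")
            hist = np.bincount(first_bin[first_bin < nbins], minlength=nbins)
            row = np.cumsum(hist) if cfg.cumulative else hist
            counts[cats_for(unique_sets[ga], unique_sets[gb])] += row
    return counts


def signature_features(wt: Structure, mut: Structure, ms: MutationSet,
                       typing: AtomTyping, cfg: SignatureConfig):
    """Signatures of wild type, mutant, and their difference (wt - mut),
    each computed on that structure's own environment of the mutated sites."""
    sig_wt = compute_signature(*environment_atoms(wt, ms, cfg, typing), cfg)
    sig_mut = compute_signature(*environment_atoms(mut, ms, cfg, typing), cfg)
    return sig_wt, sig_mut, sig_wt - sig_mut


def signature_column_names(cfg: SignatureConfig, prefix: str = "") -> list[str]:
    """Stable column names, '<classA>:<classB>@<cutoff>'."""
    return [
        f"{prefix}{a}:{b}@{c:g}"
        for (a, b) in PAIR_CATEGORIES
        for c in cfg.cutoffs
    ]
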