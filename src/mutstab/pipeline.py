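"""End-to-end featurization: structures + mutation sets -> model-ready
feature tables in forward and reverse orientation.

A feature record concatenates three signature blocks (wild-type, mutant,
and their difference, each 36 pair categories x B bins) with the
complementary feature vector. The reverse-orientation record is produced
by swapping the structural roles (the built mutant becomes the reference)
and reversing the substitutions, mirroring how hypothetical reverse
mutations are generated during dataset augmentation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import complementary_feature_names, complementary_vector
from .pharmacophores import AtomTyping, load_typing_table
from .signatures import SignatureConfig, signature_column_names, signature_features
from .structure import MutationSet, Structure, build_mutant

logger = logging.getLogger(__name__)

__all__ = [
    "feature_columns",
    "featurize_mutation",
    "featurize_mutations",
    "model_matrix",
    "SIG_BLOCK_CHANNELS",
]

# wild-type, mutant and difference signature blocks stacked as channels
SIG_BLOCK_CHANNELS = 3 * 36


def feature_columns(cfg: SignatureConfig) -> list[str]:
    cols = []
    for prefix in ("wt_", "mut_", "diff_"):
        cols.extend(signature_column_names(cfg, prefix=prefix))
    cols.extend(complementary_feature_names())
    return cols


def featurize_mutation(wt: Structure, ms: MutationSet, typing: AtomTyping,
                       cfg: SignatureConfig, sasa_points: int = 240
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse feature records for one mutation set."""
    mut = build_mutant(wt, ms)

    def record(ref: Structure, alt: Structure, mset: MutationSet) -> np.ndarray:
        sw, sm, sd = signature_features(ref, alt, mset, typing, cfg)
        comp = complementary_vector(ref, alt, mset, typing, sasa_points=sasa_points)
        return np.concatenate([sw.ravel(), sm.ravel(), sd.ravel(), comp])

    fwd = record(wt, mut, ms)
    rev = record(mut, wt, ms.reversed())
    return fwd, rev


def featurize_mutations(wt: Structure, mutation_sets: list[MutationSet],
                        typing: AtomTyping | None = None,
                        cfg: SignatureConfig | None = None,
                        sasa_points: int = 240):
    """Feature table for many mutation sets (one row per orientation).

    Unresolvable mutations are collected as rejects rather than aborting
    the run. Returns (DataFrame, rejects) where rejects is a list of
    (mutation string, reason).
    """
    typing = typing if typing is not None else load_typing_table()
    cfg = cfg if cfg is not None else SignatureConfig()
    cols = feature_columns(cfg)
    rows, index, rejects = [], [], []
    for ms in mutation_sets:
        try:
            fwd, rev = featurize_mutation(wt, ms, typing, cfg, sasa_points)
        except (KeyError, ValueError) as exc:
            logger.warning("skipping %s: %s", ms, exc)
            rejects.append((str(ms), str(exc)))
            continue
        rows.append(fwd)
        index.append((str(ms), "forward"))
        rows.append(rev)
        index.append((str(ms), "reverse"))
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "mutation", [m for m, _ in index])
    df.insert(1, "orientation", [o for _, o in index])
    return df, rejects


def model_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Pair forward/reverse rows of a featurized table into the estimator's
    X layout (n_mutations, 2 * record_width). Returns (X, mutation names)."""
    fwd = df[df["orientation"] == "forward"]
    rev = df[df["orientation"] == "reverse"]
    names = list(fwd["mutation"])
    if names != list(rev["mutation"]):
        raise ValueError("forward/reverse rows are not paired consistently")
    feat_cols = [c for c in df.columns if c not in ("mutation", "orientation")]
    X = np.hstack([fwd[feat_cols].to_numpy(float), rev[feat_cols].to_numpy(float)])
    return X, names
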