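"""Curation of labelled stability records: duplicate resolution under
physiological-condition preference, blind-set overlap removal, hypothetical
reverse-mutation augmentation, and cross-validation fold assembly at either
mutation or protein level.

Sign convention throughout: ddG >= 0 means the mutation is stabilising; a
reverse record (mutant back to wild type) carries the negated ddG of its
forward partner.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .structure import MutationSet, parse_mutation_set

__all__ = [
    "StabilityRecord",
    "FoldAssignment",
    "records_from_table",
    "deduplicate",
    "remove_test_overlap",
    "augment_reverse",
    "make_folds",
]


@dataclass(frozen=True)
class StabilityRecord:
    protein_id: str
    structure_id: str
    mutation_set: MutationSet
    ddg: float
    ph: float | None = None
    temperature_c: float | None = None
    direction: Literal["forward", "reverse"] = "forward"

    def __post_init__(self):
        if not np.isfinite(self.ddg):
            raise ValueError("ddG must be finite")

    @property
    def mutation_key(self) -> tuple:
        """Order-insensitive identity of the mutation set."""
        return tuple(sorted(
            (m.chain_id, m.seq_number, m.insertion_code, m.wt_res, m.mut_res)
            for m in self.mutation_set
        ))

    @property
    def dedup_key(self) -> tuple:
        return (self.protein_id, self.mutation_key)


def records_from_table(table: pd.DataFrame, flip_sign: bool = False) -> list[StabilityRecord]:
    """Build records from a CSV/TSV-shaped table with columns protein_id,
    structure_id, chain, mutation, ddg and optional ph / temperature.

    ``flip_sign`` accommodates input tables using the opposite ddG
    convention (negative = stabilising)."""
    records = []
    for row in table.itertuples(index=False):
        ms = parse_mutation_set(str(row.mutation), getattr(row, "chain", None))
        ddg = float(row.ddg) * (-1.0 if flip_sign else 1.0)
        ph = getattr(row, "ph", None)
        temp = getattr(row, "temperature", getattr(row, "temperature_c", None))
        records.append(StabilityRecord(
            str(row.protein_id), str(row.structure_id), ms, ddg,
            None if ph is None or pd.isna(ph) else float(ph),
            None if temp is None or pd.isna(temp) else float(temp),
        ))
    return records


def _condition_distance(r: StabilityRecord) -> tuple[float, float]:
    dph = abs(r.ph - 7.0) if r.ph is not None else np.inf
    dt = abs(r.temperature_c - 25.0) if r.temperature_c is not None else np.inf
    return (dph, dt)


def deduplicate(records: Iterable[StabilityRecord]) -> list[StabilityRecord]:
    """Resolve duplicates at the (protein, mutation) level.

    Among duplicates the survivor is the record measured closest to
    physiological conditions: smallest |pH - 7| first, then smallest
    |T - 25 C| (missing conditions count as infinitely far); remaining ties
    keep the earliest record in input order. Idempotent. Forward-only input.
    """
    records = list(records)
    if any(r.direction != "forward" for r in records):
        raise ValueError("deduplicate expects forward records only")
    best: dict[tuple, tuple[tuple, int, StabilityRecord]] = {}
    for pos, r in enumerate(records):
        rank = (*_condition_distance(r), pos)
        cur = best.get(r.dedup_key)
        if cur is None or rank < cur[0]:
            best[r.dedup_key] = (rank, pos, r)
    survivors = sorted(best.values(), key=lambda t: t[1])
    return [r for _, _, r in survivors]


def remove_test_overlap(train: Iterable[StabilityRecord],
                        test: Iterable[StabilityRecord]) -> list[StabilityRecord]:
    """Drop training records whose protein and mutation both occur in the
    blind test set. Identical mutation strings on different proteins stay."""
    test_keys = {r.dedup_key for r in test}
    return [r for r in train if r.dedup_key not in test_keys]


def augment_reverse(records: Iterable[StabilityRecord]) -> list[StabilityRecord]:
    """Add the hypothetical reverse mutation of each record.

    Each reverse record swaps wild-type and mutant residues, swaps the
    structural roles of the two endpoint structures, and carries the
    negated ddG (the unfolding free-energy cycle closes exactly). Output
    size is 2n and the augmented ddG values sum to zero. Applying the
    augmentation to an already-bidirectional set is rejected.
    """
    records = list(records)
    if any(r.direction == "reverse" for r in records):
        raise ValueError("records already contain reverse entries; "
                         "augmentation must be applied exactly once")
    out = list(records)
    for r in records:
        out.append(replace(
            r,
            mutation_set=r.mutation_set.reversed(),
            ddg=-r.ddg,
            direction="reverse",
        ))
    return out


@dataclass
class FoldAssignment:
    fold_of: dict[int, int]  # record index -> fold id
    scheme: Literal["mutation", "protein"]
    k: int
    seed: int

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.fold_of.values():
            sizes[f] += 1
        return sizes


def make_folds(records: list[StabilityRecord], scheme: Literal["mutation", "protein"],
               k: int = 10, seed: int = 0) -> FoldAssignment:
    """Assign cross-validation folds over an augmented record list.

    Forward/reverse partners always share a fold (reverse records inherit
    the assignment of their forward partner's key). Protein level: proteins
    are shuffled, then greedily assigned largest-first to the currently
    smallest fold, so no protein ever crosses folds. Mutation level:
    forward records are shuffled and dealt round-robin.
    """
    rng = np.random.default_rng(seed)
    forward_idx = [i for i, r in enumerate(records) if r.direction == "forward"]

    if scheme == "protein":
        proteins: dict[str, list[int]] = {}
        for i in forward_idx:
            proteins.setdefault(records[i].protein_id, []).append(i)
        if len(proteins) < k:
            raise ValueError(f"{len(proteins)} proteins cannot fill {k} folds")
        names = sorted(proteins)
        rng.shuffle(names)
        # stable sort: largest first, shuffle order breaks ties
        names.sort(key=lambda p: -len(proteins[p]))
        loads = [0] * k
        fold_of_protein: dict[str, int] = {}
        for p in names:
            f = int(np.argmin(loads))
            fold_of_protein[p] = f
            loads[f] += len(proteins[p])
        fold_of_key = {records[i].dedup_key: fold_of_protein[records[i].protein_id]
                       for i in forward_idx}
    elif scheme == "mutation":
        order = np.array(forward_idx)
        rng.shuffle(order)
        fold_of_key = {records[i].dedup_key: j % k for j, i in enumerate(order)}
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    fold_of: dict[int, int] = {}
    for i, r in enumerate(records):
        key = (r.dedup_key if r.direction == "forward"
               else replace(r, mutation_set=r.mutation_set.reversed()).dedup_key)
        fold_of[i] = fold_of_key[key]
    return FoldAssignment(fold_of, scheme, k, seed)
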