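"""Atomic model of a protein, PDB I/O, mutation resolution, and
fixed-backbone mutant building.

Parsing and writing of the PDB format are delegated to biotite; this module
owns the residue-centric model the rest of the pipeline works with, the
filtering policy (first model, highest-occupancy altloc, heavy atoms only,
standard residues with a small parent map for modified ones), and the
deterministic idealised-side-chain substitution used to build mutant
structures without energy minimisation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import (
    AA1_TO_3,
    AA3_TO_1,
    BACKBONE_ATOMS,
    NONSTANDARD_ATOM_RENAME,
    NONSTANDARD_PARENT,
    STANDARD_AA1,
    STANDARD_AA3,
)
from .geometry import build_cb, build_sidechain

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Mutation",
    "MutationSet",
    "parse_pdb",
    "write_pdb",
    "parse_mutation",
    "parse_mutation_set",
    "resolve_mutation",
    "build_mutant",
]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str  # "" when absent
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return AA3_TO_1[self.res_name]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.res_name} {self.key} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy]).reshape(-1, 3)


@dataclass
class Structure:
    structure_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys in structure")

    def get_residue(self, chain_id: str, seq_number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain_id, seq_number, insertion_code):
                return r
        icode = insertion_code or ""
        raise KeyError(
            f"residue {chain_id}:{seq_number}{icode} not found in {self.structure_id}"
        )

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def copy(self) -> "Structure":
        return Structure(
            self.structure_id,
            [replace(r, atoms=list(r.atoms)) for r in self.residues],
        )


_MUT_RE = re.compile(r"^([A-Z])(-?\d+)([A-Z]?)([A-Z])$")


@dataclass(frozen=True)
class Mutation:
    chain_id: str
    seq_number: int
    insertion_code: str
    wt_res: str  # 1-letter
    mut_res: str  # 1-letter

    def __post_init__(self):
        if self.wt_res not in STANDARD_AA1 or self.mut_res not in STANDARD_AA1:
            raise ValueError(f"non-standard residue in mutation {self}")
        if self.wt_res == self.mut_res:
            raise ValueError(f"wild-type and mutant residues are identical: {self}")

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def reversed(self) -> "Mutation":
        return Mutation(self.chain_id, self.seq_number, self.insertion_code,
                        self.mut_res, self.wt_res)

    def __str__(self) -> str:
        return f"{self.chain_id} {self.wt_res}{self.seq_number}{self.insertion_code}{self.mut_res}"


@dataclass(frozen=True)
class MutationSet:
    mutations: tuple[Mutation, ...]

    def __post_init__(self):
        if not 1 <= len(self.mutations) <= 3:
            raise ValueError("a mutation set holds 1-3 substitutions")
        sites = [m.site for m in self.mutations]
        if len(sites) != len(set(sites)):
            raise ValueError("mutations in a set must address distinct residues")

    def __iter__(self):
        return iter(self.mutations)

    def __len__(self):
        return len(self.mutations)

    def reversed(self) -> "MutationSet":
        return MutationSet(tuple(m.reversed() for m in self.mutations))

    def __str__(self) -> str:
        return ";".join(str(m) for m in self.mutations)


def parse_mutation(text: str, chain_id: str | None = None) -> Mutation:
    """Parse one substitution, e.g. ``"F7A"`` (with ``chain_id``) or ``"A F7A"``.

    An optional uppercase insertion code may follow the residue number
    (``"F100AA"`` is read as position 100, icode A, Phe->Ala... ambiguous
    cases are resolved greedily: digits first, then at most one icode letter).
    """
    text = text.strip()
    if " " in text:
        chain_part, text = text.split(None, 1)
        chain_id = chain_part
    if chain_id is None:
        raise ValueError(f"no chain identifier for mutation {text!r}")
    m = _MUT_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse mutation string {text!r}")
    wt, pos, icode, mut = m.groups()
    return Mutation(chain_id, int(pos), icode, wt, mut)


def parse_mutation_set(text: str, chain_id: str | None = None) -> MutationSet:
    """Parse a semicolon-separated multi-mutation entry, e.g. ``"A F7A;A V13M"``."""
    parts = [p for p in text.split(";") if p.strip()]
    if len(parts) > 3:
        logger.warning(
            "mutation set %r has %d substitutions; the model is validated "
            "for up to triple mutations only", text, len(parts)
        )
        parts = parts  # accepted, caller beware
    return MutationSet(tuple(parse_mutation(p, chain_id) for p in parts))


def _element_of(atom_name: str, arr_element: str) -> str:
    if arr_element:
        return arr_element.capitalize()
    return atom_name.strip()[0]


def parse_pdb(path, structure_id: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Keeps the first model only; resolves alternate locations to the highest
    occupancy (ties by file order); drops hydrogens, waters and hetero
    compounds; maps a small set of modified residues to their standard
    parents; skips residues with unknown names with a warning.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(
        model=1, altloc="occupancy", extra_fields=["occupancy"]
    )
    if arr.array_length() == 0:
        raise ValueError(f"no parsable ATOM records in {path}")

    residues: list[Residue] = []
    current: Residue | None = None
    skipped: set[str] = set()
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i])
        if res_name in ("HOH", "WAT", "DOD"):
            continue
        atom_name = str(arr.atom_name[i])
        if res_name in NONSTANDARD_PARENT:
            atom_name = NONSTANDARD_ATOM_RENAME.get((res_name, atom_name), atom_name)
            res_name = NONSTANDARD_PARENT[res_name]
        if res_name not in STANDARD_AA3:
            if res_name not in skipped:
                logger.warning("skipping unknown residue %s in %s", res_name, path)
                skipped.add(res_name)
            continue
        element = _element_of(atom_name, str(arr.element[i]))
        if element in ("H", "D"):
            continue
        if element == "Se":  # renamed selenomethionine atom
            element = "S"
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.ins_code[i]).strip())
        if current is None or current.key != key:
            current = Residue(key[0], key[1], key[2], res_name)
            residues.append(current)
        current.atoms.append(Atom(atom_name, element, np.array(arr.coord[i], dtype=float)))

    if not residues:
        raise ValueError(f"no parsable ATOM records in {path}")
    sid = structure_id if structure_id is not None else _stem(path)
    return Structure(sid, residues)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_pdb(s: Structure, path) -> None:
    """Write a :class:`Structure` back to PDB (ATOM records only)."""
    n = sum(len(r.atoms) for r in s.residues)
    arr = struc.AtomArray(n)
    i = 0
    for r in s.residues:
        for a in r.atoms:
            arr.chain_id[i] = r.chain_id
            arr.res_id[i] = r.seq_number
            arr.ins_code[i] = r.insertion_code
            arr.res_name[i] = r.res_name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element.upper()
            arr.hetero[i] = False
            arr.coord[i] = a.coords
            i += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def resolve_mutation(s: Structure, m: Mutation) -> Residue:
    """Find the residue a mutation addresses and check its wild-type identity."""
    r = s.get_residue(m.chain_id, m.seq_number, m.insertion_code)
    if r.one_letter != m.wt_res:
        raise ValueError(
            f"wild-type mismatch at {m.chain_id}:{m.seq_number}{m.insertion_code}: "
            f"structure has {r.one_letter} ({r.res_name}), mutation says {m.wt_res}"
        )
    return r


def _mutate_residue(r: Residue, mut_res1: str) -> Residue:
    """Fixed-backbone substitution: keep N/CA/C/O (+ CB, built if absent),
    attach the idealised side chain of the target residue."""
    mut3 = AA1_TO_3[mut_res1]
    backbone = {}
    for name in BACKBONE_ATOMS:
        backbone[name] = r.atom(name)  # KeyError -> propagate: malformed residue
    new_atoms = [backbone[n] for n in BACKBONE_ATOMS]
    coords = {n: backbone[n].coords for n in BACKBONE_ATOMS}
    if mut3 != "GLY":
        if r.has_atom("CB"):
            cb = r.atom("CB")
        else:
            cb = Atom("CB", "C", build_cb(coords["N"], coords["CA"], coords["C"]))
        new_atoms.append(cb)
        coords["CB"] = cb.coords
        for name, pos in build_sidechain(coords, mut3):
            new_atoms.append(Atom(name, name[0], pos))
    return Residue(r.chain_id, r.seq_number, r.insertion_code, mut3, new_atoms)


def build_mutant(s: Structure, ms: MutationSet) -> Structure:
    """Build an approximate mutant structure by idealised side-chain
    substitution at each mutated site; every other residue is untouched."""
    targets = {}
    for m in ms:
        resolve_mutation(s, m)
        targets[m.site] = m.mut_res
    out = s.copy()
    out.residues = [
        _mutate_residue(r, targets[r.key]) if r.key in targets else r
        for r in out.residues
    ]
    return out
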