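"""Pharmacophore typing: each heavy atom of the 20 standard residues is
assigned one or more of eight chemical-role labels (hydrophobic, positive,
negative, H-bond acceptor, H-bond donor, aromatic, sulphur, neutral).

The per-atom table ships as a plain-text TSV (``data/pharmacophore_table.tsv``)
so it can be audited or overridden; the rules that generated it are kept in
``default_typing_rules`` for provenance. Choices worth noting: histidine
side-chain nitrogens are treated as positive (single fixed protonation
state), aromatic-ring carbons of Phe/Tyr/Trp are both aromatic and
hydrophobic, and atoms matching no rule default to neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .geometry import HEAVY_ATOM_NAMES

__all__ = [
    "PHARMACOPHORES",
    "AtomTyping",
    "load_typing_table",
    "default_typing_rules",
    "validate_typing_table",
]

PHARMACOPHORES = (
    "Hydrophobic", "Positive", "Negative", "HAcceptor",
    "HDonor", "Aromatic", "Sulphur", "Neutral",
)

# unordered pair categories: 28 heterogeneous + 8 homogeneous = 36
PAIR_CATEGORIES = tuple(
    (PHARMACOPHORES[i], PHARMACOPHORES[j])
    for i in range(len(PHARMACOPHORES))
    for j in range(i, len(PHARMACOPHORES))
)

_AROMATIC = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_POSITIVE = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
             ("HIS", "ND1"), ("HIS", "NE2")}
_NEGATIVE = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_DONOR = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
          ("ASN", "ND2"), ("GLN", "NE2"), ("LYS", "NZ"),
          ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
          ("TRP", "NE1"), ("HIS", "ND1"), ("HIS", "NE2")}
_ACCEPTOR = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
             ("ASN", "OD1"), ("GLN", "OE1"),
             ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
# sp2 carbons bonded to heteroatoms only: not hydrophobic, not aromatic
_POLAR_CARBON = {("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"), ("GLN", "CD"),
                 ("ARG", "CZ")}


def default_typing_rules(res_name: str, atom_name: str) -> frozenset:
    """Chemistry rules behind the committed table (backbone + side chain)."""
    labels: set[str] = set()
    if atom_name == "N":
        labels.add("Neutral" if res_name == "PRO" else "HDonor")
    elif atom_name == "O":
        labels.add("HAcceptor")
    elif atom_name == "OXT":
        labels.update(("HAcceptor", "Negative"))
    elif atom_name == "C":
        labels.add("Neutral")
    else:
        key = (res_name, atom_name)
        if atom_name in _AROMATIC.get(res_name, ()):
            labels.add("Aromatic")
            if atom_name.startswith("C") and res_name != "HIS":
                labels.add("Hydrophobic")
        if key in _POSITIVE:
            labels.add("Positive")
        if key in _NEGATIVE:
            labels.add("Negative")
        if key in _DONOR:
            labels.add("HDonor")
        if key in _ACCEPTOR:
            labels.add("HAcceptor")
        if atom_name in ("SG", "SD"):
            labels.add("Sulphur")
        if atom_name.startswith("C") and key not in _POLAR_CARBON \
                and atom_name not in _AROMATIC.get(res_name, ()):
            labels.add("Hydrophobic")  # aliphatic carbon (incl. CA, CB)
    if not labels:
        labels.add("Neutral")
    return frozenset(labels)


@dataclass
class AtomTyping:
    """Mapping (res_name, atom_name) -> set of pharmacophore labels."""

    table: dict[tuple[str, str], frozenset] = field(default_factory=dict)

    def label_atom(self, res_name: str, atom_name: str) -> frozenset:
        try:
            return self.table[(res_name, atom_name)]
        except KeyError:
            raise KeyError(
                f"no pharmacophore typing for atom ({res_name}, {atom_name})"
            ) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.table


def load_typing_table(path=None) -> AtomTyping:
    """Load the typing TSV (res_name, atom_name, semicolon-joined labels).

    With no ``path`` the table committed with the package is used.
    """
    if path is None:
        src = resources.files("mutstab.data").joinpath("pharmacophore_table.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[tuple[str, str], frozenset] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, labels = line.split("\t")
        table[(res, atom)] = frozenset(labels.split(";"))
    return AtomTyping(table)


def validate_typing_table(typing: AtomTyping) -> list[str]:
    """Report violations: missing standard heavy atoms, labels outside the
    eight-class universe, or unlabelled atoms. Empty list = valid."""
    violations: list[str] = []
    universe = set(PHARMACOPHORES)
    for res, atoms in HEAVY_ATOM_NAMES.items():
        for atom in atoms:
            if (res, atom) not in typing:
                violations.append(f"missing atom ({res}, {atom})")
    for (res, atom), labels in typing.table.items():
        extra = set(labels) - universe
        if extra:
            violations.append(f"({res}, {atom}) has labels outside universe: {sorted(extra)}")
        if not labels:
            violations.append(f"({res}, {atom}) has no labels")
    return violations


def generate_default_table_text() -> str:
    """Serialise the rule-derived table as the TSV shipped with the package."""
    lines = ["# res_name\tatom_name\tlabels (semicolon-joined)"]
    for res in sorted(HEAVY_ATOM_NAMES):
        for atom in HEAVY_ATOM_NAMES[res] + ("OXT",):
            labels = sorted(default_typing_rules(res, atom))
            lines.append(f"{res}\t{atom}\t{';'.join(labels)}")
    return "\n".join(lines) + "\n"
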