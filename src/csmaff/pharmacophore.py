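"""Pharmacophore typing: assigning physicochemical classes to heavy atoms.

Each heavy atom of the complex is labelled with one or more of eight
coarse pharmacophore classes.  Protein atoms are typed by a bundled
(residue, atom) lookup table derived from standard amino-acid chemistry;
ligand atoms are typed from their element and bonded environment, since
HETATM records carry no chemistry of their own.

The class set and its order are part of the feature schema: the same
enum ordering is used at training and prediction time.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .structure import AtomRecord, RecordClass

__all__ = [
    "Pharmacophore",
    "TypingTable",
    "load_typing_table",
    "type_protein_atom",
    "type_ligand_atom",
    "TYPING_TABLE_VERSION",
    "CANONICAL_RESIDUE_ATOMS",
]

TYPING_TABLE_VERSION = "v1"


class Pharmacophore(enum.IntEnum):
    """The eight atom classes used to label graph nodes.

    The ordinal order is fixed and defines feature ordering in the
    signature schema; do not reorder.
    """

    HYDROPHOBIC = 0
    POSITIVE = 1
    NEGATIVE = 2
    H_ACCEPTOR = 3
    H_DONOR = 4
    AROMATIC = 5
    SULFUR = 6
    NEUTRAL = 7


#: Element-level fallback for (residue, atom) pairs missing from the table.
_ELEMENT_FALLBACK = {
    "C": frozenset({Pharmacophore.HYDROPHOBIC}),
    "N": frozenset({Pharmacophore.H_DONOR}),
    "O": frozenset({Pharmacophore.H_ACCEPTOR}),
    "S": frozenset({Pharmacophore.SULFUR}),
    "Se": frozenset({Pharmacophore.SULFUR}),
}
_FALLBACK_OTHER = frozenset({Pharmacophore.NEUTRAL})


@dataclass(frozen=True)
class TypingTable:
    """Versioned (residue, atom) -> class-set lookup for protein atoms."""

    protein_map: dict[tuple[str, str], frozenset[Pharmacophore]]
    version: str = TYPING_TABLE_VERSION

    def lookup(self, residue_name: str, atom_name: str):
        return self.protein_map.get((residue_name, atom_name))


def load_typing_table(version: str = TYPING_TABLE_VERSION) -> TypingTable:
    """Load the bundled plain-text typing table."""
    name = f"protein_typing_{version}.tsv"
    try:
        text = resources.files("csmaff.data").joinpath(name).read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"unknown typing table version: {version}") from exc
    mapping: dict[tuple[str, str], frozenset[Pharmacophore]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, classes = line.split("\t")
        members = frozenset(Pharmacophore[c] for c in classes.split(","))
        if not members:
            raise ValueError(f"empty class set for ({res}, {atom})")
        mapping[(res, atom)] = members
    return TypingTable(protein_map=mapping, version=version)


_DEFAULT_TABLE: TypingTable | None = None


def default_table() -> TypingTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_typing_table()
    return _DEFAULT_TABLE


def type_protein_atom(
    atom: AtomRecord, table: TypingTable | None = None
) -> frozenset[Pharmacophore]:
    """Type one protein heavy atom via the bundled table.

    Unknown (residue, atom) pairs fall back to element rules (C ->
    hydrophobic, N -> donor, O -> acceptor, S/Se -> sulfur, other ->
    neutral) with a warning.
    """
    if atom.record_class is not RecordClass.PROTEIN:
        raise ValueError(f"atom {atom.atom_name} is not a protein atom")
    if atom.is_hydrogen:
        raise ValueError(
            f"hydrogen {atom.atom_name} passed to heavy-atom pharmacophore typing"
        )
    table = table or default_table()
    hit = table.lookup(atom.residue_name, atom.atom_name)
    if hit is not None:
        return hit
    warnings.warn(
        f"no typing entry for ({atom.residue_name}, {atom.atom_name}); "
        "using element fallback",
        stacklevel=2,
    )
    return _ELEMENT_FALLBACK.get(atom.element, _FALLBACK_OTHER)


# --- ligand typing -------------------------------------------------------

_HALOGENS = {"F", "Cl", "Br", "I"}


def type_ligand_atom(index: int, bonds) -> frozenset[Pharmacophore]:
    """Type one ligand heavy atom from its element and bond environment.

    ``bonds`` is a :class:`csmaff.descriptors.BondGraph` over the ligand's
    heavy atoms.  Rules, applied in order and accumulated:

    * membership of a (planar, 5- or 6-membered C/N/O/S) ring -> AROMATIC;
    * carboxylate / phosphate / sulfate terminal O -> NEGATIVE + H_ACCEPTOR;
    * other O -> H_ACCEPTOR;
    * N adjacent to a carbonyl carbon (amide) -> H_DONOR; aromatic-ring N
      additionally H_ACCEPTOR; other N -> POSITIVE + H_DONOR;
    * S or Se -> SULFUR;
    * C and halogens, unless otherwise classified -> HYDROPHOBIC;
    * anything left unclassified -> NEUTRAL.
    """
    if index < 0 or index >= bonds.n_atoms:
        raise ValueError(f"atom index {index} not in bond graph")
    atom = bonds.atoms[index]
    el = atom.element
    classes: set[Pharmacophore] = set()
    aromatic = index in bonds.aromatic_atoms()
    if aromatic:
        classes.add(Pharmacophore.AROMATIC)
    neighbors = bonds.neighbors(index)
    if el == "O":
        if _is_acidic_terminal_oxygen(index, bonds):
            classes.update({Pharmacophore.NEGATIVE, Pharmacophore.H_ACCEPTOR})
        else:
            classes.add(Pharmacophore.H_ACCEPTOR)
    elif el == "N":
        if aromatic:
            if len(neighbors) <= 2:
                classes.add(Pharmacophore.H_ACCEPTOR)
        elif any(_is_carbonyl_carbon(j, bonds) for j in neighbors):
            classes.add(Pharmacophore.H_DONOR)  # amide-like
        else:
            classes.update({Pharmacophore.POSITIVE, Pharmacophore.H_DONOR})
    elif el in ("S", "Se"):
        classes.add(Pharmacophore.SULFUR)
    elif el == "C" or el in _HALOGENS:
        classes.add(Pharmacophore.HYDROPHOBIC)
    if not classes:
        classes.add(Pharmacophore.NEUTRAL)
    return frozenset(classes)


def _is_carbonyl_carbon(index: int, bonds) -> bool:
    """Carbon with at least one terminal oxygen neighbour."""
    if bonds.atoms[index].element != "C":
        return False
    return any(
        bonds.atoms[j].element == "O" and len(bonds.neighbors(j)) == 1
        for j in bonds.neighbors(index)
    )


def _is_acidic_terminal_oxygen(index: int, bonds) -> bool:
    """Terminal O on a C/P/S centre that carries >= 2 terminal oxygens.

    Covers carboxylates, phosphates and sulfates, which are deprotonated
    at physiological pH.
    """
    if len(bonds.neighbors(index)) != 1:
        return False
    (center,) = bonds.neighbors(index)
    if bonds.atoms[center].element not in ("C", "P", "S"):
        return False
    terminal_oxygens = sum(
        1
        for j in bonds.neighbors(center)
        if bonds.atoms[j].element == "O" and len(bonds.neighbors(j)) == 1
    )
    return terminal_oxygens >= 2


#: Heavy-atom composition of the canonical residues (backbone + side chain),
#: used for exhaustiveness checks of the bundled table.
_BACKBONE = ("N", "CA", "C", "O")
CANONICAL_RESIDUE_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": _BACKBONE + ("CB",),
    "ARG": _BACKBONE + ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": _BACKBONE + ("CB", "CG", "OD1", "ND2"),
    "ASP": _BACKBONE + ("CB", "CG", "OD1", "OD2"),
    "CYS": _BACKBONE + ("CB", "SG"),
    "GLN": _BACKBONE + ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": _BACKBONE + ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": _BACKBONE,
    "HIS": _BACKBONE + ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": _BACKBONE + ("CB", "CG1", "CG2", "CD1"),
    "LEU": _BACKBONE + ("CB", "CG", "CD1", "CD2"),
    "LYS": _BACKBONE + ("CB", "CG", "CD", "CE", "NZ"),
    "MET": _BACKBONE + ("CB", "CG", "SD", "CE"),
    "PHE": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": _BACKBONE + ("CB", "CG", "CD"),
    "SER": _BACKBONE + ("CB", "OG"),
    "THR": _BACKBONE + ("CB", "OG1", "CG2"),
    "TRP": _BACKBONE
    + ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": _BACKBONE + ("CB", "CG1", "CG2"),
    "MSE": _BACKBONE + ("CB", "CG", "SE", "CE"),
}
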