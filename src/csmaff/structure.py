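"""Parsing and cleanup of protein--small-molecule complexes in PDB format.

A complex is split into protein atoms (ATOM records with a standard
amino-acid residue name) and heteroatom groups (everything else).  Cleanup
follows the training-data convention for structure-based affinity
prediction: crystallographic waters are removed, only the first MODEL of a
multi-model file is kept, and alternate locations are resolved to a single
copy per atom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "LigandSelection",
    "ModelPolicy",
    "PDBParseError",
    "LigandSelectionError",
    "RecordClass",
    "parse_complex",
    "select_ligand",
    "transform_complex",
    "write_pdb",
    "STANDARD_AMINO_ACIDS",
    "WATER_RESIDUE_NAMES",
]

#: Canonical amino acids plus selenomethionine (mapped to protein class,
#: common in PDBbind-era crystal structures).
STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "MSE",
    }
)

#: Water residue-name dialects removed during cleanup.
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "DOD"})


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted as a complex."""


class LigandSelectionError(ValueError):
    """Raised when no valid ligand can be designated."""


class RecordClass(enum.Enum):
    PROTEIN = "PROTEIN"
    HET = "HET"


class ModelPolicy(enum.Enum):
    """How to treat multi-MODEL (NMR-style) files."""

    FIRST = "first"


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a parsed complex (a node of the structure graph)."""

    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    record_class: RecordClass
    occupancy: float = 1.0
    alt_loc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=np.float64)


# Key identifying one heteroatom group: (chain, residue_name, residue_seq).
HetKey = tuple[str, str, int]


@dataclass
class ComplexStructure:
    """A cleaned complex: protein atoms plus grouped heteroatoms."""

    protein_atoms: list[AtomRecord]
    het_groups: dict[HetKey, list[AtomRecord]]
    source_id: str = ""

    def all_atoms(self) -> list[AtomRecord]:
        atoms = list(self.protein_atoms)
        for group in self.het_groups.values():
            atoms.extend(group)
        return atoms


@dataclass
class LigandSelection:
    """The heteroatom group designated as the small-molecule ligand."""

    ligand_atoms: list[AtomRecord]
    ligand_key: HetKey

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.ligand_atoms if not a.is_hydrogen]


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Fallback element inference from the atom-name column."""
    name = atom_name.strip()
    if not name:
        return ""
    stripped = "".join(c for c in name if c.isalpha())
    if len(stripped) >= 2 and stripped[:2].upper() in (
        "CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE", "CA",
    ):
        # Two-letter elements only trusted for het groups; protein "CA" is
        # an alpha carbon, never calcium.
        if residue_name not in STANDARD_AMINO_ACIDS:
            return stripped[:2].capitalize()
    return stripped[0].upper()


def parse_complex(
    pdb_text: str,
    model_policy: ModelPolicy = ModelPolicy.FIRST,
    source_id: str = "",
) -> ComplexStructure:
    """Parse PDB text into a cleaned :class:`ComplexStructure`.

    Cleanup applied: waters (HOH/WAT/DOD) removed; only the first MODEL
    kept; alternate locations resolved by highest occupancy (tie: alt_loc
    'A', then first seen).  Hydrogens are retained but flagged via
    :attr:`AtomRecord.is_hydrogen`.

    Raises
    ------
    PDBParseError
        If the text contains no ATOM/HETATM records or a coordinate field
        is unreadable (the underlying reader reports the line).
    """
    if model_policy is not ModelPolicy.FIRST:  # pragma: no cover - enum guard
        raise ValueError(f"unsupported model policy: {model_policy}")
    _validate_coordinate_fields(pdb_text, source_id)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{source_id or '<pdb>'}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{source_id or '<pdb>'}: no ATOM or HETATM records found")
    model = st[0]  # FIRST-model policy

    # Collect atoms; resolve altlocs per (chain, resseq, resname, atom name).
    chosen: dict[tuple[str, int, str, str], AtomRecord] = {}
    order: list[tuple[str, int, str, str]] = []
    n_records = 0
    for chain in model:
        for residue in chain:
            resname = residue.name.strip()
            if resname in WATER_RESIDUE_NAMES:
                continue
            is_atom_record = residue.het_flag == "A"
            rc = (
                RecordClass.PROTEIN
                if is_atom_record and resname in STANDARD_AMINO_ACIDS
                else RecordClass.HET
            )
            for atom in residue:
                n_records += 1
                element = atom.element.name if not atom.element.is_metal or True else ""
                if element in ("", "X"):
                    element = _infer_element(atom.name, resname)
                rec = AtomRecord(
                    atom_name=atom.name.strip(),
                    element=element,
                    residue_name=resname,
                    residue_seq=residue.seqid.num,
                    chain_id=(chain.name or " ").strip() or "A",
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    record_class=rc,
                    occupancy=float(atom.occ),
                    alt_loc=(atom.altloc or "").replace("\x00", "").strip(),
                )
                if not all(np.isfinite(rec.xyz)):
                    raise PDBParseError(
                        f"{source_id or '<pdb>'}: non-finite coordinates for atom "
                        f"{rec.atom_name} in {resname} {rec.residue_seq}"
                    )
                key = (rec.chain_id, rec.residue_seq, resname, rec.atom_name)
                prev = chosen.get(key)
                if prev is None:
                    chosen[key] = rec
                    order.append(key)
                else:
                    chosen[key] = _resolve_altloc(prev, rec)
    if n_records == 0:
        raise PDBParseError(f"{source_id or '<pdb>'}: no ATOM or HETATM records found")

    protein_atoms: list[AtomRecord] = []
    het_groups: dict[HetKey, list[AtomRecord]] = {}
    for key in order:
        rec = chosen[key]
        if rec.record_class is RecordClass.PROTEIN:
            protein_atoms.append(rec)
        else:
            hkey: HetKey = (rec.chain_id, rec.residue_name, rec.residue_seq)
            het_groups.setdefault(hkey, []).append(rec)
    return ComplexStructure(
        protein_atoms=protein_atoms, het_groups=het_groups, source_id=source_id
    )


def _validate_coordinate_fields(pdb_text: str, source_id: str) -> None:
    """Reject unreadable coordinate fields, naming the offending line.

    The underlying reader is lenient about malformed numbers, so the
    fixed-width x/y/z columns are checked explicitly first.
    """
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(
                f"{source_id or '<pdb>'}: line {lineno}: record too short "
                "for coordinate fields"
            )
        for lo, hi, axis in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            field = line[lo:hi]
            try:
                float(field)
            except ValueError:
                raise PDBParseError(
                    f"{source_id or '<pdb>'}: line {lineno}: unreadable "
                    f"{axis} coordinate {field.strip()!r}"
                ) from None


def _resolve_altloc(a: AtomRecord, b: AtomRecord) -> AtomRecord:
    """Keep the higher-occupancy copy; tie -> alt_loc 'A', then first seen."""
    if b.occupancy > a.occupancy:
        return b
    if b.occupancy < a.occupancy:
        return a
    if a.alt_loc == "A":
        return a
    if b.alt_loc == "A":
        return b
    return a


def select_ligand(
    complex: ComplexStructure, ligand_key: HetKey | None = None
) -> LigandSelection:
    """Designate one heteroatom group as the ligand.

    When ``ligand_key`` is omitted the group with the most heavy atoms wins
    (tie broken by chain then residue number).  Atoms are returned in a
    canonical order (sorted by atom name) so downstream computation is
    independent of the record order in the source file.
    """
    if not complex.het_groups:
        raise LigandSelectionError(
            f"{complex.source_id or '<complex>'}: no ligand present "
            "(no heteroatom groups after cleanup)"
        )
    if ligand_key is not None:
        if ligand_key not in complex.het_groups:
            available = sorted(complex.het_groups)
            raise LigandSelectionError(
                f"ligand key {ligand_key!r} not found; available: {available}"
            )
        key = ligand_key
    else:
        def rank(k: HetKey) -> tuple[int, str, int]:
            heavy = sum(1 for a in complex.het_groups[k] if not a.is_hydrogen)
            return (-heavy, k[0], k[2])

        key = min(complex.het_groups, key=rank)
    atoms = sorted(complex.het_groups[key], key=lambda a: a.atom_name)
    return LigandSelection(ligand_atoms=atoms, ligand_key=key)


def transform_complex(
    complex: ComplexStructure,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> ComplexStructure:
    """Apply an exact (float64) rigid motion to every atom in memory.

    Unlike the text-level transform in :mod:`csmaff.synthetic`, this does
    not quantise coordinates, so pairwise distances are preserved to
    machine precision.
    """
    R = np.asarray(rotation, dtype=np.float64)
    t = np.asarray(translation, dtype=np.float64)
    _check_rotation(R)

    def move(a: AtomRecord) -> AtomRecord:
        new = R @ a.xyz + t
        return replace(a, coords=(float(new[0]), float(new[1]), float(new[2])))

    return ComplexStructure(
        protein_atoms=[move(a) for a in complex.protein_atoms],
        het_groups={k: [move(a) for a in v] for k, v in complex.het_groups.items()},
        source_id=complex.source_id,
    )


def _check_rotation(R: np.ndarray, tol: float = 1e-9) -> None:
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol) or abs(
        np.linalg.det(R) - 1.0
    ) > tol:
        raise ValueError("rotation must be orthonormal with determinant 1")


def _format_atom_name(name: str, element: str) -> str:
    """PDB atom-name column alignment (element right-justified in 13-14)."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and not name[:1].isdigit():
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(complex: ComplexStructure, ligand: LigandSelection | None = None) -> str:
    """Serialize retained atoms back to PDB text (debugging / round-trips).

    When ``ligand`` is given only protein atoms plus that ligand are
    written; otherwise all retained atoms.
    """
    lines: list[str] = []
    serial = 0
    atoms: list[tuple[str, AtomRecord]] = [("ATOM", a) for a in complex.protein_atoms]
    if ligand is not None:
        atoms += [("HETATM", a) for a in ligand.ligand_atoms]
    else:
        for group in complex.het_groups.values():
            atoms += [("HETATM", a) for a in group]
    for record, a in atoms:
        serial += 1
        x, y, z = a.coords
        lines.append(
            f"{record:<6s}{serial:>5d} {_format_atom_name(a.atom_name, a.element):4s}"
            f"{a.alt_loc or ' ':1s}{a.residue_name:>3s} {a.chain_id:1s}"
            f"{a.residue_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
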