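"""Ligand physicochemical descriptors appended to the structural signature.

PDB HETATM records carry coordinates but no bonds, so the molecular graph
is perceived geometrically (covalent radii plus a tolerance) and converted
to an RDKit molecule for descriptor evaluation.  When an SDF/MOL2 sidecar
with explicit chemistry is available it overrides perception.

The twelve-descriptor panel is the standard physicochemical set computable
from a molecular graph: size, lipophilicity, polarity, flexibility,
ring content, charge and saturation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Geometry import Point3D

from .structure import AtomRecord, LigandSelection

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "BondGraph",
    "LigandDescriptors",
    "DESCRIPTOR_NAMES",
    "perceive_bonds",
    "bond_graph_from_mol",
    "compute_descriptors",
    "BOND_TOLERANCE",
]

#: Extra slack over the sum of covalent radii when perceiving bonds (A);
#: permissive enough for typical crystallographic coordinate error.
BOND_TOLERANCE = 0.45

#: Single-bond covalent radii in Angstrom (Cordero-style consensus values).
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Se": 1.20, "Br": 1.20,
    "I": 1.39,
}
_DEFAULT_RADIUS = 1.5  # metals / unknowns: generous

#: Fixed descriptor order; this is part of the feature schema.
DESCRIPTOR_NAMES = (
    "molecular_weight",
    "heavy_atom_count",
    "logp",
    "tpsa",
    "h_bond_donors",
    "h_bond_acceptors",
    "rotatable_bonds",
    "ring_count",
    "aromatic_ring_count",
    "formal_charge",
    "fraction_csp3",
    "molar_refractivity",
)

#: Max deviation (A) from the best-fit plane for a ring to count as
#: aromatic in geometric perception.
_PLANARITY_TOL = 0.15


@dataclass
class BondGraph:
    """Symmetric adjacency over the ligand's heavy atoms.

    ``orders[(i, j)]`` (i < j) holds a bond-order estimate: 1 unless a
    geometric heuristic or an explicit sidecar says otherwise.
    """

    atoms: list[AtomRecord]
    edges: set[tuple[int, int]]
    orders: dict[tuple[int, int], float] = field(default_factory=dict)
    explicit: bool = False  # True when bonds came from an SDF/MOL2 sidecar
    _adj: dict[int, tuple[int, ...]] | None = field(default=None, repr=False)
    _aromatic: frozenset[int] | None = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> tuple[int, ...]:
        if self._adj is None:
            adj: dict[int, list[int]] = {k: [] for k in range(self.n_atoms)}
            for a, b in self.edges:
                adj[a].append(b)
                adj[b].append(a)
            self._adj = {k: tuple(sorted(v)) for k, v in adj.items()}
        return self._adj[i]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.edges)
        return g

    def aromatic_atoms(self) -> frozenset[int]:
        """Indices of atoms in planar 5/6-membered C/N/O/S rings."""
        if self._aromatic is None:
            aromatic: set[int] = set()
            g = self.to_networkx()
            for ring in nx.minimum_cycle_basis(g):
                if len(ring) not in (5, 6):
                    continue
                if any(self.atoms[i].element not in ("C", "N", "O", "S") for i in ring):
                    continue
                coords = np.array([self.atoms[i].xyz for i in ring])
                if _max_plane_deviation(coords) <= _PLANARITY_TOL:
                    aromatic.update(ring)
            self._aromatic = frozenset(aromatic)
        return self._aromatic


def _max_plane_deviation(coords: np.ndarray) -> float:
    centered = coords - coords.mean(axis=0)
    # smallest singular direction = plane normal
    _, _, vt = np.linalg.svd(centered)
    return float(np.abs(centered @ vt[-1]).max())


def perceive_bonds(ligand: LigandSelection) -> BondGraph:
    """Perceive the ligand bond graph from heavy-atom geometry.

    An edge joins two atoms whose distance is at most the sum of their
    covalent radii plus :data:`BOND_TOLERANCE`.  A disconnected result is
    kept (some ligands are salts) but warned about.
    """
    atoms = ligand.heavy_atoms()
    if not atoms:
        raise ValueError("ligand has no heavy atoms")
    coords = np.array([a.xyz for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, _DEFAULT_RADIUS) for a in atoms])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    thresh = radii[:, None] + radii[None, :] + BOND_TOLERANCE
    edges = {
        (i, j)
        for i in range(len(atoms))
        for j in range(i + 1, len(atoms))
        if dist[i, j] <= thresh[i, j]
    }
    graph = BondGraph(atoms=atoms, edges=edges)
    n_comp = nx.number_connected_components(graph.to_networkx())
    if n_comp > 1:
        warnings.warn(
            f"perceived ligand graph has {n_comp} connected components",
            stacklevel=2,
        )
    return graph


def bond_graph_from_mol(ligand: LigandSelection, mol: Chem.Mol) -> BondGraph:
    """Build a BondGraph from an explicit-chemistry sidecar molecule.

    Atom correspondence is positional: the sidecar's heavy atoms must be
    the same chemical entity; they are matched to ligand atoms by nearest
    coordinates when a conformer is present, else by order.
    """
    atoms = ligand.heavy_atoms()
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if len(heavy) != len(atoms):
        raise ValueError(
            f"sidecar has {len(heavy)} heavy atoms, ligand has {len(atoms)}"
        )
    if mol.GetNumConformers():
        conf = mol.GetConformer()
        lig_xyz = np.array([a.xyz for a in atoms])
        mapping = {}
        for a in heavy:
            p = conf.GetAtomPosition(a.GetIdx())
            d = np.linalg.norm(lig_xyz - np.array([p.x, p.y, p.z]), axis=1)
            mapping[a.GetIdx()] = int(np.argmin(d))
    else:
        mapping = {a.GetIdx(): k for k, a in enumerate(heavy)}
    edges = set()
    orders = {}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i not in mapping or j not in mapping:
            continue  # bond to hydrogen
        e = tuple(sorted((mapping[i], mapping[j])))
        edges.add(e)
        orders[e] = b.GetBondTypeAsDouble()
    return BondGraph(atoms=atoms, edges=edges, orders=orders, explicit=True)


# --- RDKit molecule construction ----------------------------------------


def _assign_geometric_bond_orders(graph: BondGraph) -> dict[tuple[int, int], float]:
    """Heuristic bond orders for perceived graphs.

    Only the unambiguous geometric cues are used: a terminal oxygen within
    1.28 A of a C/P/S centre is a double bond (carbonyl-like); when a
    centre has several such oxygens only the shortest becomes double and
    the rest stay single with formal charge -1 (handled by the caller).
    Aromatic rings are flagged separately.
    """
    orders: dict[tuple[int, int], float] = {e: 1.0 for e in graph.edges}
    by_center: dict[int, list[tuple[float, tuple[int, int], int]]] = {}
    for i, atom in enumerate(graph.atoms):
        if atom.element != "O" or len(graph.neighbors(i)) != 1:
            continue
        (c,) = graph.neighbors(i)
        if graph.atoms[c].element not in ("C", "P", "S"):
            continue
        d = float(np.linalg.norm(atom.xyz - graph.atoms[c].xyz))
        if d <= 1.28:
            e = tuple(sorted((i, c)))
            by_center.setdefault(c, []).append((d, e, i))
    for entries in by_center.values():
        entries.sort()
        orders[entries[0][1]] = 2.0  # shortest short C=O
    return orders


def build_rdkit_mol(graph: BondGraph) -> Chem.Mol:
    """Convert a BondGraph into a sanitized RDKit molecule.

    Hydrogens absent from the heavy-atom record are left implicit; the
    valence model fills them in.  Aromatic rings detected geometrically
    are marked aromatic.  If full sanitization fails the molecule falls
    back to a connectivity-only form (descriptors then reflect the
    single-bond skeleton).
    """
    rw = Chem.RWMol()
    conf = Chem.Conformer(graph.n_atoms)
    for i, atom in enumerate(graph.atoms):
        a = Chem.Atom(atom.element)
        rw.AddAtom(a)
        conf.SetAtomPosition(i, Point3D(*atom.coords))
    orders = dict(graph.orders) if graph.explicit else _assign_geometric_bond_orders(graph)
    aromatic = graph.aromatic_atoms() if not graph.explicit else frozenset()
    bond_type = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for (i, j) in sorted(graph.edges):
        if not graph.explicit and i in aromatic and j in aromatic:
            rw.AddBond(i, j, Chem.BondType.AROMATIC)
            rw.GetAtomWithIdx(i).SetIsAromatic(True)
            rw.GetAtomWithIdx(j).SetIsAromatic(True)
        else:
            rw.AddBond(i, j, bond_type.get(orders.get((i, j), 1.0), Chem.BondType.SINGLE))
    if not graph.explicit:
        _apply_anion_charges(rw, graph, orders)
    mol = rw.GetMol()
    mol.AddConformer(conf)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        mol = rw.GetMol()
        for a in mol.GetAtoms():
            a.SetNoImplicit(True)
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
            catchErrors=True,
        )
    return mol


def _apply_anion_charges(rw: Chem.RWMol, graph: BondGraph, orders) -> None:
    """Give -1 to the single-bonded terminal O of carboxylate-like groups."""
    for i, atom in enumerate(graph.atoms):
        if atom.element != "O" or len(graph.neighbors(i)) != 1:
            continue
        (c,) = graph.neighbors(i)
        if graph.atoms[c].element not in ("C", "P", "S"):
            continue
        e = tuple(sorted((i, c)))
        siblings = [
            j
            for j in graph.neighbors(c)
            if graph.atoms[j].element == "O" and len(graph.neighbors(j)) == 1
        ]
        has_double_sibling = any(
            orders.get(tuple(sorted((j, c)))) == 2.0 for j in siblings
        )
        d = float(np.linalg.norm(atom.xyz - graph.atoms[c].xyz))
        if orders.get(e) == 1.0 and has_double_sibling and d <= 1.32:
            rw.GetAtomWithIdx(i).SetFormalCharge(-1)


@dataclass(frozen=True)
class LigandDescriptors:
    """The fixed-order physicochemical descriptor block."""

    values: dict[str, float]

    def __post_init__(self):
        missing = set(DESCRIPTOR_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing descriptors: {sorted(missing)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in DESCRIPTOR_NAMES], dtype=np.float64)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def compute_descriptors(
    ligand: LigandSelection, bonds: BondGraph | None = None
) -> LigandDescriptors:
    """Compute the twelve-descriptor panel for one ligand.

    Hydrogens are inferred implicitly from valence when absent.  The
    computation is deterministic: it depends only on the (canonically
    ordered) ligand atoms and the bond graph.
    """
    if not ligand.heavy_atoms():
        raise ValueError("cannot compute descriptors for an empty ligand")
    if bonds is None:
        bonds = perceive_bonds(ligand)
    mol = build_rdkit_mol(bonds)
    values = {
        "molecular_weight": float(Descriptors.MolWt(mol)),
        "heavy_atom_count": float(mol.GetNumHeavyAtoms()),
        "logp": float(Crippen.MolLogP(mol)),
        "tpsa": float(rdMolDescriptors.CalcTPSA(mol)),
        "h_bond_donors": float(Lipinski.NumHDonors(mol)),
        "h_bond_acceptors": float(Lipinski.NumHAcceptors(mol)),
        "rotatable_bonds": float(Lipinski.NumRotatableBonds(mol)),
        "ring_count": float(rdMolDescriptors.CalcNumRings(mol)),
        "aromatic_ring_count": float(rdMolDescriptors.CalcNumAromaticRings(mol)),
        "formal_charge": float(Chem.GetFormalCharge(mol)),
        "fraction_csp3": float(rdMolDescriptors.CalcFractionCSP3(mol)),
        "molar_refractivity": float(Crippen.MolMR(mol)),
    }
    return LigandDescriptors(values=values)
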