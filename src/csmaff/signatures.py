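"""Cutoff-scanning structural signatures of protein--ligand complexes.

The complex is modelled as a graph whose nodes are heavy atoms labelled
with pharmacophore classes.  For every unordered class pair and every
distance cutoff on a regular grid, the signature counts the atom pairs
whose Euclidean distance is at most the cutoff — a cumulative distance
distribution per class pair.  Two blocks are computed: pairs among the
binding-pocket atoms, and protein--ligand cross pairs; the ligand's
physicochemical descriptor panel is appended.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from . import descriptors as _desc
from . import pharmacophore as _ph
from .pharmacophore import Pharmacophore
from .structure import (
    AtomRecord,
    ComplexStructure,
    LigandSelection,
    parse_complex,
    select_ligand,
)

__all__ = [
    "SignatureConfig",
    "SignatureVector",
    "PocketAtoms",
    "Normalization",
    "extract_pocket",
    "cutoff_scan",
    "build_signature",
    "CSMFeaturizer",
    "CLASS_PAIRS",
    "signature_schema",
]

#: The 36 unordered pairs over the 8 pharmacophore classes, in fixed
#: lexicographic order of the enum ordinals.  This order defines the
#: feature layout.
CLASS_PAIRS: tuple[tuple[Pharmacophore, Pharmacophore], ...] = tuple(
    (a, b)
    for a in Pharmacophore
    for b in Pharmacophore
    if a <= b
)
_PAIR_INDEX = {p: k for k, p in enumerate(CLASS_PAIRS)}


class Normalization(str, enum.Enum):
    RAW_COUNTS = "raw_counts"
    PER_PAIRCOUNT = "per_paircount"


@dataclass(frozen=True)
class SignatureConfig:
    """Geometry and grid parameters of the cutoff scan.

    Defaults follow the dense short-to-medium-range scanning convention
    of cutoff-scanning signatures: an 8 A pocket and a 1–30 A grid in
    0.5 A steps.
    """

    pocket_radius: float = 8.0
    d_min: float = 1.0
    d_max: float = 30.0
    step: float = 0.5
    heavy_atoms_only: bool = True
    normalize: Normalization = Normalization.RAW_COUNTS
    typing_table_version: str = _ph.TYPING_TABLE_VERSION

    def __post_init__(self):
        if not (0 < self.d_min < self.d_max):
            raise ValueError("require 0 < d_min < d_max")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.pocket_radius <= 0:
            raise ValueError("pocket_radius must be positive")
        if len(self.cutoffs()) < 2:
            raise ValueError("cutoff grid must have at least 2 points")

    def cutoffs(self) -> np.ndarray:
        n = int(np.floor((self.d_max - self.d_min) / self.step + 1e-9)) + 1
        return self.d_min + self.step * np.arange(n)

    def hash(self) -> str:
        payload = repr(
            (
                self.pocket_radius,
                self.d_min,
                self.d_max,
                self.step,
                self.heavy_atoms_only,
                str(self.normalize.value),
                self.typing_table_version,
                _desc.DESCRIPTOR_NAMES,
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PocketAtoms:
    """Protein heavy atoms within the pocket radius of the ligand."""

    atoms: list[AtomRecord]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class SignatureVector:
    """The final feature vector with its positional schema."""

    values: np.ndarray
    schema: tuple[str, ...]
    config_hash: str

    def __post_init__(self):
        if len(self.values) != len(self.schema):
            raise ValueError("values and schema lengths differ")


def signature_schema(config: SignatureConfig) -> tuple[str, ...]:
    """Ordered feature names: pocket block, cross block, descriptors."""
    cutoffs = config.cutoffs()
    names: list[str] = []
    for block in ("pocket", "cross"):
        for a, b in CLASS_PAIRS:
            for c in cutoffs:
                names.append(f"{block}|{a.name}-{b.name}|{c:.2f}")
    names.extend(_desc.DESCRIPTOR_NAMES)
    return tuple(names)


def extract_pocket(
    complex: ComplexStructure,
    ligand: LigandSelection,
    config: SignatureConfig | None = None,
) -> PocketAtoms:
    """Protein atoms with min distance to any ligand atom <= pocket_radius.

    The boundary is closed (an atom exactly at the radius is included) and
    the returned order follows the protein atom order of the complex.
    """
    config = config or SignatureConfig()
    protein = [
        a
        for a in complex.protein_atoms
        if not (config.heavy_atoms_only and a.is_hydrogen)
    ]
    lig_atoms = ligand.heavy_atoms() if config.heavy_atoms_only else ligand.ligand_atoms
    if not protein or not lig_atoms:
        raise ValueError("empty protein or ligand atom set")
    P = np.array([a.xyz for a in protein])
    L = np.array([a.xyz for a in lig_atoms])
    dmin = cdist(P, L).min(axis=1)
    keep = dmin <= config.pocket_radius
    if not keep.any():
        raise ValueError(
            "ligand appears isolated from protein "
            f"(min observed distance {dmin.min():.2f} A > pocket radius "
            f"{config.pocket_radius:.2f} A)"
        )
    return PocketAtoms(atoms=[a for a, k in zip(protein, keep) if k])


def cutoff_scan(
    pairs, config: SignatureConfig | None = None
) -> np.ndarray:
    """Cumulative per-class-pair distance counts over the cutoff grid.

    ``pairs`` is an iterable of ``((class_a, class_b), distance)`` where
    the class pair is unordered.  Returns an array of shape
    ``(36, n_cutoffs)``: entry ``[k, c]`` counts pairs of class-pair ``k``
    with distance <= cutoff ``c``.  Distances beyond ``d_max`` fall in no
    bin.
    """
    config = config or SignatureConfig()
    cutoffs = config.cutoffs()
    buckets: list[list[float]] = [[] for _ in CLASS_PAIRS]
    for (a, b), d in pairs:
        if d < 0:
            raise ValueError(f"negative pair distance: {d}")
        key = (a, b) if a <= b else (b, a)
        buckets[_PAIR_INDEX[(Pharmacophore(key[0]), Pharmacophore(key[1]))]].append(d)
    out = np.zeros((len(CLASS_PAIRS), len(cutoffs)), dtype=np.float64)
    for k, ds in enumerate(buckets):
        if ds:
            sorted_d = np.sort(np.asarray(ds))
            out[k] = np.searchsorted(sorted_d, cutoffs, side="right")
    return out


def _class_indicator(class_sets) -> np.ndarray:
    M = np.zeros((len(class_sets), len(Pharmacophore)), dtype=bool)
    for i, s in enumerate(class_sets):
        for c in s:
            M[i, int(c)] = True
    return M


def _count_block(
    dist: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    cutoffs: np.ndarray,
    symmetric: bool,
) -> np.ndarray:
    """Vectorised cumulative counts for one block.

    ``dist`` is the (n, m) distance matrix; ``rows``/``cols`` are boolean
    class-indicator matrices.  For the symmetric (pocket-internal) case
    only i<j pairs are counted.  A pair of atoms whose class sets admit a
    given unordered class combination increments that combination exactly
    once, regardless of multiplicity.
    """
    n, m = dist.shape
    tri = np.triu(np.ones((n, m), dtype=bool), k=1) if symmetric else None
    out = np.zeros((len(CLASS_PAIRS), len(cutoffs)), dtype=np.float64)
    for k, (a, b) in enumerate(CLASS_PAIRS):
        mask = np.outer(rows[:, int(a)], cols[:, int(b)])
        if a != b:
            mask |= np.outer(rows[:, int(b)], cols[:, int(a)])
        if symmetric:
            mask &= tri
        d = dist[mask]
        if d.size:
            out[k] = np.searchsorted(np.sort(d), cutoffs, side="right")
    return out


def build_signature(
    complex: ComplexStructure,
    ligand: LigandSelection,
    descriptors: _desc.LigandDescriptors | None = None,
    config: SignatureConfig | None = None,
    reference_schema: tuple[str, ...] | None = None,
    typing_table: _ph.TypingTable | None = None,
) -> SignatureVector:
    """Assemble the full signature for one complex.

    Layout: pocket-internal cumulative-count block (pairs among pocket
    atoms), then the protein--ligand cross block (pocket atom x ligand
    atom pairs), then the ligand descriptor panel.  A
    ``reference_schema`` (e.g. from a trained model) guards against
    train/predict layout skew.
    """
    config = config or SignatureConfig()
    table = typing_table or _ph.load_typing_table(config.typing_table_version)
    schema = signature_schema(config)
    if reference_schema is not None and tuple(reference_schema) != schema:
        raise ValueError(
            "signature schema mismatch against reference schema "
            f"({len(schema)} vs {len(reference_schema)} features)"
        )
    cutoffs = config.cutoffs()
    pocket = extract_pocket(complex, ligand, config)
    lig_atoms = ligand.heavy_atoms() if config.heavy_atoms_only else ligand.ligand_atoms

    bonds = _desc.perceive_bonds(ligand)
    pocket_classes = [_ph.type_protein_atom(a, table) for a in pocket.atoms]
    ligand_classes = [_ph.type_ligand_atom(i, bonds) for i in range(len(lig_atoms))]

    P = np.array([a.xyz for a in pocket.atoms])
    L = np.array([a.xyz for a in lig_atoms])
    rows = _class_indicator(pocket_classes)
    lcols = _class_indicator(ligand_classes)

    d_pp = cdist(P, P)
    d_pl = cdist(P, L)
    pocket_block = _count_block(d_pp, rows, rows, cutoffs, symmetric=True)
    cross_block = _count_block(d_pl, rows, lcols, cutoffs, symmetric=False)

    if config.normalize is Normalization.PER_PAIRCOUNT:
        n = len(pocket.atoms)
        n_pp = n * (n - 1) // 2
        n_pl = n * len(lig_atoms)
        if n_pp:
            pocket_block = pocket_block / n_pp
        if n_pl:
            cross_block = cross_block / n_pl

    if descriptors is None:
        descriptors = _desc.compute_descriptors(ligand, bonds)
    values = np.concatenate(
        [pocket_block.ravel(), cross_block.ravel(), descriptors.as_array()]
    )
    return SignatureVector(values=values, schema=schema, config_hash=config.hash())


class CSMFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer from complexes to signature matrices.

    Accepts an iterable of PDB strings, filesystem paths, or
    ``(ComplexStructure, LigandSelection)`` tuples, and produces the
    stacked signature matrix.  Stateless apart from the configuration;
    ``fit`` records the feature schema.

    Parameters mirror :class:`SignatureConfig`.
    """

    def __init__(
        self,
        pocket_radius: float = 8.0,
        d_min: float = 1.0,
        d_max: float = 30.0,
        step: float = 0.5,
        heavy_atoms_only: bool = True,
        normalize: str = "raw_counts",
    ):
        self.pocket_radius = pocket_radius
        self.d_min = d_min
        self.d_max = d_max
        self.step = step
        self.heavy_atoms_only = heavy_atoms_only
        self.normalize = normalize

    def _config(self) -> SignatureConfig:
        return SignatureConfig(
            pocket_radius=self.pocket_radius,
            d_min=self.d_min,
            d_max=self.d_max,
            step=self.step,
            heavy_atoms_only=self.heavy_atoms_only,
            normalize=Normalization(self.normalize),
        )

    def fit(self, X=None, y=None):
        cfg = self._config()
        self.config_ = cfg
        self.feature_names_ = signature_schema(cfg)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit()
        sigs = [self.signature_for(item) for item in X]
        return np.vstack([s.values for s in sigs])

    def signature_for(self, item) -> SignatureVector:
        """Featurize one input item into a :class:`SignatureVector`."""
        if not hasattr(self, "config_"):
            self.fit()
        if isinstance(item, tuple) and isinstance(item[0], ComplexStructure):
            cplx, lig = item
        else:
            text, source = _as_pdb_text(item)
            cplx = parse_complex(text, source_id=source)
            lig = select_ligand(cplx)
        return build_signature(cplx, lig, config=self.config_)

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "feature_names_"):
            self.fit()
        return np.asarray(self.feature_names_, dtype=object)


def _as_pdb_text(item) -> tuple[str, str]:
    import os

    s = os.fspath(item) if not isinstance(item, str) else item
    if "\n" not in s and os.path.exists(s):
        with open(s) as fh:
            return fh.read(), os.path.basename(s)
    return s, ""
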