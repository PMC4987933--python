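"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorised counting
path: they are plain double loops over atom pairs, so they can serve as
an independent recount of the cumulative-distance signature blocks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from csmaff.pharmacophore import type_ligand_atom, type_protein_atom
from csmaff.descriptors import perceive_bonds
from csmaff.signatures import CLASS_PAIRS, SignatureConfig, extract_pocket
from csmaff.structure import parse_complex, select_ligand
from csmaff.synthetic import LigandTemplate, ToySpec, generate_toy_complex


# --- tiny hand-written PDB fixtures -------------------------------------

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  O   HOH A 101       5.000   0.000   0.000  1.00  0.00           O
END
"""

GLY_LIG_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
HETATM    4  C1  LIG A 900       4.000   0.000   0.000  1.00  0.00           C
HETATM    5  C2  LIG A 900       5.400   0.000   0.000  1.00  0.00           C
HETATM    6  O1  LIG A 900       4.000   1.300   0.000  1.00  0.00           O
HETATM    7  N1  LIG A 900       5.400   1.300   0.000  1.00  0.00           N
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
END
"""


@pytest.fixture
def toy_text() -> str:
    return generate_toy_complex(
        ToySpec(n_pocket_residues=5, ligand_template=LigandTemplate.BENZENE, seed=17)
    )


@pytest.fixture
def toy_complex(toy_text):
    cplx = parse_complex(toy_text, source_id="toy17")
    lig = select_ligand(cplx)
    return cplx, lig


@pytest.fixture
def small_config() -> SignatureConfig:
    return SignatureConfig()


# --- independent oracles -------------------------------------------------


def brute_force_pair_counts(class_sets, coords, cutoffs, class_sets_b=None, coords_b=None):
    """O(n^2 * grid) recount of cumulative class-pair distance counts.

    Symmetric (i<j within one set) when the second set is omitted, else
    the full rectangular cross product.  Multi-label atoms increment each
    unordered class combination of the pair exactly once.
    """
    counts = {pair: [0] * len(cutoffs) for pair in CLASS_PAIRS}
    pair_of = {(int(a), int(b)): (a, b) for (a, b) in CLASS_PAIRS}
    if class_sets_b is None:
        indices = [
            (i, j) for i in range(len(coords)) for j in range(i + 1, len(coords))
        ]
        get = lambda i, j: (class_sets[i], coords[i], class_sets[j], coords[j])
    else:
        indices = [
            (i, j) for i in range(len(coords)) for j in range(len(coords_b))
        ]
        get = lambda i, j: (class_sets[i], coords[i], class_sets_b[j], coords_b[j])
    for i, j in indices:
        si, ci, sj, cj = get(i, j)
        d = math.dist(ci, cj)
        combos = {tuple(sorted((int(a), int(b)))) for a in si for b in sj}
        for combo in combos:
            row = counts[pair_of[combo]]
            for k, c in enumerate(cutoffs):
                if d <= c:
                    row[k] += 1
    return counts


def brute_force_blocks(cplx, lig, config: SignatureConfig):
    """Recount both signature blocks for a complex with plain loops."""
    pocket = extract_pocket(cplx, lig, config)
    bonds = perceive_bonds(lig)
    lig_atoms = lig.heavy_atoms()
    p_classes = [type_protein_atom(a) for a in pocket.atoms]
    l_classes = [type_ligand_atom(i, bonds) for i in range(len(lig_atoms))]
    p_xyz = [tuple(a.coords) for a in pocket.atoms]
    l_xyz = [tuple(a.coords) for a in lig_atoms]
    cutoffs = config.cutoffs()
    pocket_counts = brute_force_pair_counts(p_classes, p_xyz, cutoffs)
    cross_counts = brute_force_pair_counts(p_classes, p_xyz, cutoffs, l_classes, l_xyz)
    return pocket_counts, cross_counts


def blocks_as_arrays(counts, cutoffs):
    return np.array([counts[pair] for pair in CLASS_PAIRS], dtype=np.float64)
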