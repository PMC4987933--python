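"""Synthetic toy complexes and labelled datasets for validation.

The generator builds well-formed PDB text for a small binding site: a
handful of real residues (ALA, LYS, ASP, PHE, SER) with idealized
internal geometry placed on a seeded random shell around a ligand
template at the origin, optionally with water and cofactor decoys for
cleanup tests.  Labels for recovery experiments come from a declared
linear model over true signature features plus Gaussian noise, giving a
known ground truth.

The geometry validates code paths, not chemistry: poses are not
physically realistic and template bond lengths are literature values
chosen to avoid pair distances landing exactly on the default cutoff
grid.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signatures import SignatureConfig, SignatureVector, signature_schema

__all__ = [
    "LigandTemplate",
    "ToySpec",
    "SyntheticLabelModel",
    "generate_toy_complex",
    "generate_labeled_dataset",
    "rigid_transform",
    "default_label_model",
    "random_rotation",
]


class LigandTemplate(str, enum.Enum):
    BENZENE = "benzene"
    ACETATE = "acetate"
    NEOPENTANE = "neopentane"


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one synthetic complex."""

    n_pocket_residues: int = 6
    ligand_template: LigandTemplate = LigandTemplate.BENZENE
    placement_radius: float = 5.5  # A from the origin to residue centroids
    n_waters: int = 0
    n_decoys: int = 0  # sulfate decoy groups (cofactor stand-ins)
    seed: int = 0

    def __post_init__(self):
        if self.n_pocket_residues < 1:
            raise ValueError("need at least one pocket residue")
        if self.placement_radius <= 2.0:
            raise ValueError("placement_radius must exceed 2 A")


# --- idealized geometry templates ---------------------------------------

_E1 = np.array([1.0, -1.0, 1.0]) / math.sqrt(3.0)
_E2 = np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0)


def _hexagon(center: np.ndarray, e1: np.ndarray, e2: np.ndarray, r: float):
    return [
        center + r * (math.cos(math.radians(t)) * e1 + math.sin(math.radians(t)) * e2)
        for t in (180.0, 120.0, 240.0, 60.0, 300.0, 0.0)
    ]


def _residue_template(name: str) -> list[tuple[str, str, np.ndarray]]:
    """(atom_name, element, local coordinates) for one residue."""
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    C = CA + np.array([0.551, 1.423, 0.0])
    O = C + np.array([-0.762, 0.964, 0.0])
    CB = CA + 0.880 * np.array([1.0, -1.0, 1.0])  # C-C 1.524
    atoms = [("N", "N", N), ("CA", "C", CA), ("C", "C", C), ("O", "O", O)]
    u = 0.880 * np.array([1.0, -1.0, 1.0])
    v = 0.880 * np.array([1.0, 1.0, -1.0])
    if name == "ALA":
        atoms += [("CB", "C", CB)]
    elif name == "SER":
        og = CB + 0.826 * np.array([1.0, -1.0, 1.0])
        atoms += [("CB", "C", CB), ("OG", "O", og)]
    elif name == "ASP":
        cg = CB + u
        od1 = cg + np.array([1.140, 0.510, 0.0])
        od2 = cg + np.array([0.0, -0.400, -1.183])
        atoms += [("CB", "C", CB), ("CG", "C", cg), ("OD1", "O", od1), ("OD2", "O", od2)]
    elif name == "LYS":
        cg = CB + u
        cd = cg + v
        ce = cd + u
        nz = ce + 0.849 * np.array([1.0, 1.0, -1.0])
        atoms += [("CB", "C", CB), ("CG", "C", cg), ("CD", "C", cd),
                  ("CE", "C", ce), ("NZ", "N", nz)]
    elif name == "PHE":
        cg = CB + 0.877 * np.array([1.0, -1.0, 1.0])
        ring = _hexagon(cg + 1.39 * _E1, _E1, _E2, 1.39)
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        atoms += [("CB", "C", CB)]
        atoms += [(n, "C", p) for n, p in zip(names, ring)]
    else:  # pragma: no cover - template list is fixed
        raise ValueError(f"no template for residue {name}")
    return atoms


_POCKET_RESIDUES = ("ALA", "LYS", "ASP", "PHE", "SER")


def _ligand_atoms(template: LigandTemplate) -> list[tuple[str, str, str, np.ndarray]]:
    """(atom_name, element, residue_name, coords) for the ligand at the origin."""
    if template is LigandTemplate.BENZENE:
        ring = _hexagon(np.zeros(3), np.array([1.0, 0.0, 0.0]),
                        np.array([0.0, 1.0, 0.0]), 1.39)
        return [(f"C{i+1}", "C", "BNZ", p) for i, p in enumerate(ring)]
    if template is LigandTemplate.ACETATE:
        return [
            ("C1", "C", "ACT", np.array([-1.517, 0.0, 0.0])),
            ("C2", "C", "ACT", np.array([0.0, 0.0, 0.0])),
            ("O1", "O", "ACT", np.array([0.617, 1.086, 0.0])),
            ("O2", "O", "ACT", np.array([0.617, -1.086, 0.0])),
        ]
    if template is LigandTemplate.NEOPENTANE:
        d = 0.8805
        offs = [(d, d, d), (d, -d, -d), (-d, d, -d), (-d, -d, d)]
        out = [("C1", "C", "NPT", np.zeros(3))]
        out += [(f"C{i+2}", "C", "NPT", np.array(o)) for i, o in enumerate(offs)]
        return out
    raise ValueError(f"unknown ligand template: {template}")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _pdb_atom_line(
    record: str, serial: int, name: str, resname: str, chain: str,
    resseq: int, xyz: np.ndarray, element: str,
) -> str:
    aligned = f" {name:<3s}" if len(element) == 1 and len(name) < 4 else f"{name:<4s}"
    return (
        f"{record:<6s}{serial:>5d} {aligned}{' '}{resname:>3s} {chain}"
        f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def generate_toy_complex(spec: ToySpec) -> str:
    """Deterministic, well-formed PDB text for one toy complex."""
    rng = np.random.default_rng(spec.seed)
    lig = _ligand_atoms(spec.ligand_template)
    lig_xyz = np.array([a[3] for a in lig])

    lines = [
        f"REMARK 300 SYNTHETIC TOY COMPLEX SEED {spec.seed}",
        f"REMARK 300 TEMPLATE {spec.ligand_template.value.upper()} "
        f"RESIDUES {spec.n_pocket_residues}",
    ]
    serial = 0
    resseq = 0
    # pocket residues on a jittered shell around the origin; the first
    # sits exactly at the placement radius so the pocket is never empty
    for res_i in range(spec.n_pocket_residues):
        resname = _POCKET_RESIDUES[rng.integers(len(_POCKET_RESIDUES))]
        template = _residue_template(resname)
        local = np.array([a[2] for a in template])
        local = local - local.mean(axis=0)
        for _attempt in range(50):
            R = random_rotation(rng)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = spec.placement_radius + (
                rng.uniform(0.0, 3.0) if res_i > 0 else 0.0
            )
            placed = local @ R.T + direction * dist
            gap = np.sqrt(
                ((placed[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(-1)
            ).min()
            if gap > 2.2:  # avoid steric collision with the ligand
                break
        resseq += 1
        for (name, element, _), xyz in zip(template, placed):
            serial += 1
            lines.append(
                _pdb_atom_line("ATOM", serial, name, resname, "A", resseq, xyz, element)
            )
    # ligand
    for name, element, resname, xyz in lig:
        serial += 1
        lines.append(
            _pdb_atom_line("HETATM", serial, name, resname, "A", 900, xyz, element)
        )
    # waters and cofactor decoys (exercise the cleanup rules)
    for w in range(spec.n_waters):
        serial += 1
        pos = rng.normal(size=3) * 3.0 + np.array([0.0, 0.0, 12.0])
        lines.append(
            _pdb_atom_line("HETATM", serial, "O", "HOH", "A", 901 + w, pos, "O")
        )
    for d in range(spec.n_decoys):
        center = rng.normal(size=3) * 2.0 + np.array([12.0, 0.0, 0.0])
        so4 = [("S", "S", np.zeros(3))] + [
            (f"O{i+1}", "O", 0.8487 * np.array(o))
            for i, o in enumerate([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)])
        ]
        for name, element, off in so4:
            serial += 1
            lines.append(
                _pdb_atom_line(
                    "HETATM", serial, name, "SO4", "A", 950 + d, center + off, element
                )
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- labelled datasets ---------------------------------------------------


@dataclass(frozen=True)
class SyntheticLabelModel:
    """Declared linear ground truth over signature features."""

    weights: dict[str, float]
    intercept: float = 5.0
    noise_sd: float = 0.3

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not all(math.isfinite(w) for w in self.weights.values()):
            raise ValueError("weights must be finite")

    def label(self, sig: SignatureVector, rng: np.random.Generator) -> float:
        index = {n: i for i, n in enumerate(sig.schema)}
        missing = [f for f in self.weights if f not in index]
        if missing:
            raise ValueError(f"label-model features outside the schema: {missing}")
        value = self.intercept + sum(
            w * sig.values[index[f]] for f, w in sorted(self.weights.items())
        )
        if self.noise_sd > 0:
            value += rng.normal(0.0, self.noise_sd)
        return float(value)


def default_label_model(
    config: SignatureConfig | None = None, noise_sd: float = 0.3
) -> SyntheticLabelModel:
    """Ground truth tied to protein--ligand contact density.

    Weights sit on cross-block cumulative counts at short-to-medium
    cutoffs, so affinity grows as the ligand sees a denser pocket; the
    scale gives labels a few pK units of spread, comparable to the
    dynamic range of curated affinity sets.
    """
    config = config or SignatureConfig()
    schema = set(signature_schema(config))
    wanted = {
        "cross|HYDROPHOBIC-HYDROPHOBIC|6.00": 0.045,
        "cross|HYDROPHOBIC-HYDROPHOBIC|10.00": 0.012,
        "cross|HYDROPHOBIC-H_ACCEPTOR|8.00": 0.018,
        "pocket|HYDROPHOBIC-HYDROPHOBIC|8.00": 0.005,
    }
    missing = [f for f in wanted if f not in schema]
    if missing:
        raise ValueError(f"default label features missing from schema: {missing}")
    return SyntheticLabelModel(weights=wanted, intercept=2.0, noise_sd=noise_sd)


def generate_labeled_dataset(
    n: int,
    spec: ToySpec | None = None,
    label_model: SyntheticLabelModel | None = None,
    seed: int = 0,
    config: SignatureConfig | None = None,
):
    """n toy complexes with varied geometry plus linear-model labels.

    Geometry varies per complex (residue count, shell radius), so the
    contact-count features span a real dynamic range.  Returns
    ``(pdb_texts, p_affinities, signatures)``.
    """
    if n < 10:
        raise ValueError("need n >= 10 for a meaningful dataset")
    from .signatures import CSMFeaturizer  # local import to avoid cycle at init

    spec = spec or ToySpec()
    config = config or SignatureConfig()
    label_model = label_model or default_label_model(config)
    rng = np.random.default_rng(seed)
    featurizer = CSMFeaturizer(
        pocket_radius=config.pocket_radius,
        d_min=config.d_min,
        d_max=config.d_max,
        step=config.step,
        heavy_atoms_only=config.heavy_atoms_only,
        normalize=config.normalize.value,
    ).fit()
    templates = list(LigandTemplate)
    texts: list[str] = []
    sigs: list[SignatureVector] = []
    labels: list[float] = []
    for i in range(n):
        child = int(rng.integers(0, 2**31 - 1))
        s = replace(
            spec,
            seed=child,
            n_pocket_residues=int(rng.integers(4, 9)),
            placement_radius=float(rng.uniform(4.0, 7.0)),
            ligand_template=templates[rng.integers(len(templates))],
        )
        text = generate_toy_complex(s)
        sig = featurizer.signature_for(text)
        texts.append(text)
        sigs.append(sig)
        labels.append(label_model.label(sig, rng))
    return texts, np.array(labels), sigs


def rigid_transform(pdb_text: str, rotation, translation) -> str:
    """Rigid motion applied at the PDB-text level.

    Coordinates are rewritten in the fixed-width %8.3f fields, so the
    output is quantised to 0.001 A; everything outside the coordinate
    columns is byte-identical.  For exact (machine-precision) motions use
    :func:`csmaff.structure.transform_complex` instead.
    """
    R = np.asarray(rotation, dtype=np.float64)
    t = np.asarray(translation, dtype=np.float64)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-9) or abs(
        np.linalg.det(R) - 1.0
    ) > 1e-9:
        raise ValueError("rotation must be orthonormal with determinant 1")
    out = []
    for line in pdb_text.splitlines(keepends=True):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            new = R @ xyz + t
            line = (
                line[:30]
                + f"{new[0]:8.3f}{new[1]:8.3f}{new[2]:8.3f}"
                + line[54:]
            )
        out.append(line)
    return "".join(out)
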