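"""Cutoff-scan counting, pocket extraction and signature invariances."""

import numpy as np
import pytest

from csmaff.descriptors import DESCRIPTOR_NAMES
from csmaff.pharmacophore import Pharmacophore
from csmaff.signatures import (
    CLASS_PAIRS,
    CSMFeaturizer,
    Normalization,
    SignatureConfig,
    build_signature,
    cutoff_scan,
    extract_pocket,
    signature_schema,
)
from csmaff.structure import parse_complex, select_ligand, transform_complex
from csmaff.synthetic import ToySpec, generate_toy_complex, random_rotation
from conftest import blocks_as_arrays, brute_force_blocks, brute_force_pair_counts


def grid_config(**kw):
    base = dict(pocket_radius=8.0, d_min=1.0, d_max=10.0, step=1.0)
    base.update(kw)
    return SignatureConfig(**base)


class TestConfig:
    def test_grid_and_validation(self):
        cfg = grid_config()
        assert np.allclose(cfg.cutoffs(), np.arange(1.0, 10.5, 1.0))
        with pytest.raises(ValueError):
            SignatureConfig(d_min=5.0, d_max=1.0)
        with pytest.raises(ValueError):
            SignatureConfig(step=-1.0)

    def test_hash_distinguishes_configs(self):
        assert grid_config().hash() != grid_config(step=0.5).hash()


class TestCutoffScan:
    def test_single_pair_step_function(self):
        cfg = grid_config()
        pair = (Pharmacophore.HYDROPHOBIC, Pharmacophore.HYDROPHOBIC)
        block = cutoff_scan([(pair, 5.0)], cfg)
        k = CLASS_PAIRS.index(pair)
        assert block[k].tolist() == [0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
        assert block.sum() == block[k].sum()

    def test_empty_pairs_all_zero(self):
        block = cutoff_scan([], grid_config())
        assert block.shape == (36, 10)
        assert not block.any()

    def test_beyond_dmax_counted_nowhere(self):
        pair = (Pharmacophore.SULFUR, Pharmacophore.SULFUR)
        block = cutoff_scan([(pair, 11.0)], grid_config())
        assert not block.any()

    def test_negative_distance_rejected(self):
        pair = (Pharmacophore.NEUTRAL, Pharmacophore.NEUTRAL)
        with pytest.raises(ValueError, match="negative"):
            cutoff_scan([(pair, -1.0)], grid_config())

    def test_matches_brute_force_on_random_pairs(self):
        cfg = grid_config()
        rng = np.random.default_rng(12)
        classes = list(Pharmacophore)
        pairs = []
        for _ in range(200):
            a, b = rng.choice(8, size=2)
            pairs.append(((classes[a], classes[b]), float(rng.uniform(0, 12))))
        got = cutoff_scan(pairs, cfg)
        # independent recount
        expected = np.zeros_like(got)
        for (a, b), d in pairs:
            key = (a, b) if a <= b else (b, a)
            k = CLASS_PAIRS.index(key)
            for ci, c in enumerate(cfg.cutoffs()):
                if d <= c:
                    expected[k, ci] += 1
        assert (got == expected).all()


class TestExtractPocket:
    def test_huge_radius_returns_all_protein_atoms(self, toy_complex):
        cplx, lig = toy_complex
        pocket = extract_pocket(cplx, lig, grid_config(pocket_radius=1000.0))
        assert len(pocket) == len(cplx.protein_atoms)

    def test_closed_boundary_includes_exact_radius(self):
        text = (
            "ATOM      1  CA  ALA A   1       8.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  C1  LIG A 900       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        cplx = parse_complex(text)
        lig = select_ligand(cplx)
        pocket = extract_pocket(cplx, lig, grid_config(pocket_radius=8.0))
        assert len(pocket) == 1

    def test_isolated_ligand_reports_min_distance(self):
        text = (
            "ATOM      1  CA  ALA A   1      50.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  C1  LIG A 900       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        cplx = parse_complex(text)
        lig = select_ligand(cplx)
        with pytest.raises(ValueError, match="isolated.*50.00"):
            extract_pocket(cplx, lig, grid_config(pocket_radius=8.0))

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        lines = []
        for i in range(50):
            xyz = rng.uniform(-12, 12, size=3)
            lines.append(
                f"ATOM  {i+1:>5d}  CA  ALA A{i+1:>4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
            )
        for j in range(5):
            xyz = rng.uniform(-2, 2, size=3)
            lines.append(
                f"HETATM{51+j:>5d}  C{j+1}  LIG A 900    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
            )
        cplx = parse_complex("\n".join(lines) + "\nEND\n")
        lig = select_ligand(cplx)
        pocket = extract_pocket(cplx, lig, grid_config(pocket_radius=8.0))
        expected = set()
        for p in cplx.protein_atoms:
            for l in lig.ligand_atoms:
                if np.linalg.norm(p.xyz - l.xyz) <= 8.0:
                    expected.add(p.residue_seq)
                    break
        assert {a.residue_seq for a in pocket.atoms} == expected

    def test_pocket_grows_monotonically_with_radius(self, toy_complex):
        cplx, lig = toy_complex
        small = extract_pocket(cplx, lig, grid_config(pocket_radius=6.0))
        big = extract_pocket(cplx, lig, grid_config(pocket_radius=9.0))
        small_ids = {(a.residue_seq, a.atom_name) for a in small.atoms}
        big_ids = {(a.residue_seq, a.atom_name) for a in big.atoms}
        assert small_ids <= big_ids


class TestBuildSignature:
    def test_vector_length_matches_declared_layout(self, toy_complex):
        cplx, lig = toy_complex
        cfg = grid_config()  # 10 cutoffs
        sig = build_signature(cplx, lig, config=cfg)
        assert len(sig.values) == 36 * 10 * 2 + len(DESCRIPTOR_NAMES)
        assert sig.schema == signature_schema(cfg)

    def test_cumulative_monotone_and_conserved(self, toy_complex):
        cplx, lig = toy_complex
        cfg = SignatureConfig()
        sig = build_signature(cplx, lig, config=cfg)
        ncut = len(cfg.cutoffs())
        blocks = sig.values[: 2 * 36 * ncut].reshape(2, 36, ncut)
        assert (np.diff(blocks, axis=2) >= 0).all()

    def test_matches_brute_force_recount(self, toy_complex):
        cplx, lig = toy_complex
        cfg = SignatureConfig()
        sig = build_signature(cplx, lig, config=cfg)
        ncut = len(cfg.cutoffs())
        pocket_counts, cross_counts = brute_force_blocks(cplx, lig, cfg)
        got = sig.values[: 2 * 36 * ncut].reshape(2, 36, ncut)
        assert (got[0] == blocks_as_arrays(pocket_counts, cfg.cutoffs())).all()
        assert (got[1] == blocks_as_arrays(cross_counts, cfg.cutoffs())).all()

    def test_rigid_motion_leaves_signature_bit_identical(self, toy_complex):
        cplx, lig = toy_complex
        cfg = SignatureConfig()
        ref = build_signature(cplx, lig, config=cfg)
        rng = np.random.default_rng(21)
        for _ in range(5):
            moved = transform_complex(cplx, random_rotation(rng), rng.normal(size=3) * 20)
            mlig = select_ligand(moved)
            sig = build_signature(moved, mlig, config=cfg)
            assert (sig.values == ref.values).all()

    def test_record_order_permutation_leaves_signature_bit_identical(self, toy_text):
        cfg = SignatureConfig()
        cplx = parse_complex(toy_text)
        ref = build_signature(cplx, select_ligand(cplx), config=cfg)
        lines = toy_text.splitlines()
        atoms = [l for l in lines if l.startswith(("ATOM", "HETATM"))]
        rng = np.random.default_rng(5)
        shuffled = [atoms[i] for i in rng.permutation(len(atoms))]
        cplx2 = parse_complex("\n".join(shuffled) + "\nEND\n")
        sig = build_signature(cplx2, select_ligand(cplx2), config=cfg)
        assert (sig.values == ref.values).all()

    def test_geometry_sensitivity_negative_control(self, toy_complex):
        # doubling all coordinates moves pair distances across bins
        cplx, lig = toy_complex
        cfg = SignatureConfig()
        ref = build_signature(cplx, lig, config=cfg)
        from dataclasses import replace

        def scale(a):
            return replace(a, coords=tuple(2.0 * c for c in a.coords))

        from csmaff.structure import ComplexStructure

        scaled = ComplexStructure(
            protein_atoms=[scale(a) for a in cplx.protein_atoms],
            het_groups={k: [scale(a) for a in v] for k, v in cplx.het_groups.items()},
        )
        slig = select_ligand(scaled)
        sig = build_signature(scaled, slig, config=cfg)
        ncut = len(cfg.cutoffs())
        n_block = 2 * 36 * ncut
        assert not (sig.values[:n_block] == ref.values[:n_block]).all()

    def test_schema_guard_rejects_mismatched_reference(self, toy_complex):
        cplx, lig = toy_complex
        other_schema = signature_schema(grid_config())
        with pytest.raises(ValueError, match="schema mismatch"):
            build_signature(
                cplx, lig, config=SignatureConfig(), reference_schema=other_schema
            )

    def test_per_paircount_normalization_bounded(self, toy_complex):
        cplx, lig = toy_complex
        cfg = SignatureConfig(normalize=Normalization.PER_PAIRCOUNT)
        sig = build_signature(cplx, lig, config=cfg)
        ncut = len(cfg.cutoffs())
        blocks = sig.values[: 2 * 36 * ncut]
        assert blocks.min() >= 0.0
        assert blocks.max() <= 1.0


class TestFeaturizer:
    def test_sklearn_contract_and_matrix_shape(self, toy_text):
        feat = CSMFeaturizer(d_max=10.0, step=1.0)
        X = feat.fit_transform([toy_text, toy_text])
        assert X.shape == (2, 36 * 10 * 2 + len(DESCRIPTOR_NAMES))
        assert (X[0] == X[1]).all()
        params = feat.get_params()
        assert params["d_max"] == 10.0
        assert len(feat.get_feature_names_out()) == X.shape[1]
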