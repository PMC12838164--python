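"""Descriptor extraction: closed-form anchors, brute-force oracles,
rigid-motion invariance, PDB parsing contracts, and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from confvar import synthetic as syn
from confvar.features import (DESCRIPTOR_COLUMNS, FeatureMatrix, MotifSpec,
                              activation_loop_length, build_feature_matrix,
                              dfg_dihedral, dihedral_angle,
                              radius_of_gyration, salt_bridge_distance,
                              standardize)
from confvar.structures import Conformer, PDBParseError, Provenance, read_pdb


def make_conformer(atoms):
    """atoms: list of (atom_name, res_name, res_id, xyz)."""
    return Conformer(
        atom_name=np.array([a[0] for a in atoms]),
        res_name=np.array([a[1] for a in atoms]),
        res_id=np.array([a[2] for a in atoms], dtype=int),
        chain_id=np.array(["A"] * len(atoms)),
        coord=np.array([a[3] for a in atoms], dtype=float),
    )


class TestSaltBridge:
    MOTIF = MotifSpec(lys_residue=1, glu_residue=2, loop_start=1, loop_end=2)

    def test_minimum_over_carboxylate_oxygens(self):
        conf = make_conformer([
            ("NZ", "LYS", 1, (0, 0, 0)),
            ("OE1", "GLU", 2, (3, 4, 0)),     # 5.0
            ("OE2", "GLU", 2, (10, 0, 0)),    # 10.0
        ])
        assert salt_bridge_distance(conf, self.MOTIF) == pytest.approx(5.0)

    def test_coincident_atoms_give_zero(self):
        conf = make_conformer([("NZ", "LYS", 1, (1, 2, 3)),
                               ("OE1", "GLU", 2, (1, 2, 3))])
        assert salt_bridge_distance(conf, self.MOTIF) == 0.0

    def test_single_oxygen_suffices(self):
        conf = make_conformer([("NZ", "LYS", 1, (0, 0, 0)),
                               ("OE2", "GLU", 2, (0, 0, 2))])
        assert salt_bridge_distance(conf, self.MOTIF) == pytest.approx(2.0)

    def test_missing_atoms_reported_by_name(self):
        conf = make_conformer([("CA", "LYS", 1, (0, 0, 0)),
                               ("OE1", "GLU", 2, (1, 0, 0))])
        with pytest.raises(KeyError, match="NZ"):
            salt_bridge_distance(conf, self.MOTIF)
        conf2 = make_conformer([("NZ", "LYS", 1, (0, 0, 0)),
                                ("CA", "GLU", 2, (1, 0, 0))])
        with pytest.raises(KeyError, match="OE"):
            salt_bridge_distance(conf2, self.MOTIF)


class TestLoopLength:
    def test_straight_chain(self):
        atoms = [("CA", "GLY", i + 1, (3.8 * i, 0, 0)) for i in range(11)]
        conf = make_conformer(atoms)
        motif = MotifSpec(lys_residue=1, glu_residue=1, loop_start=1, loop_end=11)
        assert activation_loop_length(conf, motif) == pytest.approx(38.0)

    def test_degenerate_span_is_zero(self):
        conf = make_conformer([("CA", "GLY", 5, (1, 1, 1))])
        motif = MotifSpec(lys_residue=5, glu_residue=5, loop_start=5, loop_end=5)
        assert activation_loop_length(conf, motif) == 0.0

    def test_matches_direct_distance(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        conf = make_conformer([("CA", "GLY", 1, a), ("CA", "GLY", 9, b)])
        motif = MotifSpec(lys_residue=1, glu_residue=1, loop_start=1, loop_end=9)
        assert activation_loop_length(conf, motif) == pytest.approx(
            float(np.sqrt(((a - b) ** 2).sum())), rel=1e-12)


class TestDihedral:
    def test_planar_anti_is_180(self):
        assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_planar_syn_is_0(self):
        assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_result_in_half_open_interval(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(4, 3))
            ang = dihedral_angle(*pts)
            assert -180.0 < ang <= 180.0

    def test_mirror_reflection_flips_sign(self, rng):
        pts = rng.normal(size=(4, 3))
        ang = dihedral_angle(*pts)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral_angle(*mirrored) == pytest.approx(-ang, abs=1e-9)

    def test_phi_choice_uses_preceding_carbonyl(self):
        """The toy topology plants psi; phi resolves to the fixed -60."""
        row = {"variant": "V", "depth": 0, "seed": 0, "frame": 0,
               "salt_bridge_dist": 4.0, "aloop_length": 20.0,
               "dfg_dihedral": 45.0, "energy": 0.0}
        conf = syn.build_toy_conformer(row)
        psi_motif = syn.toy_motif(dihedral_choice="psi")
        phi_motif = syn.toy_motif(dihedral_choice="phi")
        assert dfg_dihedral(conf, psi_motif) == pytest.approx(45.0, abs=1e-6)
        assert dfg_dihedral(conf, phi_motif) == pytest.approx(-60.0, abs=1e-6)


class TestRadiusOfGyration:
    def test_coincident_atoms(self):
        conf = make_conformer([("CA", "GLY", 1, (1, 1, 1)),
                               ("CB", "GLY", 2, (1, 1, 1))])
        assert radius_of_gyration(conf) == 0.0

    def test_two_equal_masses(self):
        conf = make_conformer([("CA", "GLY", 1, (0, 0, 0)),
                               ("CB", "GLY", 2, (2, 0, 0))])
        assert radius_of_gyration(conf) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        coords = rng.normal(scale=5.0, size=(100, 3))
        names = rng.choice(["CA", "N", "O", "SD", "CB"], size=100)
        conf = make_conformer([(n, "GLY", i + 1, c)
                               for i, (n, c) in enumerate(zip(names, coords))])
        masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
        m = np.array([masses[n[0]] for n in names])
        com = (coords * m[:, None]).sum(0) / m.sum()
        expected = np.sqrt((m * ((coords - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(conf) == pytest.approx(expected, rel=1e-9)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_descriptors_invariant_under_rigid_motion(seed):
    """Rotation + translation leaves all geometric descriptors unchanged."""
    rng = np.random.default_rng(seed)
    row = {"variant": "V", "depth": 0, "seed": 0, "frame": 0,
           "salt_bridge_dist": float(rng.uniform(2, 9)),
           "aloop_length": float(rng.uniform(5, 37)),
           "dfg_dihedral": float(rng.uniform(-179, 180)), "energy": 0.0}
    conf = syn.build_toy_conformer(row)
    motif = syn.toy_motif()
    R = Rotation.random(random_state=int(seed % 2**31)).as_matrix()
    moved = conf.transformed(R, rng.normal(scale=50.0, size=3))
    assert salt_bridge_distance(moved, motif) == pytest.approx(
        salt_bridge_distance(conf, motif), abs=1e-8)
    assert activation_loop_length(moved, motif) == pytest.approx(
        activation_loop_length(conf, motif), abs=1e-8)
    assert dfg_dihedral(moved, motif) == pytest.approx(
        dfg_dihedral(conf, motif), abs=1e-6)
    assert radius_of_gyration(moved) == pytest.approx(
        radius_of_gyration(conf), abs=1e-8)


class TestPdbParsing:
    def test_multi_model_file_expands(self, tmp_path):
        lines = []
        for m in (1, 2, 3):
            lines.append(f"MODEL     {m:4d}")
            lines.append("ATOM      1  CA  GLY A   1    "
                         f"{0.0:8.3f}{0.0:8.3f}{float(m):8.3f}"
                         "  1.00  0.00           C  ")
            lines.append("ENDMDL")
        lines.append("END")
        path = tmp_path / "multi.pdb"
        path.write_text("\n".join(lines) + "\n")
        confs = read_pdb(path, provenance=Provenance("V", 0, 0, 0))
        assert len(confs) == 3
        assert [c.provenance.frame for c in confs] == [0, 1, 2]

    def test_malformed_coordinate_names_file_and_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
            "  1.00  0.00           C  \n"
            "ATOM      2  CB  GLY A   2       x.xxx   0.000   0.000"
            "  1.00  0.00           C  \n")
        with pytest.raises(PDBParseError, match=r"bad\.pdb.*line 2"):
            read_pdb(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(PDBParseError):
            read_pdb(path)


class TestFeatureMatrix:
    def test_row_count_and_columns(self, small_study, small_config):
        conformers, _, fm = small_study
        assert fm.n == len(conformers)
        assert fm.n == (len(small_config.variants)
                        * small_config.frames_per_variant())
        assert list(fm.data.columns[-5:]) == DESCRIPTOR_COLUMNS

    def test_rows_sorted_by_provenance(self, small_fm):
        key = small_fm.data[["variant", "depth", "seed", "frame"]]
        assert key.equals(key.sort_values(["variant", "depth", "seed", "frame"])
                          .reset_index(drop=True))

    def test_unmatched_energy_rejected(self, motif):
        cfg = syn.GeneratorConfig(variants=[("V1", "WT")], n_depths=1,
                                  n_seeds_per_depth=1, n_frames_per_seed=3,
                                  rng_seed=0)
        conformers, targets = syn.generate_variant_ensemble(cfg, "V1")
        for c in conformers:
            c.energy = None
        bad_energy = syn.energy_table(targets).iloc[:2]
        with pytest.raises(ValueError, match="without matching energy"):
            build_feature_matrix(conformers, motif, bad_energy, {"V1": 0})


class TestStandardize:
    def test_zero_mean_unit_sd(self, small_fm):
        fm_std, _ = standardize(small_fm)
        X = fm_std.X
        assert np.abs(X.mean(axis=0)).max() < 1e-10
        assert np.abs(X.std(axis=0) - 1).max() < 1e-10

    def test_inverse_round_trip(self, small_fm):
        _, scaler = standardize(small_fm)
        X = small_fm.X
        assert np.allclose(scaler.inverse_transform(scaler.transform(X)), X,
                           rtol=1e-12, atol=1e-9)

    def test_constant_column_rejected(self, small_fm):
        data = small_fm.data.copy()
        data["energy"] = 1.0
        with pytest.raises(ValueError, match="energy"):
            standardize(FeatureMatrix(data))

    def test_new_data_uses_training_statistics(self, small_fm):
        _, scaler = standardize(small_fm)
        X_new = small_fm.X[:10] + 100.0
        Z = scaler.transform(X_new)
        # shifted data standardized with TRAINING stats keeps the shift:
        # mean moves by 100/sd per column instead of re-centering to zero
        expected = 100.0 / scaler.sd + scaler.transform(small_fm.X[:10]).mean(axis=0)
        assert np.allclose(Z.mean(axis=0), expected, rtol=1e-10)
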