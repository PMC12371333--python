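"""Atom encoding, pocket extraction, rotations and voxelization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridbind.datatypes import AtomRecord, ComplexFrame
from gridbind.errors import GridbindError
from gridbind.featurize import (CHANNELS, N_CHANNELS, Rotation, apply_rotation,
                                encode_atom, encode_frame, enumerate_rotations,
                                extract_pocket, make_box, mask_partner,
                                random_rotation, rotate_grid, voxelize_trajectory)
from gridbind.datatypes import Trajectory
from conftest import make_atom, make_frame, random_frame


class TestEncodeAtom:
    def test_layout_has_19_channels(self):
        assert N_CHANNELS == 19
        assert len(CHANNELS) == 19

    def test_sp3_ring_carbon_ligand(self):
        atom = make_atom("C", role="ligand", hybridization=3, heavy_valence=4,
                         hetero_valence=0, is_ring=True, is_hydrophobic=True,
                         partial_charge=-0.1)
        v = encode_atom(atom)
        expected = np.zeros(19)
        expected[CHANNELS.index("type_C")] = 1
        expected[CHANNELS.index("hybridization")] = 3
        expected[CHANNELS.index("heavy_valence")] = 4
        expected[CHANNELS.index("hydrophobic")] = 1
        expected[CHANNELS.index("ring")] = 1
        expected[CHANNELS.index("partial_charge")] = -0.1
        expected[CHANNELS.index("moltype")] = -1
        np.testing.assert_array_equal(v, expected)

    def test_aromatic_protein_nitrogen_acceptor(self):
        atom = make_atom("N", role="protein", hybridization=2,
                         is_aromatic=True, is_acceptor=True)
        v = encode_atom(atom)
        assert v[CHANNELS.index("type_N")] == 1
        assert v[CHANNELS.index("moltype")] == 1
        assert v[CHANNELS.index("aromatic")] == 1
        assert v[CHANNELS.index("acceptor")] == 1
        assert v[:9].sum() == 1  # exactly one type flag

    @pytest.mark.parametrize("element,channel", [
        ("Zn", "type_metal"), ("Fe", "type_metal"), ("Cl", "type_halogen"),
        ("Br", "type_halogen"), ("Se", "type_Se"), ("P", "type_P"),
    ])
    def test_element_classes(self, element, channel):
        v = encode_atom(make_atom(element))
        assert v[CHANNELS.index(channel)] == 1
        assert v[:9].sum() == 1

    def test_unclassifiable_element_all_zero_type(self):
        v = encode_atom(make_atom("D"))
        assert v[:9].sum() == 0


class TestExtractPocket:
    def test_boundary_inclusive_at_exactly_radius(self):
        # residues with nearest atoms at 5, 11.9, 12.0, 12.1 from the ligand center
        frame = make_frame([
            ("C", (5.0, 0, 0), "protein", "A:1"),
            ("C", (11.9, 0, 0), "protein", "A:2"),
            ("C", (12.0, 0, 0), "protein", "A:3"),
            ("C", (12.1, 0, 0), "protein", "A:4"),
            ("O", (0.0, 0, 0), "ligand"),
        ])
        assert extract_pocket(frame, 12.0) == {"A:1", "A:2", "A:3"}

    def test_zero_radius_selects_nothing_generically(self):
        frame = make_frame([("C", (1.0, 0, 0), "protein", "A:1"),
                            ("O", (0.0, 0, 0), "ligand")])
        assert extract_pocket(frame, 0.0) == set()

    def test_single_atom_ligand_center(self):
        frame = make_frame([("C", (3.0, 0, 0), "protein", "A:1"),
                            ("O", (1.0, 2.0, 3.0), "ligand")])
        np.testing.assert_allclose(frame.ligand_center(), [1.0, 2.0, 3.0])

    def test_no_ligand_is_error(self):
        frame = make_frame([("C", (0, 0, 0), "protein", "A:1")])
        with pytest.raises(GridbindError, match="no ligand"):
            extract_pocket(frame)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            frame = random_frame(rng, n_protein=40, n_ligand=5)
            radius = float(rng.uniform(3.0, 10.0))
            got = extract_pocket(frame, radius)
            center = np.mean([a.coords for a in frame.atoms if a.role == "ligand"], axis=0)
            expected = set()
            for a in frame.atoms:
                if a.role == "protein":
                    if np.sqrt(((a.coords - center) ** 2).sum()) <= radius:
                        expected.add(a.residue_id)
            assert got == expected


class TestRotations:
    def test_octahedral_group(self):
        rots = enumerate_rotations()
        assert len(rots) == 24
        mats = [r.matrix for r in rots]
        # pairwise distinct
        for i in range(24):
            for j in range(i + 1, 24):
                assert not np.allclose(mats[i], mats[j])
        # identity first, closure under composition
        assert np.allclose(mats[0], np.eye(3))
        for a in mats:
            for b in mats:
                prod = a @ b
                assert any(np.allclose(prod, m) for m in mats)

    def test_all_proper_orthonormal(self):
        for r in enumerate_rotations():
            np.testing.assert_allclose(r.matrix @ r.matrix.T, np.eye(3), atol=1e-12)
            assert np.isclose(np.linalg.det(r.matrix), 1.0)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(GridbindError):
            Rotation(np.diag([1.0, 1.0, -1.0]), "bad")  # improper (det -1)
        with pytest.raises(GridbindError):
            Rotation(np.eye(3) * 2, "bad")

    def test_known_90_degree_rotation(self):
        rots = enumerate_rotations()
        frame = make_frame([("O", (1.0, 0.0, 0.0), "ligand")])
        # find the z-rotation by its matrix
        rz = next(r for r in rots if np.allclose(
            r.matrix, [[0, -1, 0], [1, 0, 0], [0, 0, 1]]))
        out = apply_rotation(frame, rz, pivot=np.zeros(3))
        np.testing.assert_allclose(out.atoms[0].coords, [0.0, 1.0, 0.0], atol=1e-12)

    def test_identity_rotation_is_noop(self, toy_frame):
        out = apply_rotation(toy_frame, enumerate_rotations()[0], pivot=np.ones(3))
        np.testing.assert_allclose(out.coords(), toy_frame.coords())

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 23), st.integers(0, 2 ** 31 - 1))
    def test_rotation_is_isometry(self, rot_idx, seed):
        rng = np.random.default_rng(seed)
        frame = random_frame(rng)
        rot = enumerate_rotations()[rot_idx]
        pivot = rng.normal(0, 5, 3)
        out = apply_rotation(frame, rot, pivot)
        center_before = frame.ligand_center()
        center_after = out.ligand_center()
        d_before = np.linalg.norm(frame.coords() - center_before, axis=1)
        d_after = np.linalg.norm(out.coords() - center_after, axis=1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-9)

    def test_random_so3_rotation_valid(self):
        rot = random_rotation(np.random.default_rng(0), "so3")
        assert rot.tag == "random"


class TestMaskPartner:
    def test_complex_is_identity(self, toy_frame):
        assert mask_partner(toy_frame, "complex") is toy_frame

    def test_ligand_only_count(self, toy_frame):
        out = mask_partner(toy_frame, "ligand_only")
        assert len(out.atoms) == 1 and out.atoms[0].role == "ligand"

    def test_empty_result_is_error(self):
        frame = make_frame([("O", (0, 0, 0), "ligand")])
        with pytest.raises(GridbindError, match="removes every atom"):
            mask_partner(frame, "protein_only")


class TestMakeBox:
    def test_atom_at_center_occupies_middle_voxel(self):
        frame = make_frame([("O", (0.0, 0.0, 0.0), "ligand")])
        grid = make_box(frame, edge_A=25, resolution_A=1)
        vec = encode_frame(frame)[1][0]
        occupied = np.argwhere(grid.values.sum(axis=0) != 0)
        assert occupied.tolist() == [[12, 12, 12]]
        np.testing.assert_allclose(grid.values[:, 12, 12, 12], vec)
        np.testing.assert_allclose(grid.values.sum(axis=(1, 2, 3)), vec)

    def test_atom_outside_box_dropped(self):
        frame = make_frame([("O", (0.0, 0.0, 0.0), "ligand"),
                            ("C", (13.0, 0.0, 0.0), "protein", "A:1")])
        grid = make_box(frame, center=np.zeros(3))
        lig_vec = encode_frame(frame)[1][0]
        np.testing.assert_allclose(grid.values.sum(axis=(1, 2, 3)), lig_vec)

    def test_colliding_atoms_sum(self):
        frame = make_frame([("O", (0.2, 0.2, 0.2), "ligand"),
                            ("O", (0.3, 0.3, 0.3), "ligand")])
        grid = make_box(frame, center=np.zeros(3))
        vec = encode_frame(frame)[1][0]
        np.testing.assert_allclose(grid.values[:, 12, 12, 12], 2 * vec)

    def test_non_integer_grid_dimension_rejected(self, toy_frame):
        with pytest.raises(GridbindError, match="integer multiple"):
            make_box(toy_frame, edge_A=25, resolution_A=0.7)

    def test_mass_conservation_random_frames(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            frame = random_frame(rng)
            grid = make_box(frame, center=np.zeros(3))
            coords, feats = encode_frame(frame)
            inside = np.all(np.abs(coords - grid.center) < 12.5, axis=1)
            np.testing.assert_allclose(grid.values.sum(axis=(1, 2, 3)),
                                       feats[inside].sum(axis=0), atol=1e-12)

    def test_ablation_additivity(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            frame = random_frame(rng)
            center = np.zeros(3)
            full = make_box(frame, center=center).values
            prot = make_box(mask_partner(frame, "protein_only"), center=center).values
            lig = make_box(mask_partner(frame, "ligand_only"), center=center).values
            np.testing.assert_allclose(full, prot + lig, atol=1e-12)

    def test_right_angle_equivariance(self):
        """Rotating the frame about the box center equals the corresponding
        axis permutation/flip of the grid, voxel for voxel."""
        rng = np.random.default_rng(8)
        rots = enumerate_rotations()
        frame = random_frame(rng)
        center = np.zeros(3)
        base = make_box(frame, center=center).values
        for rot in rots:
            rotated = make_box(apply_rotation(frame, rot, center), center=center).values
            np.testing.assert_allclose(rotated, rotate_grid(base, rot), atol=1e-12)

    def test_rotate_grid_rejects_continuous_rotation(self):
        rot = random_rotation(np.random.default_rng(3), "so3")
        with pytest.raises(GridbindError):
            rotate_grid(np.zeros((19, 5, 5, 5)), rot)


class TestVoxelizeTrajectory:
    def _rigid_traj(self, frame, T=4):
        frames = [frame.with_coords(frame.coords()) for _ in range(T)]
        for i, f in enumerate(frames):
            f.frame_index = i
            f.replicate_id = 0
        return Trajectory.from_frames(frames)

    def test_rigid_trajectory_gives_identical_grids(self, toy_frame):
        traj = self._rigid_traj(toy_frame)
        seq = voxelize_trajectory(traj)
        for g in seq.grids[1:]:
            np.testing.assert_array_equal(g.values, seq.grids[0].values)

    def test_tracking_mode_cancels_uniform_translation(self):
        base = make_frame([("O", (0.5, 0.5, 0.5), "ligand"),
                           ("C", (1.5, 0.5, 0.5), "ligand")])
        frames = []
        for t in range(5):
            f = base.with_coords(base.coords() + np.array([0.31, -0.17, 0.23]) * t)
            f.frame_index, f.replicate_id = t, 0
            frames.append(f)
        traj = Trajectory.from_frames(frames)
        seq = voxelize_trajectory(traj, centering="ligand_tracking")
        for g in seq.grids[1:]:
            np.testing.assert_array_equal(g.values, seq.grids[0].values)

    def test_pocket_mode_shows_ligand_motion(self):
        base = make_frame([("O", (0.5, 0.5, 0.5), "ligand"),
                           ("C", (5.5, 0.5, 0.5), "protein", "A:1")])
        frames = []
        for t in range(3):
            coords = base.coords().copy()
            coords[0] += np.array([2.0, 0.0, 0.0]) * t  # ligand drifts
            f = base.with_coords(coords)
            f.frame_index, f.replicate_id = t, 0
            frames.append(f)
        traj = Trajectory.from_frames(frames)
        seq = voxelize_trajectory(traj, centering="pocket")
        assert not np.array_equal(seq.grids[0].values, seq.grids[1].values)
        # the ligand channel mass is conserved while it stays in the box
        moltype = CHANNELS.index("moltype")
        sums = [g.values[moltype].sum() for g in seq.grids]
        assert sums[0] == sums[1] == sums[2]
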