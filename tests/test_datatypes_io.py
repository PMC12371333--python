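"""Domain-type invariants and file round trips (PDB, HDF5, CSV)."""

import numpy as np
import pandas as pd
import pytest

from gridbind.datatypes import (AtomRecord, ComplexFrame, Manifest, PredictionSet,
                                Trajectory)
from gridbind.errors import GridbindError, LeakageError, ParseError
from gridbind.featurize import CHANNELS
from gridbind.io import (read_complex, read_trajectory, read_replicates_h5,
                         write_trajectories_h5, write_grid_dataset,
                         read_grid_dataset, write_structure_pdb,
                         write_annotations_csv)
from conftest import make_frame

TOY_PDB = """\
ATOM      1  CA  ALA A   1       4.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   ALA A   2       0.000   4.000   0.000  1.00  0.00           N
HETATM    3  O1  LIG L 900       0.000   0.000   0.000  1.00  0.00           O
END
"""

TOY_PDB_WITH_H = """\
ATOM      1  CA  ALA A   1       4.000   0.000   0.000  1.00  0.00           C
ATOM      2  H   ALA A   1       4.500   0.500   0.000  1.00  0.00           H
ATOM      3  N   ALA A   2       0.000   4.000   0.000  1.00  0.00           N
HETATM    4  O1  LIG L 900       0.000   0.000   0.000  1.00  0.00           O
HETATM    5  H1  LIG L 900       0.300   0.300   0.000  1.00  0.00           H
END
"""


class TestAtomRecord:
    def test_rejects_non_finite_coords(self):
        with pytest.raises(GridbindError, match="finite"):
            AtomRecord("C", np.array([np.nan, 0, 0]))

    def test_rejects_bad_role_and_counts(self):
        with pytest.raises(GridbindError):
            AtomRecord("C", np.zeros(3), role="solvent")
        with pytest.raises(GridbindError):
            AtomRecord("C", np.zeros(3), heavy_valence=-1)
        with pytest.raises(GridbindError):
            AtomRecord("C", np.zeros(3), hybridization=4)


class TestTrajectory:
    def test_frame_index_must_increase(self):
        frame = make_frame([("O", (0, 0, 0), "ligand")])
        coords = np.zeros((3, 1, 3))
        with pytest.raises(GridbindError, match="strictly increasing"):
            Trajectory("toy", 0, frame.atoms, coords, frame_indices=[0, 2, 1])

    def test_roster_mismatch_rejected(self):
        f1 = make_frame([("O", (0, 0, 0), "ligand")])
        f2 = make_frame([("N", (0, 0, 0), "ligand")])
        f2.frame_index = 1
        with pytest.raises(GridbindError, match="roster"):
            Trajectory.from_frames([f1, f2])

    def test_lazy_frames_round_trip(self):
        frame = make_frame([("O", (0, 0, 0), "ligand"), ("C", (1, 1, 1), "protein", "A:1")])
        coords = np.stack([frame.coords(), frame.coords() + 1.0])
        traj = Trajectory("toy", 0, frame.atoms, coords, label_pk=4.2)
        assert traj.n_frames == 2
        f1 = traj.frame(1)
        assert f1.frame_index == 1 and f1.label_pk == 4.2
        np.testing.assert_allclose(f1.coords(), coords[1])


class TestReadComplex:
    def test_toy_pdb_roles_and_order(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        frame = read_complex(path)
        assert [a.role for a in frame.atoms] == ["protein", "protein", "ligand"]
        assert [a.element for a in frame.atoms] == ["C", "N", "O"]
        assert frame.atoms[0].residue_id == "A:1"
        assert frame.atoms[2].residue_id == ""

    def test_hydrogens_dropped(self, tmp_path):
        path = tmp_path / "toy_h.pdb"
        path.write_text(TOY_PDB_WITH_H)
        frame = read_complex(path)
        assert len(frame.atoms) == 3
        assert all(a.element != "H" for a in frame.atoms)

    def test_no_ligand_is_error(self, tmp_path):
        path = tmp_path / "nolig.pdb"
        path.write_text("\n".join(TOY_PDB.splitlines()[:2]) + "\nEND\n")
        with pytest.raises(GridbindError, match="no ligand"):
            read_complex(path)

    def test_unparseable_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        bad = TOY_PDB.replace("   4.000   0.000   0.000", "   4.0xx   0.000   0.000")
        path.write_text(bad)
        with pytest.raises(ParseError, match="line 1"):
            read_complex(path)

    def test_sidecar_annotations_respected(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        ann = pd.DataFrame({
            "partial_charge": [0.1, -0.2, 0.3], "hybridization": [3, 2, 2],
            "heavy_valence": [4, 3, 1], "hetero_valence": [0, 1, 1],
            "is_hydrophobic": [True, False, False], "is_aromatic": [False, True, False],
            "is_acceptor": [False, True, True], "is_donor": [False, False, True],
            "is_ring": [False, True, False]})
        ann_path = tmp_path / "toy.atoms.csv"
        ann.to_csv(ann_path, index=False)
        frame = read_complex(path, ann_path)
        assert frame.atoms[0].partial_charge == pytest.approx(0.1)
        assert frame.atoms[1].is_aromatic and frame.atoms[1].hybridization == 2

    def test_pdb_round_trip_via_writer(self, tmp_path, small_dataset):
        cid = "SYN_0000"
        frame = small_dataset.crystals[cid]
        pdb = tmp_path / f"{cid}.pdb"
        write_structure_pdb(frame, pdb)
        write_annotations_csv(frame, tmp_path / f"{cid}.atoms.csv")
        back = read_complex(pdb, tmp_path / f"{cid}.atoms.csv")
        assert len(back.atoms) == len(frame.atoms)
        assert [a.role for a in back.atoms] == [a.role for a in frame.atoms]
        np.testing.assert_allclose(back.coords(), frame.coords(), atol=1e-2)  # PDB precision
        assert [a.partial_charge for a in back.atoms] == [a.partial_charge for a in frame.atoms]


class TestTrajectoryIO:
    def test_h5_round_trip_shape_contract(self, tmp_path):
        frame = make_frame([("O", (float(i), 0, 0), "ligand") for i in range(12)])
        coords = np.cumsum(np.ones((50, 12, 3)) * 0.01, axis=0) + frame.coords()
        traj = Trajectory("toy", 0, frame.atoms, coords, label_pk=6.0)
        path = tmp_path / "toy.h5"
        write_trajectories_h5(path, [traj])
        back = read_trajectory(path)
        assert back.n_frames == 50 and len(back.topology) == 12
        np.testing.assert_array_equal(back.coords, coords)
        assert back.label_pk == 6.0

    def test_bad_coordinate_rank_rejected(self):
        frame = make_frame([("O", (0, 0, 0), "ligand")] * 12)
        with pytest.raises(GridbindError, match="3-dimensional"):
            Trajectory("toy", 0, frame.atoms, np.zeros((50, 12, 2)))

    def test_multi_model_pdb_two_models(self, tmp_path):
        lines = []
        for m in (1, 2):
            lines.append(f"MODEL     {m}")
            lines.append(TOY_PDB.splitlines()[0])
            lines.append(TOY_PDB.splitlines()[1])
            lines.append(TOY_PDB.splitlines()[2])
            lines.append("ENDMDL")
        (tmp_path / "mm.pdb").write_text("\n".join(lines) + "\nEND\n")
        traj = read_trajectory(tmp_path / "mm.pdb")
        assert traj.n_frames == 2
        assert list(traj.frame_indices) == [0, 1]

    def test_multi_replicate_container(self, tmp_path, small_dataset):
        cid = "SYN_0001"
        trajs = small_dataset.trajectories[cid]
        path = tmp_path / f"{cid}.h5"
        write_trajectories_h5(path, trajs)
        back = read_replicates_h5(path)
        assert [t.replicate_id for t in back] == [t.replicate_id for t in trajs]
        for a, b in zip(back, trajs):
            np.testing.assert_array_equal(a.coords, b.coords)
            assert a.label_pk == pytest.approx(b.label_pk)


class TestGridDataset:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        grids = rng.normal(size=(2, 19, 25, 25, 25)).astype(np.float32)
        labels = np.array([5.0, 6.0])
        path = tmp_path / "grids.h5"
        write_grid_dataset(path, {"train": (grids, labels, ["a", "b"])},
                           edge_A=25, resolution_A=1, centering="pocket")
        splits, attrs = read_grid_dataset(path, expected_channels=CHANNELS)
        np.testing.assert_array_equal(splits["train"][0], grids)
        np.testing.assert_array_equal(splits["train"][1], labels)
        assert splits["train"][2] == ["a", "b"]
        assert attrs["edge_A"] == 25 and attrs["resolution_A"] == 1
        assert attrs["channels"] == CHANNELS and attrs["centering"] == "pocket"

    def test_sequence_dataset_shape(self, tmp_path):
        seqs = np.zeros((2, 50, 19, 5, 5, 5), dtype=np.float32)
        path = tmp_path / "seq.h5"
        write_grid_dataset(path, {"train": (seqs, [1.0, 2.0], ["a", "b"])},
                           edge_A=5, resolution_A=1, centering="pocket")
        splits, _ = read_grid_dataset(path)
        assert splits["train"][0].shape == (2, 50, 19, 5, 5, 5)

    def test_npz_dialect_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        grids = rng.normal(size=(3, 19, 5, 5, 5)).astype(np.float32)
        path = tmp_path / "grids.npz"
        write_grid_dataset(path, {"val": (grids, [1.0, 2.0, 3.0], ["a", "b", "c"])},
                           edge_A=5, resolution_A=1, centering="ligand_tracking")
        splits, attrs = read_grid_dataset(path, expected_channels=CHANNELS)
        np.testing.assert_array_equal(splits["val"][0], grids)
        assert splits["val"][2] == ["a", "b", "c"]
        assert attrs["centering"] == "ligand_tracking"

    def test_missing_attribute_is_error(self, tmp_path):
        import h5py
        path = tmp_path / "broken.h5"
        write_grid_dataset(path, {}, edge_A=25, resolution_A=1, centering="pocket")
        with h5py.File(path, "a") as fh:
            del fh.attrs["resolution_A"]
        with pytest.raises(GridbindError, match="resolution_A"):
            read_grid_dataset(path)

    def test_channel_mismatch_is_error(self, tmp_path):
        path = tmp_path / "g.h5"
        write_grid_dataset(path, {}, edge_A=25, resolution_A=1, centering="pocket",
                           channels=("a", "b"))
        with pytest.raises(GridbindError, match="channel"):
            read_grid_dataset(path, expected_channels=CHANNELS)


class TestManifest:
    def _manifest(self, rows):
        return Manifest(pd.DataFrame(rows, columns=["complex_id", "label_pk", "split",
                                                    "protein_family", "cluster_id"]))

    def test_split_integrity_enforced(self):
        m = self._manifest([("a", 5.0, "train", "F1", "c1"),
                            ("a", 5.0, "test", "F1", "c1")])
        with pytest.raises(LeakageError):
            m.check()

    def test_unknown_split_rejected(self):
        m = self._manifest([("a", 5.0, "holdout", "F1", "c1")])
        with pytest.raises(GridbindError, match="split"):
            m.check()

    def test_csv_round_trip(self, tmp_path):
        m = self._manifest([("a", 5.0, "train", "F1", "c1"),
                            ("b", 6.5, "test", "F2", "c2")])
        m.to_csv(tmp_path / "m.csv")
        back = Manifest.from_csv(tmp_path / "m.csv")
        pd.testing.assert_frame_equal(back.table, m.table)


class TestPredictionSet:
    def test_finite_required(self):
        with pytest.raises(GridbindError, match="finite"):
            PredictionSet.from_rows([{"complex_id": "a", "replicate_id": 0,
                                      "frame_index": 0, "model_replicate": 0,
                                      "predicted_pk": np.inf}])

    def test_csv_round_trip_exact_columns(self, tmp_path):
        ps = PredictionSet.from_rows([
            {"complex_id": "a", "replicate_id": -1, "frame_index": 0,
             "model_replicate": 0, "predicted_pk": 5.5}])
        ps.to_csv(tmp_path / "p.csv")
        header = (tmp_path / "p.csv").read_text().splitlines()[0]
        assert header == "complex_id,replicate_id,frame_index,model_replicate,predicted_pk"
        back = PredictionSet.from_csv(tmp_path / "p.csv")
        pd.testing.assert_frame_equal(back.table, ps.table)
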