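"""Readers and writers for structures, trajectories and grid datasets.

Structures are single-model PDB files; trajectories are either multi-model
PDB files or an HDF5 container holding one atom roster plus per-replicate
``(T, n_atoms, 3)`` coordinate arrays.  Voxel-grid datasets are HDF5 files
with one group per split and metadata attributes recording the grid edge,
resolution, channel order and centering mode.

Feature annotations (partial charge, valences, pharmacophore flags) are not
representable in PDB; they come from a sidecar CSV with one row per heavy
atom in file order, or, failing that, from a deterministic perception of the
input structure (:func:`annotate_fallback`) that sets partial charges to 0.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .datatypes import AtomRecord, ComplexFrame, Trajectory, CRYSTAL_REPLICATE
from .errors import GridbindError, ParseError
from .featurize import CHANNELS

STANDARD_RESIDUES = frozenset("""
ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL
HOH WAT
""".split())

ANNOTATION_COLUMNS = ["partial_charge", "hybridization", "heavy_valence", "hetero_valence",
                      "is_hydrophobic", "is_aromatic", "is_acceptor", "is_donor", "is_ring"]

_FLAG_FIELDS = ("is_hydrophobic", "is_aromatic", "is_acceptor", "is_donor", "is_ring")


def _precheck_pdb(path) -> None:
    """Report unparseable coordinate records with their line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    raise ParseError(f"{path}: unparseable atom line {lineno}: {line.rstrip()!r}")


def _read_structure(path, model: int | None):
    _precheck_pdb(path)
    try:
        pdb = PDBFile.read(str(path))
        return pdb.get_structure(model=model)
    except ParseError:
        raise
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise ParseError(f"{path}: could not parse PDB file: {exc}") from exc


def _ligand_mask(atoms, ligand_resname: str | None, path) -> np.ndarray:
    res_names = atoms.res_name
    if ligand_resname is not None:
        mask = res_names == ligand_resname
        if not mask.any():
            raise GridbindError(f"{path}: no ligand atoms with residue name {ligand_resname!r}")
        return mask
    candidates = sorted({rn for rn, het in zip(res_names, atoms.hetero)
                         if het and rn not in STANDARD_RESIDUES})
    if not candidates:
        raise GridbindError(f"{path}: no ligand atoms (no non-standard HETATM residue found)")
    if len(candidates) > 1:
        raise GridbindError(f"{path}: several candidate ligand residues {candidates}; "
                            "pass ligand_resname to disambiguate")
    return res_names == candidates[0]


def annotate_fallback(atoms) -> pd.DataFrame:
    """Deterministic perception of annotation features from the structure alone.

    Bonds are inferred from interatomic distances; hybridization, valences and
    pharmacophore flags follow simple element/connectivity rules; partial
    charges are set to 0.  Real use should supply a sidecar annotation table
    computed with proper charge/perception tooling.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bonds = struc.connect_via_distances(atoms)
    n = atoms.array_length()
    elements = np.char.upper(atoms.element)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from((int(a), int(b)) for a, b, _ in bonds.as_array())
    ring_atoms: set[int] = set()
    aromatic_atoms: set[int] = set()
    for cycle in nx.cycle_basis(graph):
        ring_atoms.update(cycle)
        if len(cycle) in (5, 6) and all(elements[i] in ("C", "N") for i in cycle):
            aromatic_atoms.update(cycle)
    rows = []
    for i in range(n):
        nbrs = list(graph.neighbors(i))
        heavy_nbrs = [j for j in nbrs if elements[j] != "H"]
        h_nbrs = [j for j in nbrs if elements[j] == "H"]
        hetero = sum(1 for j in heavy_nbrs if elements[j] != "C")
        el = elements[i]
        if el == "C":
            hyb = 3 if len(heavy_nbrs) + len(h_nbrs) >= 4 else (2 if i in aromatic_atoms or len(heavy_nbrs) == 3 else 3)
        elif el in ("N", "O", "S"):
            hyb = 2 if i in aromatic_atoms else 3
        else:
            hyb = 3
        rows.append({
            "partial_charge": 0.0,
            "hybridization": hyb,
            "heavy_valence": len(heavy_nbrs),
            "hetero_valence": hetero,
            "is_hydrophobic": el == "C" and hetero == 0,
            "is_aromatic": i in aromatic_atoms,
            "is_acceptor": el in ("N", "O"),
            "is_donor": el in ("N", "O") and len(h_nbrs) > 0,
            "is_ring": i in ring_atoms,
        })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _atoms_to_records(atoms, annotations: pd.DataFrame, ligand_mask: np.ndarray) -> list[AtomRecord]:
    records = []
    for i in range(atoms.array_length()):
        row = annotations.iloc[i]
        is_lig = bool(ligand_mask[i])
        records.append(AtomRecord(
            element=str(atoms.element[i]),
            coords=np.array(atoms.coord[i], dtype=float),
            partial_charge=float(row["partial_charge"]),
            hybridization=int(row["hybridization"]),
            heavy_valence=int(row["heavy_valence"]),
            hetero_valence=int(row["hetero_valence"]),
            is_hydrophobic=bool(row["is_hydrophobic"]),
            is_aromatic=bool(row["is_aromatic"]),
            is_acceptor=bool(row["is_acceptor"]),
            is_donor=bool(row["is_donor"]),
            is_ring=bool(row["is_ring"]),
            role="ligand" if is_lig else "protein",
            residue_id="" if is_lig else f"{atoms.chain_id[i]}:{int(atoms.res_id[i])}",
        ))
    return records


def read_complex(structure_path, annotation_path=None, ligand_resname: str | None = None,
                 complex_id: str | None = None, label_pk: float | None = None) -> ComplexFrame:
    """Read a single-model PDB into a heavy-atom :class:`ComplexFrame`.

    The ligand is the residue named ``ligand_resname`` (fallback: the sole
    non-standard HETATM residue).  Hydrogens are dropped; annotations come
    from the sidecar CSV (one row per heavy atom in file order) or from
    :func:`annotate_fallback`.
    """
    structure_path = Path(structure_path)
    atoms = _read_structure(structure_path, model=1)
    lig_mask_all = _ligand_mask(atoms, ligand_resname, structure_path)
    heavy = np.char.upper(atoms.element) != "H"
    if annotation_path is not None:
        annotations = pd.read_csv(annotation_path)
        missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
        if missing:
            raise GridbindError(f"{annotation_path}: annotation table is missing columns {missing}")
        if len(annotations) != int(heavy.sum()):
            raise GridbindError(f"{annotation_path}: {len(annotations)} annotation rows for "
                                f"{int(heavy.sum())} heavy atoms")
        heavy_atoms = atoms[heavy]
        lig_mask = lig_mask_all[heavy]
    else:
        annotations_all = annotate_fallback(atoms)
        heavy_atoms = atoms[heavy]
        annotations = annotations_all[heavy].reset_index(drop=True)
        lig_mask = lig_mask_all[heavy]
    if not lig_mask.any():
        raise GridbindError(f"{structure_path}: no ligand atoms among the heavy atoms")
    records = _atoms_to_records(heavy_atoms, annotations, lig_mask)
    cid = complex_id if complex_id is not None else structure_path.stem
    return ComplexFrame(cid, records, replicate_id=CRYSTAL_REPLICATE, frame_index=0,
                        label_pk=label_pk)


def write_structure_pdb(frame: ComplexFrame, path, ligand_resname: str = "LIG") -> None:
    """Write a frame as a single-model PDB (ligand atoms as HETATM)."""
    n = len(frame.atoms)
    atoms = struc.AtomArray(n)
    atoms.coord = frame.coords().astype(np.float32)
    for i, a in enumerate(frame.atoms):
        is_lig = a.role == "ligand"
        atoms.element[i] = a.element.upper()
        atoms.atom_name[i] = f"{a.element.upper()}{i % 100}"
        atoms.hetero[i] = is_lig
        if is_lig:
            atoms.chain_id[i] = "L"
            atoms.res_id[i] = 900
            atoms.res_name[i] = ligand_resname
        else:
            chain, _, rid = a.residue_id.partition(":")
            atoms.chain_id[i] = chain or "A"
            atoms.res_id[i] = int(rid) if rid else 1
            atoms.res_name[i] = "ALA"
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def write_annotations_csv(frame: ComplexFrame, path) -> None:
    """Sidecar annotation table matching the heavy-atom order of the PDB."""
    rows = [{c: getattr(a, c) for c in ANNOTATION_COLUMNS} for a in frame.atoms]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


# -- trajectories --------------------------------------------------------

_STR_FIELDS = ("element", "role", "residue_id")


def _atoms_to_h5(group: h5py.Group, atoms: list[AtomRecord]) -> None:
    sub = group.create_group("atoms")
    enc = lambda values: np.array([v.encode() for v in values])
    sub.create_dataset("element", data=enc([a.element for a in atoms]))
    sub.create_dataset("role", data=enc([a.role for a in atoms]))
    sub.create_dataset("residue_id", data=enc([a.residue_id for a in atoms]))
    sub.create_dataset("partial_charge", data=np.array([a.partial_charge for a in atoms]))
    sub.create_dataset("hybridization", data=np.array([a.hybridization for a in atoms]))
    sub.create_dataset("heavy_valence", data=np.array([a.heavy_valence for a in atoms]))
    sub.create_dataset("hetero_valence", data=np.array([a.hetero_valence for a in atoms]))
    for f in _FLAG_FIELDS:
        sub.create_dataset(f, data=np.array([getattr(a, f) for a in atoms], dtype=bool))


def _atoms_from_h5(group: h5py.Group) -> list[AtomRecord]:
    sub = group["atoms"]
    n = sub["element"].shape[0]
    dec = {name: [_as_str(v) for v in sub[name][()]] for name in _STR_FIELDS}
    nums = {name: sub[name][()] for name in
            ("partial_charge", "hybridization", "heavy_valence", "hetero_valence") + _FLAG_FIELDS}
    return [AtomRecord(
        element=dec["element"][i], coords=np.zeros(3),
        partial_charge=float(nums["partial_charge"][i]),
        hybridization=int(nums["hybridization"][i]),
        heavy_valence=int(nums["heavy_valence"][i]),
        hetero_valence=int(nums["hetero_valence"][i]),
        **{f: bool(nums[f][i]) for f in _FLAG_FIELDS},
        role=dec["role"][i], residue_id=dec["residue_id"][i],
    ) for i in range(n)]


def write_trajectories_h5(path, trajectories: list[Trajectory]) -> None:
    """One HDF5 container per complex: shared atom roster + per-replicate coords."""
    if not trajectories:
        raise GridbindError("no trajectories to write")
    first = trajectories[0]
    with h5py.File(path, "w") as fh:
        fh.attrs["complex_id"] = first.complex_id
        fh.attrs["label_pk"] = np.nan if first.label_pk is None else float(first.label_pk)
        _atoms_to_h5(fh, first.topology)
        reps = fh.create_group("replicates")
        for traj in trajectories:
            if traj.complex_id != first.complex_id:
                raise GridbindError("all trajectories in one file must share a complex id")
            g = reps.create_group(f"rep_{traj.replicate_id:03d}")
            g.attrs["replicate_id"] = traj.replicate_id
            g.create_dataset("coords", data=traj.coords)
            g.create_dataset("frame_indices", data=traj.frame_indices)


def _traj_from_h5(fh: h5py.File, topology: list[AtomRecord], rep_name: str) -> Trajectory:
    g = fh["replicates"][rep_name]
    coords = np.asarray(g["coords"][()])
    if coords.ndim != 3 or coords.shape[-1] != 3:
        raise GridbindError("coordinates must be 3-dimensional: expected shape "
                            f"(T, n_atoms, 3), got {coords.shape}")
    label = float(fh.attrs["label_pk"])
    topo = [a.with_coords(c) for a, c in zip(topology, coords[0])]
    return Trajectory(str(fh.attrs["complex_id"]), int(g.attrs["replicate_id"]), topo,
                      coords, np.asarray(g["frame_indices"][()]),
                      None if np.isnan(label) else label)


def read_replicates_h5(path) -> list[Trajectory]:
    """All replicate trajectories stored in one HDF5 container."""
    with h5py.File(path, "r") as fh:
        topology = _atoms_from_h5(fh)
        names = sorted(fh["replicates"].keys())
        return [_traj_from_h5(fh, topology, name) for name in names]


def read_trajectory(path, replicate_id: int | None = None, **read_complex_kwargs) -> Trajectory:
    """Read one replicate trajectory from HDF5 or from a multi-model PDB.

    For HDF5 containers holding several replicates, ``replicate_id`` selects
    one (default: the first).  For multi-model PDB the frame index is the
    model order and ``read_complex_kwargs`` (ligand selection, annotations)
    are forwarded to :func:`read_complex` semantics.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            topology = _atoms_from_h5(fh)
            names = sorted(fh["replicates"].keys())
            if not names:
                raise GridbindError(f"{path}: no replicates stored")
            if replicate_id is None:
                return _traj_from_h5(fh, topology, names[0])
            name = f"rep_{replicate_id:03d}"
            if name not in fh["replicates"]:
                raise GridbindError(f"{path}: no replicate {replicate_id}")
            return _traj_from_h5(fh, topology, name)
    # multi-model PDB
    stack = _read_structure(path, model=None)
    if stack.stack_depth() == 0:
        raise GridbindError(f"{path}: no models found")
    first = read_complex(path, **read_complex_kwargs)
    heavy = np.char.upper(stack.element) != "H"
    coords = np.asarray(stack.coord)[:, heavy, :]
    if coords.shape[1] != len(first.atoms):
        raise GridbindError(f"{path}: atom count differs across models")
    rep = replicate_id if replicate_id is not None else 0
    topo = [a for a in first.atoms]
    return Trajectory(first.complex_id, rep, topo, coords.astype(float),
                      np.arange(coords.shape[0]), first.label_pk)


# -- grid datasets -------------------------------------------------------

GRID_ATTRS = ("edge_A", "resolution_A", "channels", "centering")


def _as_str(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def write_grid_dataset(path, splits: dict, edge_A: float, resolution_A: float,
                       centering: str, channels=CHANNELS) -> None:
    """Write voxel grids (or grid sequences) to HDF5.

    ``splits`` maps a split name to ``(grids, labels, complex_ids)`` where
    ``grids`` is ``(N, C, D, D, D)`` or ``(N, T, C, D, D, D)``.  Dataset
    attributes record the grid edge (Å), resolution (Å), channel names and
    centering mode; the round trip is bit-exact.  A ``.npz`` path selects
    the NumPy dialect (one named-array container holding every split).
    """
    if str(path).endswith(".npz"):
        _write_grid_npz(path, splits, edge_A, resolution_A, centering, channels)
        return
    with h5py.File(path, "w") as fh:
        fh.attrs["edge_A"] = float(edge_A)
        fh.attrs["resolution_A"] = float(resolution_A)
        fh.attrs["channels"] = [c.encode() for c in channels]
        fh.attrs["centering"] = centering
        for split, (grids, labels, complex_ids) in splits.items():
            grids = np.asarray(grids)
            if grids.ndim not in (5, 6):
                raise GridbindError(f"grids must be (N,C,D,D,D) or (N,T,C,D,D,D), got {grids.shape}")
            cax = 1 if grids.ndim == 5 else 2
            if grids.shape[cax] != len(channels):
                raise GridbindError(f"split {split!r}: {grids.shape[cax]} channels but "
                                    f"{len(channels)} channel names")
            g = fh.create_group(split)
            g.create_dataset("grids", data=grids, compression="gzip", compression_opts=1)
            g.create_dataset("labels", data=np.asarray(labels, dtype=float))
            g.create_dataset("complex_ids", data=np.array([c.encode() for c in complex_ids]))


def _write_grid_npz(path, splits, edge_A, resolution_A, centering, channels) -> None:
    import json
    arrays = {"__attrs__": np.bytes_(json.dumps({
        "edge_A": float(edge_A), "resolution_A": float(resolution_A),
        "channels": list(channels), "centering": centering}).encode())}
    for split, (grids, labels, complex_ids) in splits.items():
        grids = np.asarray(grids)
        if grids.ndim not in (5, 6):
            raise GridbindError(f"grids must be (N,C,D,D,D) or (N,T,C,D,D,D), got {grids.shape}")
        if grids.shape[1 if grids.ndim == 5 else 2] != len(channels):
            raise GridbindError(f"split {split!r}: channel count does not match channel names")
        arrays[f"{split}/grids"] = grids
        arrays[f"{split}/labels"] = np.asarray(labels, dtype=float)
        arrays[f"{split}/complex_ids"] = np.array(list(complex_ids))
    np.savez_compressed(path, **arrays)


def _read_grid_npz(path, expected_channels) -> tuple[dict, dict]:
    import json
    with np.load(path) as archive:
        if "__attrs__" not in archive.files:
            raise GridbindError(f"{path}: grid dataset is missing its attributes record")
        attrs = json.loads(bytes(archive["__attrs__"]).decode())
        attrs["channels"] = tuple(attrs["channels"])
        for attr in GRID_ATTRS:
            if attr not in attrs:
                raise GridbindError(f"{path}: grid dataset is missing the {attr!r} attribute")
        if expected_channels is not None and attrs["channels"] != tuple(expected_channels):
            raise GridbindError(f"{path}: channel names do not match expectation")
        names = sorted({k.split("/")[0] for k in archive.files if "/" in k})
        splits = {s: (archive[f"{s}/grids"], archive[f"{s}/labels"],
                      [str(c) for c in archive[f"{s}/complex_ids"]]) for s in names}
    return splits, attrs


def read_grid_dataset(path, expected_channels=None) -> tuple[dict, dict]:
    """Inverse of :func:`write_grid_dataset`; returns ``(splits, attrs)``."""
    if str(path).endswith(".npz"):
        return _read_grid_npz(path, expected_channels)
    with h5py.File(path, "r") as fh:
        for attr in GRID_ATTRS:
            if attr not in fh.attrs:
                raise GridbindError(f"{path}: grid dataset is missing the {attr!r} attribute")
        attrs = {
            "edge_A": float(fh.attrs["edge_A"]),
            "resolution_A": float(fh.attrs["resolution_A"]),
            "channels": tuple(_as_str(c) for c in fh.attrs["channels"]),
            "centering": str(fh.attrs["centering"]),
        }
        if expected_channels is not None and attrs["channels"] != tuple(expected_channels):
            raise GridbindError(f"{path}: channel names do not match expectation")
        splits = {}
        for split in fh.keys():
            g = fh[split]
            splits[split] = (np.asarray(g["grids"][()]),
                             np.asarray(g["labels"][()]),
                             [_as_str(c) for c in g["complex_ids"][()]])
    return splits, attrs
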