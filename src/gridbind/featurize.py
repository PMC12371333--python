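"""Pocket extraction, atom encoding, box construction and voxelization.

The network input is a cubic box around the binding site (default edge 25 Å)
discretised into 1 Å³ voxels.  Each heavy atom contributes a 19-channel
feature vector to the voxel containing it; atoms falling in the same voxel
have their vectors summed, so the sum of a channel over the whole grid equals
the sum of that feature over in-box atoms (mass conservation).

Voxel binning is half-open: cell ``k`` along an axis covers
``[origin + k*res, origin + (k+1)*res)``; an atom exactly on the maximum face
of the box is dropped.  This makes the grid exactly equivariant under the 24
right-angle rotations of the cube about the box center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import permutations, product

import numpy as np
from scipy.spatial.transform import Rotation as ScipyRotation

from .datatypes import AtomRecord, ComplexFrame, Trajectory
from .errors import GridbindError

logger = logging.getLogger(__name__)

#: the frozen 19-channel layout, recorded in every grid dataset's metadata
CHANNELS = (
    "type_B", "type_C", "type_N", "type_O", "type_P", "type_S", "type_Se",
    "type_halogen", "type_metal",
    "hybridization", "heavy_valence", "hetero_valence",
    "hydrophobic", "aromatic", "acceptor", "donor", "ring",
    "partial_charge", "moltype",
)

N_CHANNELS = len(CHANNELS)

_TYPE_INDEX = {"B": 0, "C": 1, "N": 2, "O": 3, "P": 4, "S": 5, "SE": 6}
HALOGENS = frozenset({"F", "CL", "BR", "I"})
_NON_METALS = frozenset({"H", "D", "B", "C", "N", "O", "P", "S", "SE"})

_warned_elements: set[str] = set()

CENTERINGS = ("pocket", "ligand_tracking")
KEEP_MODES = ("complex", "protein_only", "ligand_only")


def encode_atom(atom: AtomRecord) -> np.ndarray:
    """Deterministic 19-vector for one heavy atom.

    Channels 0-8 are a one-hot atom-type code (B, C, N, O, P, S, Se, halogen,
    metal); the halogen class is {F, Cl, Br, I} and the metal class is every
    element outside B/C/N/O/P/S/Se/H and outside the halogens.  Unclassifiable
    symbols leave all type flags at zero (logged once per element).  Channel 18
    ("moltype") is +1 for protein atoms and -1 for ligand atoms.
    """
    v = np.zeros(N_CHANNELS)
    el = atom.element.strip().upper()
    if el in _TYPE_INDEX:
        v[_TYPE_INDEX[el]] = 1.0
    elif el in HALOGENS:
        v[7] = 1.0
    elif el and el not in _NON_METALS:
        v[8] = 1.0
    else:
        if el not in _warned_elements:
            _warned_elements.add(el)
            logger.warning("element %r has no atom-type class; type flags left at zero", atom.element)
    v[9] = atom.hybridization
    v[10] = atom.heavy_valence
    v[11] = atom.hetero_valence
    v[12] = float(atom.is_hydrophobic)
    v[13] = float(atom.is_aromatic)
    v[14] = float(atom.is_acceptor)
    v[15] = float(atom.is_donor)
    v[16] = float(atom.is_ring)
    v[17] = atom.partial_charge
    v[18] = 1.0 if atom.role == "protein" else -1.0
    return v


def encode_frame(frame: ComplexFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(coords (n,3), features (n,19))`` for a frame's heavy atoms."""
    n = len(frame.atoms)
    coords = frame.coords()
    feats = np.zeros((n, N_CHANNELS))
    for i, a in enumerate(frame.atoms):
        feats[i] = encode_atom(a)
    return coords, feats


def extract_pocket(crystal_frame: ComplexFrame, radius_A: float = 12.0) -> set[str]:
    """Residues with >= 1 heavy atom within ``radius_A`` of the ligand center.

    The ligand center is the unweighted mean of the ligand heavy-atom
    coordinates of the crystallographic pose; the boundary is inclusive.  The
    selection is meant to be computed once on the crystal pose and reused for
    every frame and replicate of the complex.
    """
    center = crystal_frame.ligand_center()
    selected: set[str] = set()
    for atom in crystal_frame.atoms:
        if atom.role != "protein":
            continue
        if np.linalg.norm(atom.coords - center) <= radius_A:
            selected.add(atom.residue_id)
    return selected


@dataclass(frozen=True)
class Rotation:
    """A proper rotation: 3x3 orthonormal matrix with determinant +1.

    ``tag`` is the systematic index 0-23 for the right-angle rotations of the
    cube, or ``"random"`` for a rotation drawn at random.
    """

    matrix: np.ndarray
    tag: int | str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise GridbindError("rotation matrix must be 3x3")
        if np.max(np.abs(m @ m.T - np.eye(3))) > 1e-10:
            raise GridbindError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(m) - 1.0) > 1e-10:
            raise GridbindError("rotation matrix must have determinant +1")


def enumerate_rotations() -> list[Rotation]:
    """The 24 right-angle rotations of the cube (proper octahedral group).

    Generated as the signed permutation matrices with determinant +1; the
    identity comes first and the order is deterministic.
    """
    mats = []
    for perm in permutations(range(3)):
        for signs in product((1.0, -1.0), repeat=3):
            m = np.zeros((3, 3))
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if np.linalg.det(m) > 0:
                mats.append(m)
    mats.sort(key=lambda m: -np.trace(m))  # identity (trace 3) first
    return [Rotation(m, i) for i, m in enumerate(mats)]


def random_rotation(rng: np.random.Generator, kind: str = "right_angle") -> Rotation:
    """One random rotation: uniform over the 24 cube rotations, or uniform on SO(3)."""
    if kind == "right_angle":
        rots = enumerate_rotations()
        return Rotation(rots[int(rng.integers(len(rots)))].matrix, "random")
    if kind == "so3":
        return Rotation(ScipyRotation.random(rng=rng).as_matrix(), "random")
    raise GridbindError(f"unknown rotation kind {kind!r}")


def apply_rotation(frame: ComplexFrame, rotation: Rotation, pivot: np.ndarray) -> ComplexFrame:
    """Rotate all atom coordinates about ``pivot``; features are unchanged."""
    pivot = np.asarray(pivot, dtype=float)
    coords = frame.coords()
    rotated = (coords - pivot) @ rotation.matrix.T + pivot
    return frame.with_coords(rotated)


def mask_partner(frame: ComplexFrame, keep: str = "complex") -> ComplexFrame:
    """Remove the protein or the ligand partner (bias-ablation inputs).

    Box-centering metadata is deliberately not touched here: an "only ligand"
    frame still gets pocket-centered boxes unless ligand tracking is requested
    separately when voxelizing.
    """
    if keep not in KEEP_MODES:
        raise GridbindError(f"keep must be one of {KEEP_MODES}, got {keep!r}")
    if keep == "complex":
        return frame
    role = "protein" if keep == "protein_only" else "ligand"
    atoms = [a for a in frame.atoms if a.role == role]
    if not atoms:
        raise GridbindError(f"complex {frame.complex_id!r}: mask {keep!r} removes every atom")
    return replace(frame, atoms=atoms)


@dataclass
class VoxelGrid:
    """A C x D x D x D feature grid with its placement metadata."""

    values: np.ndarray
    edge_A: float
    resolution_A: float
    origin: np.ndarray
    centering: str

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def D(self) -> int:
        return self.values.shape[1]

    @property
    def center(self) -> np.ndarray:
        return self.origin + self.edge_A / 2.0


@dataclass
class VoxelSequence:
    """An ordered list of T voxel grids sharing shape and centering."""

    grids: list[VoxelGrid]
    label_pk: float | None = None

    def __post_init__(self) -> None:
        if not self.grids:
            raise GridbindError("a voxel sequence needs at least one grid")
        shape = self.grids[0].values.shape
        centering = self.grids[0].centering
        for g in self.grids[1:]:
            if g.values.shape != shape or g.centering != centering:
                raise GridbindError("all grids of a sequence must share shape and centering")

    def __len__(self) -> int:
        return len(self.grids)

    def to_array(self) -> np.ndarray:
        return np.stack([g.values for g in self.grids])


def _grid_dim(edge_A: float, resolution_A: float) -> int:
    d = edge_A / resolution_A
    if abs(d - round(d)) > 1e-9:
        raise GridbindError(f"edge {edge_A} Å is not an integer multiple of resolution {resolution_A} Å")
    return int(round(d))


def voxelize_points(coords: np.ndarray, feats: np.ndarray, center: np.ndarray,
                    edge_A: float = 25.0, resolution_A: float = 1.0,
                    centering: str = "pocket", out_dtype=np.float64) -> VoxelGrid:
    """Bin point features into a cubic grid centered at ``center``.

    Atoms whose voxel index falls outside ``[0, D)`` on any axis are dropped;
    colliding atoms' feature vectors are summed elementwise.
    """
    d = _grid_dim(edge_A, resolution_A)
    center = np.asarray(center, dtype=float)
    origin = center - edge_A / 2.0
    idx = np.floor((coords - origin) / resolution_A).astype(int)
    inside = np.all((idx >= 0) & (idx < d), axis=1)
    acc = np.zeros((d * d * d, feats.shape[1]), dtype=out_dtype)
    if inside.any():
        flat = (idx[inside, 0] * d + idx[inside, 1]) * d + idx[inside, 2]
        np.add.at(acc, flat, feats[inside])
    values = acc.T.reshape(feats.shape[1], d, d, d)
    return VoxelGrid(values, edge_A, resolution_A, origin, centering)


def make_box(frame: ComplexFrame, centering: str = "pocket", edge_A: float = 25.0,
             resolution_A: float = 1.0, center: np.ndarray | None = None,
             rotation: Rotation | None = None) -> VoxelGrid:
    """Voxelize one frame.

    In ``pocket`` mode the box center is the crystal-pose ligand geometric
    center, fixed for all frames of a complex: pass it as ``center`` when
    voxelizing a non-crystal frame (when ``center`` is None the current
    frame's ligand center is used, which is correct for the crystal pose
    itself).  In ``ligand_tracking`` mode the box follows the current frame's
    ligand center.  An optional rotation is applied to the coordinates about
    the box center before binning.
    """
    if centering not in CENTERINGS:
        raise GridbindError(f"centering must be one of {CENTERINGS}, got {centering!r}")
    if not frame.atoms:
        raise GridbindError("cannot voxelize an empty frame")
    coords, feats = encode_frame(frame)
    if centering == "ligand_tracking" or center is None:
        box_center = frame.ligand_center()
    else:
        box_center = np.asarray(center, dtype=float)
    if rotation is not None:
        pivot = np.asarray(center, dtype=float) if center is not None else box_center
        coords = (coords - pivot) @ rotation.matrix.T + pivot
        if centering == "ligand_tracking":
            roles = frame.roles()
            box_center = coords[roles == "ligand"].mean(axis=0)
    return voxelize_points(coords, feats, box_center, edge_A, resolution_A, centering)


def rotate_grid(values: np.ndarray, rotation: Rotation) -> np.ndarray:
    """Apply a right-angle rotation about the box center directly to a grid.

    For the 24 cube rotations (signed permutation matrices) the voxel lattice
    maps onto itself: axis ``i`` of the result is axis ``p(i)`` of the input,
    flipped when the sign is negative.  With half-open binning this agrees
    voxel-for-voxel with rotating the atom coordinates and re-voxelizing, for
    atoms not exactly on a cell boundary.
    """
    m = rotation.matrix
    if not np.allclose(np.abs(m).sum(axis=1), 1.0) or not np.allclose(np.abs(m) * (np.abs(m) - 1), 0, atol=1e-12):
        raise GridbindError("rotate_grid needs one of the 24 right-angle rotations")
    ndim = values.ndim
    lead = ndim - 3  # leading non-spatial axes (channels, batch...)
    perm, signs = [], []
    for i in range(3):
        j = int(np.argmax(np.abs(m[i])))
        perm.append(j)
        signs.append(float(np.sign(m[i, j])))
    out = np.transpose(values, tuple(range(lead)) + tuple(lead + p for p in perm))
    flip_axes = tuple(lead + i for i in range(3) if signs[i] < 0)
    if flip_axes:
        out = np.flip(out, axis=flip_axes)
    return np.ascontiguousarray(out)


def voxelize_trajectory(traj: Trajectory, centering: str = "pocket", edge_A: float = 25.0,
                        resolution_A: float = 1.0, rotation: Rotation | None = None,
                        center: np.ndarray | None = None) -> VoxelSequence:
    """Voxelize every frame of a trajectory into a sequence of grids.

    Pocket mode uses one fixed box center for all frames (the first frame's
    ligand center unless ``center`` is given); tracking mode recenters on the
    ligand at every frame.  One rotation (same matrix, same pivot) is applied
    consistently to every frame.
    """
    if centering not in CENTERINGS:
        raise GridbindError(f"centering must be one of {CENTERINGS}, got {centering!r}")
    topo_coords, feats = encode_frame(traj.frame(0))
    roles = np.array([a.role for a in traj.topology])
    lig_mask = roles == "ligand"
    if not lig_mask.any():
        raise GridbindError(f"complex {traj.complex_id!r}: no ligand atoms")
    if center is None:
        pivot = traj.coords[0][lig_mask].mean(axis=0)
    else:
        pivot = np.asarray(center, dtype=float)
    grids = []
    for t in range(traj.n_frames):
        coords = traj.coords[t]
        if rotation is not None:
            coords = (coords - pivot) @ rotation.matrix.T + pivot
        if centering == "pocket":
            box_center = pivot
        else:
            box_center = coords[lig_mask].mean(axis=0)
        grids.append(voxelize_points(coords, feats, box_center, edge_A, resolution_A, centering))
    return VoxelSequence(grids, label_pk=traj.label_pk)
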