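"""Domain types: atoms, frames, trajectories, manifests and predictions.

The unit conventions used throughout the package:

* coordinates are in angstroms (Å), treated as continuous values;
* partial charges are in elementary charge units;
* affinity labels are on the pK scale, i.e. -log10 of a dissociation or
  inhibition constant (Kd/Ki) in molar units.

A *complex* is one protein-ligand pair identified by ``complex_id``.  Each
complex has a crystallographic pose (modelled as replicate ``-1``) and any
number of replicate molecular-dynamics simulations (replicates ``0, 1, ...``),
each an ordered sequence of frames sharing one atom roster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import GridbindError, LeakageError

ROLES = ("protein", "ligand")
SPLITS = ("train", "val", "test")

MANIFEST_COLUMNS = ["complex_id", "label_pk", "split", "protein_family", "cluster_id"]
PREDICTION_COLUMNS = ["complex_id", "replicate_id", "frame_index", "model_replicate", "predicted_pk"]

#: replicate id reserved for the crystallographic pose
CRYSTAL_REPLICATE = -1


@dataclass
class AtomRecord:
    """One heavy atom with its voxel-feature annotations.

    ``hybridization`` follows the 1/2/3 convention (sp, sp2, sp3; 3 also used
    for other/unknown).  ``heavy_valence`` counts bonds to heavy atoms and
    ``hetero_valence`` counts bonds to heteroatoms (non C/H).  ``residue_id``
    is a chain+residue identifier for protein atoms and empty for ligand atoms.
    """

    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    hybridization: int = 3
    heavy_valence: int = 0
    hetero_valence: int = 0
    is_hydrophobic: bool = False
    is_aromatic: bool = False
    is_acceptor: bool = False
    is_donor: bool = False
    is_ring: bool = False
    role: str = "protein"
    residue_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise GridbindError(f"atom coords must be a 3-vector, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise GridbindError("atom coords must be finite")
        if self.role not in ROLES:
            raise GridbindError(f"atom role must be one of {ROLES}, got {self.role!r}")
        if self.hybridization not in (1, 2, 3):
            raise GridbindError(f"hybridization must be in {{1,2,3}}, got {self.hybridization}")
        if self.heavy_valence < 0 or self.hetero_valence < 0:
            raise GridbindError("valence counts must be non-negative")

    def with_coords(self, coords: np.ndarray) -> "AtomRecord":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class ComplexFrame:
    """One time point of one complex: an ordered atom list plus provenance."""

    complex_id: str
    atoms: list[AtomRecord]
    replicate_id: int = CRYSTAL_REPLICATE
    frame_index: int = 0
    label_pk: float | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise GridbindError("frame_index must be >= 0")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) array of atom coordinates in file order."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(len(self.atoms), 3)

    def roles(self) -> np.ndarray:
        return np.array([a.role for a in self.atoms])

    def ligand_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.role == "ligand"]

    def protein_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.role == "protein"]

    def ligand_center(self) -> np.ndarray:
        """Unweighted geometric center of the ligand heavy atoms."""
        lig = self.ligand_atoms()
        if not lig:
            raise GridbindError(f"complex {self.complex_id!r}: no ligand atoms")
        return np.mean([a.coords for a in lig], axis=0)

    def with_coords(self, coords: np.ndarray) -> "ComplexFrame":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise GridbindError(f"expected coords shape {(len(self.atoms), 3)}, got {coords.shape}")
        atoms = [a.with_coords(c) for a, c in zip(self.atoms, coords)]
        return replace(self, atoms=atoms)


def _roster_signature(atoms: Sequence[AtomRecord]) -> tuple:
    return tuple((a.element, a.role, a.residue_id) for a in atoms)


@dataclass
class Trajectory:
    """Ordered frames of one replicate simulation of one complex.

    Stored as one topology roster (the atoms of the first frame) plus a
    ``(T, n_atoms, 3)`` coordinate array; :meth:`frame` materialises a
    :class:`ComplexFrame` on demand so that large datasets never hold millions
    of atom objects at once.  All frames share the complex id, replicate id and
    atom roster, and ``frame_indices`` is strictly increasing.
    """

    complex_id: str
    replicate_id: int
    topology: list[AtomRecord]
    coords: np.ndarray
    frame_indices: np.ndarray | None = None
    label_pk: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise GridbindError("coordinates must be 3-dimensional: expected shape (T, n_atoms, 3), "
                                f"got {self.coords.shape}")
        if self.coords.shape[1] != len(self.topology):
            raise GridbindError(f"coordinate array has {self.coords.shape[1]} atoms but the "
                                f"topology has {len(self.topology)}")
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.coords.shape[0])
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.frame_indices.shape != (self.coords.shape[0],):
            raise GridbindError("frame_indices length must match the number of frames")
        if len(self.frame_indices) and np.any(np.diff(self.frame_indices) <= 0):
            raise GridbindError("frame_index must be strictly increasing")

    @classmethod
    def from_frames(cls, frames: Sequence[ComplexFrame], label_pk: float | None = None) -> "Trajectory":
        if not frames:
            raise GridbindError("a trajectory needs at least one frame")
        first = frames[0]
        sig = _roster_signature(first.atoms)
        for f in frames[1:]:
            if f.complex_id != first.complex_id or f.replicate_id != first.replicate_id:
                raise GridbindError("all frames of a trajectory must share complex_id and replicate_id")
            if _roster_signature(f.atoms) != sig:
                raise GridbindError(f"complex {first.complex_id!r}: atom roster differs between frames")
        coords = np.stack([f.coords() for f in frames])
        idx = np.array([f.frame_index for f in frames])
        if label_pk is None:
            label_pk = first.label_pk
        return cls(first.complex_id, first.replicate_id, list(first.atoms), coords, idx, label_pk)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, t: int) -> ComplexFrame:
        atoms = [a.with_coords(c) for a, c in zip(self.topology, self.coords[t])]
        return ComplexFrame(self.complex_id, atoms, self.replicate_id,
                            int(self.frame_indices[t]), self.label_pk)

    @property
    def frames(self) -> list[ComplexFrame]:
        """Materialised frame list (convenience; prefer :meth:`frame` for large T)."""
        return [self.frame(t) for t in range(self.n_frames)]

    def iter_frames(self) -> Iterator[ComplexFrame]:
        for t in range(self.n_frames):
            yield self.frame(t)


@dataclass
class Manifest:
    """Complex-level bookkeeping: label, split, protein family and cluster.

    Every complex appears exactly once, so the train/val/test id sets are
    pairwise disjoint by construction; :meth:`check` enforces this and is
    called before any training run.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise GridbindError(f"manifest is missing columns {missing}")
        self.table = self.table[MANIFEST_COLUMNS].reset_index(drop=True)

    def check(self) -> None:
        dup = self.table["complex_id"][self.table["complex_id"].duplicated()]
        if len(dup):
            raise LeakageError(f"complex ids appear in more than one manifest row: {sorted(set(dup))}")
        bad = set(self.table["split"]) - set(SPLITS)
        if bad:
            raise GridbindError(f"unknown split names {sorted(bad)}; expected {SPLITS}")
        for a in SPLITS:
            for b in SPLITS:
                if a < b:
                    overlap = set(self.ids(a)) & set(self.ids(b))
                    if overlap:
                        raise LeakageError(f"complexes in both {a!r} and {b!r}: {sorted(overlap)}")

    def ids(self, split: str | None = None) -> list[str]:
        if split is None:
            return list(self.table["complex_id"])
        return list(self.table.loc[self.table["split"] == split, "complex_id"])

    def labels(self) -> dict[str, float]:
        return dict(zip(self.table["complex_id"], self.table["label_pk"].astype(float)))

    def families(self) -> list[str]:
        return sorted(set(self.table["protein_family"]))

    def clusters(self) -> dict[str, str]:
        return dict(zip(self.table["complex_id"], self.table["cluster_id"]))

    @classmethod
    def from_csv(cls, path) -> "Manifest":
        return cls(pd.read_csv(path, dtype={"complex_id": str, "split": str,
                                            "protein_family": str, "cluster_id": str}))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PredictionSet:
    """Per-entity predictions with provenance.

    One row per predicted entity: a crystal pose (``replicate_id == -1``), a
    single frame, or a whole simulation (``frame_index == -1``), from one
    trained model replicate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PREDICTION_COLUMNS if c not in self.table.columns]
        if missing:
            raise GridbindError(f"prediction table is missing columns {missing}")
        self.table = self.table[PREDICTION_COLUMNS].reset_index(drop=True)
        vals = self.table["predicted_pk"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise GridbindError("predicted_pk must be finite")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "PredictionSet":
        return cls(pd.DataFrame(rows, columns=PREDICTION_COLUMNS))

    @classmethod
    def concat(cls, parts: Sequence["PredictionSet"]) -> "PredictionSet":
        return cls(pd.concat([p.table for p in parts], ignore_index=True))

    def per_complex(self) -> pd.Series:
        """Arithmetic mean of the entity-level predictions for each complex."""
        if self.table.empty:
            raise GridbindError("cannot aggregate an empty prediction set")
        return self.table.groupby("complex_id")["predicted_pk"].mean()

    @classmethod
    def from_csv(cls, path) -> "PredictionSet":
        return cls(pd.read_csv(path, dtype={"complex_id": str}))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)
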