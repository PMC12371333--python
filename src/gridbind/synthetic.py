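"""Synthetic protein-ligand complexes with a planted, recoverable signal.

The generator emulates the *shape* of a pocket/ligand MD dataset at desk
scale, not its physics.  Each complex is a rigid pseudo-pocket shell (atoms
scattered on a sphere whose radius varies between complexes) plus a small
ligand sampled inside it.  The affinity label is a known linear function of
the number of ligand-pocket atom pairs within a contact radius, plus
Gaussian noise, clipped to [0, 14] pK:

    pK = a + b * n_contacts + N(0, sigma)

Because the shell radius varies across complexes, neither partner alone
determines the contact count, so partner-ablated models must lose accuracy -
a planted analogue of the bias-gap protocol.

Replicate trajectories move the ligand as a rigid body along a random walk
whose per-frame step scales inversely with affinity,

    sigma_drift(pK) = s0 + s1 * max(0, pk_mid - pK),

so low-affinity ligands drift further (larger max RMSD), mirroring the
observed link between ligand stability in the site and affinity.  Pocket
atoms get small independent jitter.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datatypes import AtomRecord, ComplexFrame, Manifest, Trajectory, CRYSTAL_REPLICATE
from .errors import GridbindError
from . import io as gb_io

_POCKET_ELEMENTS = ("C", "C", "C", "N", "O", "S")
_LIGAND_ELEMENTS = ("C", "C", "N", "O", "S", "CL")


@dataclass
class SyntheticSpec:
    """Generator parameters; the defaults define the study conditions.

    120 complexes with 10 replicate trajectories of 50 frames each reproduce
    the shape of the real corpus (500 frames per complex) at desk scale.
    """

    n_complexes: int = 120
    n_replicates: int = 10
    n_frames: int = 50
    # geometry (Å)
    shell_radius_range: tuple = (6.5, 10.0)
    n_pocket_atoms: int = 60
    shell_thickness_sd: float = 0.3
    ligand_atom_range: tuple = (4, 10)
    ligand_radius_A: float = 3.5
    contact_radius_A: float = 5.5
    # planted affinity signal (pK units)
    affinity_intercept: float = 2.5
    affinity_per_contact: float = 0.12
    affinity_noise_sd: float = 0.35
    # affinity-dependent ligand drift (Å per frame step)
    drift_base_sd: float = 0.08
    drift_affinity_slope: float = 0.06
    drift_pk_mid: float = 6.5
    pocket_jitter_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_complexes < 1 or self.n_replicates < 1 or self.n_frames < 1:
            raise GridbindError("counts must be >= 1")
        for name in ("affinity_noise_sd", "drift_base_sd", "drift_affinity_slope",
                     "pocket_jitter_sd", "shell_thickness_sd"):
            if getattr(self, name) < 0:
                raise GridbindError(f"{name} must be >= 0")
        if self.shell_radius_range[0] > self.shell_radius_range[1]:
            raise GridbindError("shell_radius_range must be (low, high)")
        if self.ligand_atom_range[0] > self.ligand_atom_range[1] or self.ligand_atom_range[0] < 1:
            raise GridbindError("ligand_atom_range must be (low, high) with low >= 1")


def count_contacts(frame: ComplexFrame, radius_A: float) -> int:
    """Number of (ligand atom, pocket atom) pairs within ``radius_A``."""
    lig = np.array([a.coords for a in frame.atoms if a.role == "ligand"])
    prot = np.array([a.coords for a in frame.atoms if a.role == "protein"])
    if len(lig) == 0 or len(prot) == 0:
        return 0
    return int(np.sum(cdist(lig, prot) <= radius_A))


def drift_sd(spec: SyntheticSpec, label_pk: float) -> float:
    """Per-frame random-walk step of the ligand for a given affinity."""
    return spec.drift_base_sd + spec.drift_affinity_slope * max(0.0, spec.drift_pk_mid - label_pk)


def _sphere_points(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _make_atom(rng: np.random.Generator, element: str, coords: np.ndarray,
               role: str, residue_id: str) -> AtomRecord:
    return AtomRecord(
        element=element, coords=coords,
        partial_charge=float(np.round(rng.normal(0.0, 0.15), 4)),
        hybridization=int(rng.choice((1, 2, 3), p=(0.1, 0.3, 0.6))),
        heavy_valence=int(rng.integers(1, 5)),
        hetero_valence=int(rng.integers(0, 3)),
        is_hydrophobic=element == "C" and rng.random() < 0.7,
        is_aromatic=bool(rng.random() < 0.25),
        is_acceptor=element in ("N", "O"),
        is_donor=element in ("N", "O") and rng.random() < 0.5,
        is_ring=bool(rng.random() < 0.3),
        role=role, residue_id=residue_id,
    )


def generate_complex(spec: SyntheticSpec, rng: np.random.Generator,
                     complex_id: str = "SYN_0000") -> ComplexFrame:
    """One pseudo-complex with its planted affinity label.

    Pocket atoms sit on a spherical shell around the origin (4 atoms per
    pseudo-residue); ligand atoms are sampled inside.  The label is
    ``a + b * contacts + noise`` clipped to [0, 14] pK.
    """
    shell_r = float(rng.uniform(*spec.shell_radius_range))
    n_p = spec.n_pocket_atoms
    radii = shell_r + rng.normal(0.0, spec.shell_thickness_sd, n_p)
    pocket_coords = _sphere_points(rng, n_p) * radii[:, None]
    atoms = []
    for i in range(n_p):
        el = str(rng.choice(_POCKET_ELEMENTS))
        atoms.append(_make_atom(rng, el, pocket_coords[i], "protein", f"A:{i // 4 + 1}"))
    n_l = int(rng.integers(spec.ligand_atom_range[0], spec.ligand_atom_range[1] + 1))
    lig_dirs = _sphere_points(rng, n_l)
    lig_radii = spec.ligand_radius_A * rng.random(n_l) ** (1.0 / 3.0)
    lig_coords = lig_dirs * lig_radii[:, None]
    for i in range(n_l):
        el = str(rng.choice(_LIGAND_ELEMENTS))
        atoms.append(_make_atom(rng, el, lig_coords[i], "ligand", ""))
    frame = ComplexFrame(complex_id, atoms)
    contacts = count_contacts(frame, spec.contact_radius_A)
    pk = spec.affinity_intercept + spec.affinity_per_contact * contacts
    pk += float(rng.normal(0.0, spec.affinity_noise_sd))
    frame.label_pk = float(np.clip(pk, 0.0, 14.0))
    return frame


def generate_trajectory(complex_frame: ComplexFrame, spec: SyntheticSpec,
                        rng: np.random.Generator, replicate_id: int = 0) -> Trajectory:
    """One replicate trajectory: frame 0 is the input pose; the ligand then
    follows a rigid-body translation random walk with affinity-dependent
    step size while pocket atoms get independent Gaussian jitter."""
    if complex_frame.label_pk is None:
        raise GridbindError("the complex must carry an affinity label before simulation")
    T = spec.n_frames
    coords0 = complex_frame.coords()
    lig_mask = complex_frame.roles() == "ligand"
    sd = drift_sd(spec, complex_frame.label_pk)
    coords = np.tile(coords0, (T, 1, 1))
    if T > 1:
        steps = rng.normal(0.0, sd, (T - 1, 3)) if sd > 0 else np.zeros((T - 1, 3))
        offsets = np.cumsum(steps, axis=0)
        coords[1:, lig_mask, :] += offsets[:, None, :]
        if spec.pocket_jitter_sd > 0:
            n_prot = int((~lig_mask).sum())
            coords[1:, ~lig_mask, :] += rng.normal(0.0, spec.pocket_jitter_sd, (T - 1, n_prot, 3))
    topo = [a.with_coords(c) for a, c in zip(complex_frame.atoms, coords0)]
    return Trajectory(complex_frame.complex_id, replicate_id, topo, coords,
                      np.arange(T), complex_frame.label_pk)


def assign_splits(n: int, rng: np.random.Generator,
                  test_frac: float = 0.2, val_frac: float = 0.2) -> list[str]:
    """Complex-exclusive splits: ``test_frac`` held out, then an 80/20
    train/validation split of the remainder."""
    order = rng.permutation(n)
    n_test = int(round(n * test_frac))
    n_val = int(round((n - n_test) * val_frac))
    splits = np.empty(n, dtype=object)
    splits[order[:n_test]] = "test"
    splits[order[n_test:n_test + n_val]] = "val"
    splits[order[n_test + n_val:]] = "train"
    return list(splits)


@dataclass
class SyntheticDataset:
    """In-memory dataset: crystal poses, trajectories and the manifest."""

    spec: SyntheticSpec
    crystals: dict[str, ComplexFrame]
    trajectories: dict[str, list[Trajectory]]
    manifest: Manifest


def build_dataset(spec: SyntheticSpec, n_replicates: int | None = None) -> SyntheticDataset:
    """Generate the full dataset in memory (deterministic in ``spec.seed``).

    ``n_replicates`` can restrict how many of the configured replicates are
    actually simulated (the replicate rng streams are drawn in order, so the
    first k replicates are identical whether or not the rest are generated).
    """
    rng = np.random.default_rng(spec.seed)
    keep_reps = spec.n_replicates if n_replicates is None else n_replicates
    n_families = 6
    crystals: dict[str, ComplexFrame] = {}
    trajectories: dict[str, list[Trajectory]] = {}
    rows = []
    family_codes = rng.integers(0, n_families, spec.n_complexes)
    for i in range(spec.n_complexes):
        cid = f"SYN_{i:04d}"
        frame = generate_complex(spec, rng, cid)
        crystals[cid] = frame
        trajs = []
        for r in range(spec.n_replicates):
            traj = generate_trajectory(frame, spec, rng, replicate_id=r)
            if r < keep_reps:
                trajs.append(traj)
        trajectories[cid] = trajs
        rows.append({"complex_id": cid, "label_pk": frame.label_pk,
                     "protein_family": f"FAM{family_codes[i]}"})
    splits = assign_splits(spec.n_complexes, rng)
    for row, split in zip(rows, splits):
        row["split"] = split
    # CASF-style clusters: groups of 5 complexes within a family, spanning affinities
    order = sorted(range(len(rows)), key=lambda i: (rows[i]["protein_family"], rows[i]["label_pk"]))
    for rank, i in enumerate(order):
        rows[i]["cluster_id"] = f"{rows[i]['protein_family']}_c{rank // 5:02d}"
    manifest = Manifest(pd.DataFrame(rows))
    manifest.check()
    return SyntheticDataset(spec, crystals, trajectories, manifest)


def generate_dataset(spec: SyntheticSpec, out_dir) -> SyntheticDataset:
    """Generate and write the dataset to disk.

    Layout: ``structures/<id>.pdb`` + ``structures/<id>.atoms.csv`` (crystal
    poses with sidecar annotations), ``trajectories/<id>.h5`` (all replicate
    coordinate arrays over one roster), and ``manifest.csv``.  On failure the
    partially written output directory is removed.
    """
    out_dir = Path(out_dir)
    created = not out_dir.exists()
    try:
        (out_dir / "structures").mkdir(parents=True, exist_ok=True)
        (out_dir / "trajectories").mkdir(parents=True, exist_ok=True)
        ds = build_dataset(spec)
        for cid, frame in ds.crystals.items():
            gb_io.write_structure_pdb(frame, out_dir / "structures" / f"{cid}.pdb")
            gb_io.write_annotations_csv(frame, out_dir / "structures" / f"{cid}.atoms.csv")
            gb_io.write_trajectories_h5(out_dir / "trajectories" / f"{cid}.h5",
                                        ds.trajectories[cid])
        ds.manifest.to_csv(out_dir / "manifest.csv")
        return ds
    except Exception:
        if created and out_dir.exists():
            shutil.rmtree(out_dir)
        raise
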