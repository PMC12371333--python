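import numpy as np
import pytest

from gridbind.datatypes import AtomRecord, ComplexFrame
from gridbind.synthetic import SyntheticSpec, build_dataset


def make_atom(element="C", coords=(0.0, 0.0, 0.0), role="ligand", **kwargs):
    return AtomRecord(element=element, coords=np.asarray(coords, float), role=role, **kwargs)


def make_frame(atom_specs, complex_id="toy", label_pk=5.0):
    """atom_specs: list of (element, coords, role[, residue_id])."""
    atoms = []
    for spec in atom_specs:
        element, coords, role = spec[:3]
        residue_id = spec[3] if len(spec) > 3 else ("" if role == "ligand" else "A:1")
        atoms.append(make_atom(element, coords, role, residue_id=residue_id))
    return ComplexFrame(complex_id, atoms, label_pk=label_pk)


@pytest.fixture
def toy_frame():
    """2 protein atoms + 1 ligand atom."""
    return make_frame([
        ("C", (4.0, 0.0, 0.0), "protein", "A:1"),
        ("N", (0.0, 4.0, 0.0), "protein", "A:2"),
        ("O", (0.0, 0.0, 0.0), "ligand"),
    ])


@pytest.fixture(scope="session")
def small_dataset():
    """A desk-scale synthetic dataset shared by the cheaper tests."""
    spec = SyntheticSpec(n_complexes=24, n_replicates=2, n_frames=10, seed=7)
    return build_dataset(spec)


def random_frame(rng, n_protein=12, n_ligand=4, complex_id="rnd"):
    """A randomized toy complex: pocket atoms in a shell, ligand inside."""
    atoms = []
    elements = ["C", "N", "O", "S"]
    for i in range(n_protein):
        d = rng.normal(size=3)
        d = d / np.linalg.norm(d) * rng.uniform(5.0, 9.0)
        atoms.append(AtomRecord(
            element=elements[int(rng.integers(4))], coords=d,
            partial_charge=float(rng.normal(0, 0.2)),
            hybridization=int(rng.integers(1, 4)),
            heavy_valence=int(rng.integers(0, 4)),
            hetero_valence=int(rng.integers(0, 3)),
            is_aromatic=bool(rng.random() < 0.3),
            role="protein", residue_id=f"A:{i // 3 + 1}"))
    for _ in range(n_ligand):
        atoms.append(AtomRecord(
            element=elements[int(rng.integers(4))],
            coords=rng.normal(0, 1.5, 3),
            partial_charge=float(rng.normal(0, 0.2)),
            hybridization=int(rng.integers(1, 4)),
            role="ligand"))
    return ComplexFrame(complex_id, atoms, label_pk=5.0)
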