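import numpy as np
import pytest

from cntor.system import Atom, MolecularSystem, Trajectory


@pytest.fixture
def water_triple():
    """One water molecule: O, H1, H2."""
    atoms = [
        Atom(index=0, name="O", element="O", residue_index=0,
             residue_name="WAT", group="solvent", radius=1.52),
        Atom(index=1, name="H1", element="H", residue_index=0,
             residue_name="WAT", group="solvent", radius=1.2),
        Atom(index=2, name="H2", element="H", residue_index=0,
             residue_name="WAT", group="solvent", radius=1.2),
    ]
    coords = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]])
    return MolecularSystem(atoms), coords


@pytest.fixture
def peptide_system():
    """One residue with N, CA, C, O, CB plus a two-atom tube."""
    names = ["N", "CA", "C", "O", "CB"]
    atoms = [
        Atom(index=i, name=n, element="N" if n == "N" else ("O" if n == "O" else "C"),
             residue_index=0, residue_name="ALA", group="receptor", radius=1.7)
        for i, n in enumerate(names)
    ]
    atoms += [
        Atom(index=5, name="C", element="C", residue_index=1,
             residue_name="CNT", group="tube", radius=1.7),
        Atom(index=6, name="C", element="C", residue_index=1,
             residue_name="CNT", group="tube", radius=1.7),
    ]
    coords = np.array(
        [
            [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.2, 1.3, 0.0],
            [3.4, 1.3, 0.3], [1.9, -1.0, 1.1],
            [0.0, 0.0, 10.0], [1.4, 0.0, 10.0],
        ]
    )
    return MolecularSystem(atoms), coords


def make_chain_trajectory(frames):
    """Trajectory over a minimal Cα chain matching the frame atom count."""
    frames = np.asarray(frames, dtype=float)
    n_atoms = frames.shape[1]
    atoms = [
        Atom(index=i, name="CA", element="C", residue_index=i,
             residue_name="ALA", group="receptor", radius=1.7)
        for i in range(n_atoms)
    ]
    return Trajectory(MolecularSystem(atoms), frames)
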