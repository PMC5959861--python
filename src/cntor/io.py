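"""Readers and writers for the external text formats.

PDB parsing and writing delegate to biotite; a light pre-scan adds
per-model atom-count diagnostics. The XYZ trajectory format (count line,
comment line, ``elem x y z`` rows) is read and written directly. Parameter
tables and odor tables are delimited text handled through pandas.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .errors import FormatError, UnparameterizedAtomError
from .system import Atom, MolecularSystem, Trajectory, element_from_name

#: Residue names mapped to atom groups on import; anything else is receptor.
DEFAULT_GROUP_RULES: Dict[str, str] = {
    "CNT": "tube",
    "HOH": "solvent",
    "WAT": "solvent",
    "TIP3": "solvent",
    "SOL": "solvent",
}


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _scan_model_counts(text: str) -> list[int]:
    """Atom counts per MODEL block (one entry for model-less files)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not saw_model:
        counts = [current]
    elif in_model:  # MODEL without ENDMDL before EOF
        counts.append(current)
    return counts


def read_pdb(
    path,
    model_range: Optional[Tuple[int, int]] = None,
    dt: float = 1.0,
    group_rules: Optional[Dict[str, str]] = None,
) -> Trajectory:
    """Read a (multi-model) PDB file into a trajectory.

    One frame per MODEL, in file order; frame times default to
    ``frame index × dt`` ps. ``model_range`` is an inclusive 1-based
    (first, last) pair selecting a subset of models after reading.
    Atom groups are assigned from residue names via ``group_rules``
    (:data:`DEFAULT_GROUP_RULES` by default).
    """
    text = Path(path).read_text()
    counts = _scan_model_counts(text)
    if not counts or all(c == 0 for c in counts):
        raise FormatError(f"{path}: no ATOM/HETATM records")
    for i, c in enumerate(counts, start=1):
        if c != counts[0]:
            raise FormatError(
                f"{path}: model {i} has {c} atoms, expected {counts[0]} "
                f"(model 1)"
            )

    pdb = PDBFile.read(_io.StringIO(text))
    stack = pdb.get_structure(model=None)  # AtomArrayStack
    coords = np.asarray(stack.coord, dtype=float)  # (n_models, n_atoms, 3)

    rules = DEFAULT_GROUP_RULES if group_rules is None else group_rules
    atoms: list[Atom] = []
    residue_key_to_index: Dict[tuple, int] = {}
    arr = stack[0]
    for i in range(arr.array_length()):
        res_key = (arr.chain_id[i], int(arr.res_id[i]), arr.res_name[i])
        if res_key not in residue_key_to_index:
            residue_key_to_index[res_key] = len(residue_key_to_index)
        elem = str(arr.element[i]).strip() or element_from_name(str(arr.atom_name[i]))
        res_name = str(arr.res_name[i])
        atoms.append(
            Atom(
                index=i,
                name=str(arr.atom_name[i]),
                element=elem,
                residue_index=residue_key_to_index[res_key],
                residue_name=res_name,
                chain_id=str(arr.chain_id[i]),
                group=rules.get(res_name, "receptor"),
            )
        )
    system = MolecularSystem(atoms)
    if model_range is not None:
        lo, hi = model_range
        coords = coords[lo - 1 : hi]
        if coords.shape[0] == 0:
            raise FormatError(f"{path}: model range {model_range} selects no models")
    times = np.arange(coords.shape[0], dtype=float) * dt
    return Trajectory(system, coords, times)


def write_pdb(path, traj: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB file."""
    system = traj.system
    n = system.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.zeros((n, 3))
    arr.chain_id = np.array([a.chain_id for a in system.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_index + 1 for a in system.atoms])
    arr.res_name = np.array([a.residue_name for a in system.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in system.atoms], dtype="U6")
    arr.element = np.array([a.element for a in system.atoms], dtype="U2")
    arr.hetero = np.array(
        [a.group in ("tube", "solvent", "ligand") for a in system.atoms]
    )
    stack = bst.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.frames, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# XYZ trajectory
# ---------------------------------------------------------------------------

def read_xyz_trajectory(path, system: MolecularSystem, dt: float = 1.0) -> Trajectory:
    """Read an XYZ trajectory whose frames all match ``system``.

    The comment line is scanned for a ``t= <ps>`` tag; missing stamps fall
    back to ``frame index × dt``.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    times: list[Optional[float]] = []
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_no += 1
        try:
            count = int(lines[pos].split()[0])
        except ValueError as exc:
            raise FormatError(
                f"{path}: frame {frame_no}: expected an atom count, got "
                f"{lines[pos]!r}"
            ) from exc
        if count != system.n_atoms:
            raise FormatError(
                f"{path}: frame {frame_no} has {count} atoms, system has "
                f"{system.n_atoms}"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        t: Optional[float] = None
        if "t=" in comment:
            try:
                t = float(comment.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                t = None
        body = lines[pos + 2 : pos + 2 + count]
        if len(body) < count:
            raise FormatError(f"{path}: frame {frame_no} is truncated")
        coords = np.empty((count, 3))
        for i, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: frame {frame_no}, atom {i + 1}: bad row {row!r}"
                )
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        times.append(t)
        pos += 2 + count
    if not frames:
        raise FormatError(f"{path}: empty XYZ file")
    if any(t is None for t in times):
        times_arr = np.arange(len(frames), dtype=float) * dt
    else:
        times_arr = np.asarray(times, dtype=float)
    return Trajectory(system, np.asarray(frames), times_arr)


def write_xyz_trajectory(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {t:.6f}\n")
            for atom, (x, y, z) in zip(traj.system.atoms, frame):
                fh.write(f"{atom.element:<3s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

REQUIRED_PARAMETER_COLUMNS = (
    "atom_name",
    "residue_name",
    "radius",
    "charge",
    "epsilon",
    "sigma",
)


class ParameterTable:
    """Per-atom parameters keyed by (residue_name, atom_name).

    Residue name ``*`` is a wildcard fallback matched after the exact key.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in REQUIRED_PARAMETER_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"parameter table missing columns: {missing}")
        self._map: Dict[Tuple[str, str], Tuple[float, float, float, float]] = {}
        for _, row in table.iterrows():
            key = (str(row["residue_name"]), str(row["atom_name"]))
            if key in self._map:
                raise FormatError(f"duplicate parameter key {key}")
            self._map[key] = (
                float(row["radius"]),
                float(row["charge"]),
                float(row["epsilon"]),
                float(row["sigma"]),
            )

    @classmethod
    def from_file(cls, path) -> "ParameterTable":
        table = pd.read_csv(path, sep=None, engine="python", comment="#")
        return cls(table)

    def lookup(self, residue_name: str, atom_name: str):
        """(radius, charge, epsilon, sigma), exact key first, then wildcard."""
        for key in ((residue_name, atom_name), ("*", atom_name)):
            if key in self._map:
                return self._map[key]
        raise UnparameterizedAtomError(
            f"unparameterized atom: residue {residue_name!r}, atom {atom_name!r}"
        )

    def apply(self, system: MolecularSystem) -> MolecularSystem:
        """Assign radius/charge/LJ parameters to every atom in place."""
        for atom in system.atoms:
            radius, charge, epsilon, sigma = self.lookup(atom.residue_name, atom.name)
            atom.radius = radius
            atom.charge = charge
            atom.lj_epsilon = epsilon
            atom.lj_sigma = sigma
        system.invalidate_cache()
        return system

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "atom_name": a,
                "residue_name": r,
                "radius": v[0],
                "charge": v[1],
                "epsilon": v[2],
                "sigma": v[3],
            }
            for (r, a), v in self._map.items()
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_PARAMETER_COLUMNS))

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def write_series(path, times: Sequence[float], values: Sequence[float],
                 header: Tuple[str, str] = ("time_ps", "value")) -> None:
    """Write a (time, value) series as two-column delimited text."""
    pd.DataFrame({header[0]: times, header[1]: values}).to_csv(path, index=False)
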