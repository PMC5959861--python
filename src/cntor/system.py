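"""Core containers: atoms, molecular systems, trajectories, and selections.

Conventions used throughout the package: coordinates in Å, times in ps,
energies in kcal mol⁻¹, charges in elementary charge units. Indices are
0-based internally; 1-based residue numbers appear only at format
boundaries (PDB ``resSeq``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import AnalysisError, SelectionError

GROUPS = ("receptor", "tube", "solvent", "ligand", "other")

#: Backbone atom names of a standard amino-acid residue.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

_LEADING_DIGITS = re.compile(r"^\d+")


def element_from_name(name: str) -> str:
    """Guess an element symbol from a PDB-style atom name.

    Digits are stripped from the front (``1HB`` → ``HB``) and the leading
    letter is taken; two-letter elements common in biomolecular files
    (Cl, Br, Na, Mg, Zn, Fe) are recognised when the name matches them
    case-insensitively.
    """
    stripped = _LEADING_DIGITS.sub("", name.strip())
    if not stripped:
        return "X"
    two = stripped[:2].capitalize()
    if two in {"Cl", "Br", "Na", "Mg", "Zn", "Fe", "Mn", "Cu"}:
        return two
    return stripped[0].upper()


@dataclass
class Atom:
    """One atom with geometry-independent attributes.

    Coordinates live in :class:`Trajectory` frames, not here, so a single
    system can be shared by many frames.
    """

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str = "A"
    radius: float = 0.0          # Å, used by SASA
    charge: float = 0.0          # e
    lj_epsilon: float = 0.0      # kcal mol⁻¹
    lj_sigma: float = 0.0        # Å
    group: str = "other"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not self.element:
            self.element = element_from_name(self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES


class MolecularSystem:
    """An ordered collection of atoms grouped into residues.

    Atoms must be ordered so that each residue occupies one contiguous
    range; the residue table is derived from that ordering.
    """

    def __init__(self, atoms: Sequence[Atom], box: Optional[np.ndarray] = None):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a MolecularSystem needs at least one atom")
        indices = [a.index for a in atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("atom indices must be unique")
        self.atoms: list[Atom] = atoms
        self.box = None if box is None else np.asarray(box, dtype=float)

        # derived residue table: (residue_index, residue_name, (start, stop))
        residues: list[tuple[int, str, tuple[int, int]]] = []
        seen: set[int] = set()
        start = 0
        for i in range(1, len(atoms) + 1):
            if i == len(atoms) or atoms[i].residue_index != atoms[start].residue_index:
                ridx = atoms[start].residue_index
                if ridx in seen:
                    raise ValueError(
                        f"residue {ridx} is not contiguous in the atom list"
                    )
                seen.add(ridx)
                residues.append((ridx, atoms[start].residue_name, (start, i)))
                start = i
        self.residues = residues
        self._cache: dict[str, np.ndarray] = {}

    # -- cached column views ------------------------------------------------
    def _column(self, key: str, getter) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = np.asarray([getter(a) for a in self.atoms])
        return self._cache[key]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def names(self) -> np.ndarray:
        return self._column("names", lambda a: a.name)

    @property
    def elements(self) -> np.ndarray:
        return self._column("elements", lambda a: a.element.upper())

    @property
    def residue_indices(self) -> np.ndarray:
        return self._column("residue_indices", lambda a: a.residue_index)

    @property
    def groups(self) -> np.ndarray:
        return self._column("groups", lambda a: a.group)

    @property
    def radii(self) -> np.ndarray:
        return self._column("radii", lambda a: a.radius).astype(float)

    @property
    def charges(self) -> np.ndarray:
        return self._column("charges", lambda a: a.charge).astype(float)

    @property
    def lj_epsilons(self) -> np.ndarray:
        return self._column("lj_epsilons", lambda a: a.lj_epsilon).astype(float)

    @property
    def lj_sigmas(self) -> np.ndarray:
        return self._column("lj_sigmas", lambda a: a.lj_sigma).astype(float)

    def invalidate_cache(self) -> None:
        """Drop cached column arrays after in-place atom edits."""
        self._cache.clear()

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        for ridx, _name, (start, stop) in self.residues:
            if ridx == residue_index:
                return np.arange(start, stop)
        raise KeyError(f"no residue with index {residue_index}")

    def residue_name(self, residue_index: int) -> str:
        for ridx, name, _rng in self.residues:
            if ridx == residue_index:
                return name
        raise KeyError(f"no residue with index {residue_index}")


@dataclass(frozen=True)
class Selection:
    """A labelled, sorted, duplicate-free set of atom indices."""

    label: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.atom_indices, dtype=np.int64))
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return int(self.atom_indices.size)

    def validate(self, system: MolecularSystem) -> "Selection":
        if len(self) and (
            self.atom_indices[0] < 0 or self.atom_indices[-1] >= system.n_atoms
        ):
            raise SelectionError(
                f"selection {self.label!r} has indices outside 0..{system.n_atoms - 1}"
            )
        return self


@dataclass
class Trajectory:
    """Ordered coordinate frames over one :class:`MolecularSystem`.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``times`` are strictly
    increasing and in ps.
    """

    system: MolecularSystem
    frames: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.system.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms but the system has "
                f"{self.system.n_atoms}"
            )
        if self.times is None:
            self.times = np.arange(self.frames.shape[0], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape[0] != self.frames.shape[0]:
            raise ValueError("len(times) must equal the number of frames")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def window(self, start: Optional[int] = None, stop: Optional[int] = None,
               stride: int = 1) -> "Trajectory":
        """Frame slice [start:stop:stride] as a new trajectory (shared system)."""
        if stride < 1:
            raise AnalysisError("stride must be >= 1")
        sl = slice(start, stop, stride)
        frames = self.frames[sl]
        if frames.shape[0] == 0:
            raise AnalysisError(
                f"window [{start}:{stop}:{stride}] selects no frames "
                f"(trajectory has {self.n_frames})"
            )
        return Trajectory(self.system, frames.copy(), self.times[sl].copy())


# ---------------------------------------------------------------------------
# Selection expression language
# ---------------------------------------------------------------------------
#
# Grammar (lowest to highest precedence):
#   expr    := orexpr
#   orexpr  := andexpr ('or' andexpr)*
#   andexpr := unary ('and' unary)*
#   unary   := 'not' unary | primary
#   primary := 'all' | 'heavy' | 'backbone'
#            | 'group' NAME | 'element' NAME+ | 'name' NAME+
#            | 'resid' RANGE (',' RANGE)*      e.g. resid 3:10,15
#            | '(' expr ')'
#
# NAME lists terminate at the reserved words and/or/not/(/).

_RESERVED = {"and", "or", "not", "(", ")"}


def _tokenize(expr: str) -> list[str]:
    out: list[str] = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], system: MolecularSystem):
        self.tokens = tokens
        self.pos = 0
        self.system = system

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        if self.peek() == "not":
            self.take()
            return ~self.unary()
        return self.primary()

    def _name_list(self) -> list[str]:
        names = []
        while self.peek() is not None and self.peek() not in _RESERVED:
            names.append(self.take())
        if not names:
            raise SelectionError("expected at least one value")
        return names

    def primary(self) -> np.ndarray:
        sysm = self.system
        tok = self.take()
        if tok == "(":
            mask = self.or_expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        if tok == "all":
            return np.ones(sysm.n_atoms, dtype=bool)
        if tok == "heavy":
            return sysm.elements != "H"
        if tok == "backbone":
            return np.isin(sysm.names, sorted(BACKBONE_NAMES))
        if tok == "group":
            value = self.take()
            if value not in GROUPS:
                raise SelectionError(f"unknown group {value!r}")
            return sysm.groups == value
        if tok == "element":
            values = [v.upper() for v in self._name_list()]
            return np.isin(sysm.elements, values)
        if tok == "name":
            return np.isin(sysm.names, self._name_list())
        if tok == "resid":
            spec = self.take()
            mask = np.zeros(sysm.n_atoms, dtype=bool)
            for part in spec.split(","):
                if ":" in part:
                    lo, hi = part.split(":")
                    mask |= (sysm.residue_indices >= int(lo)) & (
                        sysm.residue_indices <= int(hi)
                    )
                else:
                    mask |= sysm.residue_indices == int(part)
            return mask
        raise SelectionError(f"unknown selection key {tok!r}")


def select(system: MolecularSystem, expr: str, label: Optional[str] = None) -> Selection:
    """Evaluate a selection expression against a system.

    Supported keys: ``all``, ``heavy`` (element ≠ H), ``backbone``
    (names N, CA, C, O), ``group <g>``, ``element <e>...``, ``name <n>...``,
    ``resid <i>|<lo>:<hi>[,...]``, combined with ``and``/``or``/``not`` and
    parentheses. Residue indices are the package's 0-based indices.
    """
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, system).parse()
    return Selection(label or expr, np.nonzero(mask)[0]).validate(system)


def selection_from_indices(indices: Iterable[int], label: str,
                           system: Optional[MolecularSystem] = None) -> Selection:
    sel = Selection(label, np.asarray(list(indices), dtype=np.int64))
    if system is not None:
        sel.validate(system)
    return sel
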