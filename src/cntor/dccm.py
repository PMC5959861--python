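"""Dynamical cross-correlation of Cα positional fluctuations.

The correlation between residues i and j is the normalized covariance of
their displacement vectors over the trajectory,

    C(i, j) = c(i, j) / [c(i, i)^1/2 c(j, j)^1/2],
    c(i, j) = ⟨Δr_i · Δr_j⟩,   Δr_i = r_i − ⟨r_i⟩,

giving a symmetric matrix with unit diagonal and entries in [−1, 1].
Frames are first superposed onto the iteratively refined mean structure so
that rigid-body motion does not masquerade as correlated fluctuation; pass
``align=None`` for trajectories that are already aligned (e.g. synthetic
fluctuation draws with no rigid-body component).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .geometry import apply_transform, kabsch_superpose
from .system import Selection, Trajectory


@dataclass
class CorrelationMatrix:
    """Residue-residue correlation matrix with residue labels."""

    values: np.ndarray
    residue_labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.residue_labels) != n:
            raise ValueError("values must be square and match residue_labels")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.residue_labels, columns=self.residue_labels
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path)


def mean_structure_alignment(
    traj_coords: np.ndarray,
    fit_indices: Optional[np.ndarray] = None,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> Tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto the iterated mean structure.

    Fit → recompute mean → refit until the mean moves by less than ``tol``
    Å (RMS) or ``max_iter`` passes. Returns (aligned coords, mean).
    """
    coords = np.array(traj_coords, dtype=float, copy=True)
    n_atoms = coords.shape[1]
    fit_sel = Selection(
        "fit", np.arange(n_atoms) if fit_indices is None else fit_indices
    )
    mean = coords[0].copy()
    for _ in range(max_iter):
        for f in range(coords.shape[0]):
            rot, trans, _ = kabsch_superpose(coords[f], mean, fit_sel)
            coords[f] = apply_transform(coords[f], rot, trans)
        new_mean = coords.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return coords, mean


def fluctuation_matrix(
    traj: Trajectory,
    ca_selection: Selection,
    align: Optional[Selection] = None,
) -> np.ndarray:
    """Per-frame displacement vectors Δr_i for the selected Cα atoms.

    Returns an (n_frames, n_sel, 3) array. When ``align`` is given, frames
    are first superposed onto the iterated mean structure over the align
    selection (evaluated on the Cα subset); ``align=None`` skips the fit.
    """
    if traj.n_frames < 2:
        raise AnalysisError("fluctuations need at least 2 frames")
    ca = traj.frames[:, ca_selection.atom_indices, :]
    if align is not None:
        # map align indices into positions within the Cα subset
        pos = {int(a): k for k, a in enumerate(ca_selection.atom_indices)}
        fit_idx = np.asarray(
            [pos[int(a)] for a in align.atom_indices if int(a) in pos], dtype=int
        )
        ca, mean = mean_structure_alignment(
            ca, fit_idx if fit_idx.size else None
        )
    else:
        mean = ca.mean(axis=0)
    return ca - mean[None, :, :]


def dccm(
    traj: Trajectory,
    ca_selection: Selection,
    align: Optional[Selection] = None,
    residue_labels: Optional[Sequence] = None,
    drop_zero_variance: bool = False,
) -> CorrelationMatrix:
    """Dynamical cross-correlation matrix over the selected Cα atoms."""
    deltas = fluctuation_matrix(traj, ca_selection, align)
    # c(i, j) = ⟨Δr_i · Δr_j⟩, accumulated one Cartesian component at a time
    n_frames = deltas.shape[0]
    cov = sum(deltas[:, :, d].T @ deltas[:, :, d] for d in range(3)) / n_frames
    var = np.diag(cov).copy()
    labels = (
        list(residue_labels)
        if residue_labels is not None
        else [
            int(traj.system.residue_indices[a]) for a in ca_selection.atom_indices
        ]
    )
    zero = var <= 0
    if np.any(zero):
        if not drop_zero_variance:
            bad = [labels[i] for i in np.nonzero(zero)[0]]
            raise AnalysisError(
                f"zero-variance residues {bad}; pass drop_zero_variance=True to drop"
            )
        keep = ~zero
        cov = cov[np.ix_(keep, keep)]
        var = var[keep]
        labels = [l for l, k in zip(labels, keep) if k]
    denom = np.sqrt(np.outer(var, var))
    values = cov / denom
    # enforce exact structural invariants against floating-point drift
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    np.clip(values, -1.0, 1.0, out=values)
    return CorrelationMatrix(values, labels)
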