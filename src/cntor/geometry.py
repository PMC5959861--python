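"""Superposition, RMSD, solvent-accessible surface area, contact area, and
receptor-on-nanotube adsorption metrics.

The adsorption criterion follows the hydrophobic-interaction convention:
a receptor heavy atom is adsorbed when its minimum distance to any tube
atom is ≤ 6 Å (inclusive). The buried interface is quantified as

    contact area = ½ [(SAS_rec + SAS_cnt) − SAS_complex]

with the three solvent-accessible surface areas evaluated on the isolated
receptor, the isolated tube, and their union.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnalysisError, DegenerateFitError, ParameterError, SelectionError
from .system import MolecularSystem, Selection, Trajectory


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: Optional[Selection] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the least-squares
    deviation over the fit atoms; the rotation is proper (det = +1).
    The RMSD is over the fit atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = (
        np.arange(mobile.shape[0])
        if fit_selection is None
        else fit_selection.atom_indices
    )
    if idx.size < 3:
        raise DegenerateFitError(f"need >= 3 fit atoms, got {idx.size}")
    x = mobile[idx]
    y = reference[idx]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # collinear point sets leave the rotation about the line undetermined
    if np.linalg.matrix_rank(xc, tol=1e-8) < 2 or np.linalg.matrix_rank(yc, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = y.mean(axis=0) - rotation @ x.mean(axis=0)
    fitted = x @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) against a fixed reference structure."""

    times: np.ndarray
    rmsd: np.ndarray
    reference_label: str = "reference"
    selection_label: str = ""


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_selection: Selection,
    measure_selection: Optional[Selection] = None,
    reference_label: str = "reference",
) -> RmsdSeries:
    """RMSD of ``measure_selection`` per frame after superposing each frame
    onto the reference over ``fit_selection`` (the two may differ, e.g.
    whole-backbone fit with pocket-backbone measurement)."""
    measure = measure_selection if measure_selection is not None else fit_selection
    if len(fit_selection) == 0 or len(measure) == 0:
        raise SelectionError("fit and measure selections must be nonempty")
    reference = np.asarray(reference, dtype=float)
    out = np.empty(traj.n_frames)
    midx = measure.atom_indices
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.frames[f], reference, fit_selection)
        moved = apply_transform(traj.frames[f][midx], rot, trans)
        delta = moved - reference[midx]
        out[f] = np.sqrt(np.mean(np.sum(delta**2, axis=1)))
    return RmsdSeries(traj.times.copy(), out, reference_label,
                      measure.label)


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4  # Å, water probe
    n_points: int = 960


def sasa(
    frame: np.ndarray,
    selection: Selection,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> Tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area of an isolated selection.

    Only atoms inside the selection occlude each other, so disjoint
    selections can be measured both separately and as a union. Returns
    ``(total Å², per-atom Å²)``; the per-atom values sum to the total.
    """
    frame = np.asarray(frame, dtype=float)
    idx = selection.atom_indices
    if idx.size == 0:
        raise SelectionError("SASA of an empty selection")
    r = np.asarray(radii, dtype=float)[idx]
    if np.any(r <= 0):
        raise ParameterError("SASA requires positive radii for all selected atoms")
    centers = frame[idx]
    expanded = r + probe_radius
    points = sphere_points(n_points)
    tree = cKDTree(centers)
    per_atom = np.zeros(idx.size)
    for k in range(idx.size):
        neighbors = [
            j
            for j in tree.query_ball_point(centers[k], expanded[k] + expanded.max())
            if j != k
            and np.linalg.norm(centers[j] - centers[k]) < expanded[k] + expanded[j]
        ]
        surface = centers[k] + expanded[k] * points
        if neighbors:
            ncenters = centers[neighbors]
            nrad2 = expanded[neighbors] ** 2
            d2 = np.sum(
                (surface[:, None, :] - ncenters[None, :, :]) ** 2, axis=2
            )
            # boundary convention: a point exactly on a neighbor's surface is
            # buried only by lower-index neighbors, so coincident equal
            # spheres contribute one sphere's area in total
            lower = np.asarray(neighbors) < k
            tol = 1e-9 * nrad2
            buried = np.where(
                lower[None, :], d2 <= nrad2 + tol, d2 < nrad2 - tol
            )
            frac = float(np.mean(~np.any(buried, axis=1)))
        else:
            frac = 1.0
        per_atom[k] = frac * 4.0 * np.pi * expanded[k] ** 2
    return float(per_atom.sum()), per_atom


def contact_area(
    frame: np.ndarray,
    rec_selection: Selection,
    tube_selection: Selection,
    radii: np.ndarray,
    sasa_params: SasaParams = SasaParams(),
) -> float:
    """Buried interface area ½[(SAS_rec + SAS_cnt) − SAS_complex] in Å²."""
    a = rec_selection.atom_indices
    b = tube_selection.atom_indices
    if a.size == 0 or b.size == 0:
        raise SelectionError("contact_area needs nonempty selections")
    if np.intersect1d(a, b).size:
        raise SelectionError("receptor and tube selections overlap")
    union = Selection("complex", np.concatenate([a, b]))
    kw = dict(probe_radius=sasa_params.probe_radius, n_points=sasa_params.n_points)
    sas_rec, _ = sasa(frame, rec_selection, radii, **kw)
    sas_tube, _ = sasa(frame, tube_selection, radii, **kw)
    sas_complex, _ = sasa(frame, union, radii, **kw)
    return 0.5 * ((sas_rec + sas_tube) - sas_complex)


# ---------------------------------------------------------------------------
# Adsorption metrics
# ---------------------------------------------------------------------------

def adsorbed_atom_count(
    frame: np.ndarray,
    rec_heavy: Selection,
    tube: Selection,
    cutoff: float = 6.0,
) -> int:
    """Number of receptor heavy atoms within ``cutoff`` Å (inclusive) of any
    tube atom."""
    if cutoff <= 0:
        raise AnalysisError("cutoff must be positive")
    if len(tube) == 0:
        raise SelectionError("empty tube selection")
    if len(rec_heavy) == 0:
        return 0
    frame = np.asarray(frame, dtype=float)
    tree = cKDTree(frame[tube.atom_indices])
    dmin, _ = tree.query(frame[rec_heavy.atom_indices], k=1)
    return int(np.count_nonzero(dmin <= cutoff))


def adsorbed_residues(
    frame: np.ndarray,
    system: MolecularSystem,
    tube: Selection,
    cutoff: float = 6.0,
    rec_heavy: Optional[Selection] = None,
) -> set[int]:
    """Residues with at least one heavy atom within ``cutoff`` of the tube."""
    if cutoff <= 0:
        raise AnalysisError("cutoff must be positive")
    if len(tube) == 0:
        raise SelectionError("empty tube selection")
    if rec_heavy is None:
        mask = (system.groups == "receptor") & (system.elements != "H")
        idx = np.nonzero(mask)[0]
    else:
        idx = rec_heavy.atom_indices
    if idx.size == 0:
        return set()
    frame = np.asarray(frame, dtype=float)
    tree = cKDTree(frame[tube.atom_indices])
    dmin, _ = tree.query(frame[idx], k=1)
    close = idx[dmin <= cutoff]
    return set(int(r) for r in system.residue_indices[close])


@dataclass
class AdsorptionSeries:
    """Per-frame adsorption metrics: adsorbed-heavy-atom counts and, when
    SASA parameters are supplied, the receptor–tube contact area with its
    three SASA terms retained."""

    times: np.ndarray
    adsorbed_atom_count: np.ndarray
    contact_area: Optional[np.ndarray] = None
    sas_rec: Optional[np.ndarray] = None
    sas_tube: Optional[np.ndarray] = None
    sas_complex: Optional[np.ndarray] = None
    cutoff: float = 6.0
    stride: int = 1


def adsorption_series(
    traj: Trajectory,
    rec_heavy: Selection,
    tube: Selection,
    cutoff: float = 6.0,
    sasa_params: Optional[SasaParams] = None,
    stride: int = 1,
) -> AdsorptionSeries:
    """Adsorbed-atom counts (and optionally contact areas) on strided frames.

    Contact areas are computed only when ``sasa_params`` is given, since the
    three SASA evaluations per frame dominate the cost.
    """
    if stride < 1:
        raise AnalysisError("stride must be >= 1")
    frames = traj.frames[::stride]
    times = traj.times[::stride]
    counts = np.empty(frames.shape[0], dtype=int)
    do_area = sasa_params is not None
    areas = np.empty(frames.shape[0]) if do_area else None
    sas_r = np.empty(frames.shape[0]) if do_area else None
    sas_t = np.empty(frames.shape[0]) if do_area else None
    sas_c = np.empty(frames.shape[0]) if do_area else None
    radii = traj.system.radii
    kw = (
        dict(probe_radius=sasa_params.probe_radius, n_points=sasa_params.n_points)
        if do_area
        else {}
    )
    union = (
        Selection("complex", np.concatenate([rec_heavy.atom_indices, tube.atom_indices]))
        if do_area
        else None
    )
    for f in range(frames.shape[0]):
        counts[f] = adsorbed_atom_count(frames[f], rec_heavy, tube, cutoff)
        if do_area:
            sr, _ = sasa(frames[f], rec_heavy, radii, **kw)
            st, _ = sasa(frames[f], tube, radii, **kw)
            sc, _ = sasa(frames[f], union, radii, **kw)
            sas_r[f], sas_t[f], sas_c[f] = sr, st, sc
            areas[f] = 0.5 * ((sr + st) - sc)
    return AdsorptionSeries(
        times=times.copy(),
        adsorbed_atom_count=counts,
        contact_area=areas,
        sas_rec=sas_r,
        sas_tube=sas_t,
        sas_complex=sas_c,
        cutoff=cutoff,
        stride=stride,
    )
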