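"""Binding-pocket geometry and water-distribution analysis.

Pocket volume is a grid cavity estimate: grid points inside the padded
convex hull of the pocket-lining atoms that lie at least (atom radius +
probe) from every receptor atom, times the voxel volume. The method is
deterministic for a fixed spacing; it is one of several defensible cavity
definitions and is not guaranteed to reproduce volumes computed with
other tools.

Water distributions are occupancy grids of water-oxygen positions after
an all-receptor-atom rigid fit of each frame onto a reference, with the
axial (Z) profile as the membrane-normal summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import AnalysisError, SelectionError
from .geometry import RmsdSeries, apply_transform, kabsch_superpose, rmsd_series
from .system import MolecularSystem, Selection, Trajectory


@dataclass
class PocketDefinition:
    """A pocket given by its lining residues plus grid parameters."""

    residue_indices: Tuple[int, ...]
    spacing: float = 0.5      # Å grid spacing
    probe_radius: float = 1.4  # Å solvent probe
    padding: float = 1.0       # Å outward hull padding

    def __post_init__(self) -> None:
        self.residue_indices = tuple(sorted(set(int(r) for r in self.residue_indices)))
        if len(self.residue_indices) < 3:
            raise AnalysisError("a pocket needs at least 3 lining residues")
        if self.spacing <= 0:
            raise AnalysisError("grid spacing must be positive")

    def lining_atom_indices(self, system: MolecularSystem) -> np.ndarray:
        idx = [
            i
            for i, r in enumerate(system.residue_indices)
            if int(r) in set(self.residue_indices)
        ]
        if not idx:
            raise SelectionError("pocket residues select no atoms")
        return np.asarray(idx, dtype=int)


def pocket_rmsd(
    traj: Trajectory,
    pocket: PocketDefinition,
    reference: np.ndarray,
    receptor_backbone: Selection,
) -> RmsdSeries:
    """Backbone RMSD of the pocket residues after a whole-receptor-backbone
    fit of each frame onto the reference."""
    system = traj.system
    pocket_res = set(pocket.residue_indices)
    pocket_bb = [
        i
        for i in range(system.n_atoms)
        if int(system.residue_indices[i]) in pocket_res
        and system.atoms[i].is_backbone
    ]
    if not pocket_bb:
        raise SelectionError("pocket residues have no backbone atoms")
    measure = Selection("pocket-backbone", np.asarray(pocket_bb))
    return rmsd_series(traj, reference, receptor_backbone, measure,
                       reference_label="pocket-reference")


def pocket_volume(
    frame: np.ndarray,
    system: MolecularSystem,
    pocket: PocketDefinition,
    receptor_sel: Optional[Selection] = None,
) -> float:
    """Grid cavity volume (Å³) inside the padded convex hull of the
    pocket-lining atoms.

    A grid point counts when it is inside the hull (padded outward by
    ``pocket.padding``) and no receptor atom sphere inflated by the probe
    reaches it. Occluding atoms default to all receptor-group atoms.
    """
    frame = np.asarray(frame, dtype=float)
    lining = pocket.lining_atom_indices(system)
    try:
        hull = ConvexHull(frame[lining])
    except QhullError as exc:
        raise AnalysisError(f"degenerate pocket hull: {exc}") from exc

    if receptor_sel is None:
        occluder_idx = np.nonzero(system.groups == "receptor")[0]
    else:
        occluder_idx = receptor_sel.atom_indices
    occ_coords = frame[occluder_idx]
    occ_reach = system.radii[occluder_idx] + pocket.probe_radius

    pad = pocket.padding
    lo = frame[lining].min(axis=0) - pad
    hi = frame[lining].max(axis=0) + pad
    s = pocket.spacing
    axes = [np.arange(lo[d] + s / 2, hi[d], s) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    # inside the padded hull: every outward facet inequality ≤ padding
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    inside = np.all(points @ normals.T + offsets[None, :] <= pad, axis=1)
    points = points[inside]
    if points.size == 0:
        return 0.0

    if occ_coords.shape[0]:
        tree = cKDTree(occ_coords)
        max_reach = float(occ_reach.max())
        neighbor_lists = tree.query_ball_point(points, max_reach)
        free = np.ones(points.shape[0], dtype=bool)
        for k, neigh in enumerate(neighbor_lists):
            if not neigh:
                continue
            d = np.linalg.norm(occ_coords[neigh] - points[k], axis=1)
            if np.any(d < occ_reach[neigh]):
                free[k] = False
        count = int(free.sum())
    else:
        count = points.shape[0]
    return count * s**3


@dataclass
class DensityGrid:
    """Voxel occupancy counts of water oxygens over a frame window."""

    origin: np.ndarray          # Å, corner of voxel (0,0,0)
    spacing: float              # Å
    counts: np.ndarray          # (nx, ny, nz) int64
    n_frames: int
    out_of_box: int = 0         # waters falling outside the grid, summed

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.counts.shape)  # type: ignore[return-value]

    def total_in_box(self) -> int:
        return int(self.counts.sum())

    def write_opendx(self, path) -> None:
        """OpenDX scalar-field export (mean occupancy per frame)."""
        nx, ny, nz = self.counts.shape
        data = self.counts.astype(float) / max(self.n_frames, 1)
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(
                "origin {:.4f} {:.4f} {:.4f}\n".format(*self.origin)
            )
            fh.write(f"delta {self.spacing:.4f} 0 0\n")
            fh.write(f"delta 0 {self.spacing:.4f} 0\n")
            fh.write(f"delta 0 0 {self.spacing:.4f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {data.size} data follows\n"
            )
            flat = data.ravel()
            for i in range(0, flat.size, 3):
                fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "density" class field\n')


def _fit_transforms(traj: Trajectory, fit_sel: Selection, reference: np.ndarray):
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.frames[f], reference, fit_sel)
        yield f, rot, trans


def water_density_grid(
    traj: Trajectory,
    water_oxygen_sel: Selection,
    fit_sel: Selection,
    reference: np.ndarray,
    spacing: float = 0.5,
    box: float = 150.0,
    center: Optional[np.ndarray] = None,
    stride: int = 1,
) -> DensityGrid:
    """Occupancy grid of water oxygens after per-frame rigid fit.

    Each frame is superposed onto ``reference`` over ``fit_sel`` (all
    receptor atoms in the reference workflow), then the selected water
    oxygens are binned on a cubic grid of side ``box`` centered on
    ``center`` (default: centroid of the reference fit atoms). Waters
    outside the grid are tallied in ``out_of_box`` so that
    in-box + out-of-box equals n_waters × n_frames exactly.
    """
    if len(water_oxygen_sel) == 0:
        raise SelectionError("empty water selection")
    if spacing <= 0 or box <= 0:
        raise AnalysisError("spacing and box must be positive")
    reference = np.asarray(reference, dtype=float)
    if center is None:
        center = reference[fit_sel.atom_indices].mean(axis=0)
    center = np.asarray(center, dtype=float)
    n_bins = int(round(box / spacing))
    origin = center - box / 2.0
    counts = np.zeros((n_bins, n_bins, n_bins), dtype=np.int64)
    out_of_box = 0
    sub = traj.window(stride=stride)
    widx = water_oxygen_sel.atom_indices
    for f, rot, trans in _fit_transforms(sub, fit_sel, reference):
        waters = apply_transform(sub.frames[f][widx], rot, trans)
        ijk = np.floor((waters - origin) / spacing).astype(int)
        ok = np.all((ijk >= 0) & (ijk < n_bins), axis=1)
        out_of_box += int(np.count_nonzero(~ok))
        good = ijk[ok]
        np.add.at(counts, (good[:, 0], good[:, 1], good[:, 2]), 1)
    return DensityGrid(
        origin=origin, spacing=spacing, counts=counts,
        n_frames=sub.n_frames, out_of_box=out_of_box,
    )


def z_profile(
    traj: Trajectory,
    water_oxygen_sel: Selection,
    fit_sel: Selection,
    reference: np.ndarray,
    bin_width: float = 1.0,
    z_range: Optional[Tuple[float, float]] = None,
    stride: int = 1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean per-frame water count along Z after the rigid fit.

    Returns ``(bin_edges, mean_counts)``; the sum of mean counts equals
    the mean number of in-range waters per frame. The Z axis is taken as
    the membrane normal of the input frames (no axis auto-detection).
    """
    if bin_width <= 0:
        raise AnalysisError("bin_width must be positive")
    if len(water_oxygen_sel) == 0:
        raise SelectionError("empty water selection")
    reference = np.asarray(reference, dtype=float)
    sub = traj.window(stride=stride)
    widx = water_oxygen_sel.atom_indices
    zs = []
    for f, rot, trans in _fit_transforms(sub, fit_sel, reference):
        zs.append(apply_transform(sub.frames[f][widx], rot, trans)[:, 2])
    allz = np.concatenate(zs)
    if z_range is None:
        lo = np.floor(allz.min() / bin_width) * bin_width
        hi = np.ceil(allz.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = z_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, edges = np.histogram(allz, bins=edges)
    return edges, hist.astype(float) / sub.n_frames
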