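"""Seeded synthetic-data generators with recorded ground truth.

Each generator emulates one class of input the analysis pipeline needs —
correlated Cα fluctuations, a rigid bundle adsorbing onto a cylindrical
tube in programmed stages, water boxes with a prescribed axial density,
toy charged/LJ two-body complexes, and odor score tables — and returns
the dataset together with a truth block sufficient to compute every
downstream expected value without re-deriving it. The same spec and seed
always reproduce bit-identical output (one explicit
``numpy.random.default_rng`` stream per call, no global state).

Realism is deliberately limited: bundles are coarse Cα + pseudo-side-chain
models, waters are oxygen-only, and score models are simple parametric
responses. Countability and exact ground truth are the goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io import ParameterTable
from .system import Atom, MolecularSystem, Trajectory


@dataclass
class GeneratorSpec:
    """A reproducible generator invocation: kind, parameters, seed."""

    kind: str
    parameters: Dict[str, object] = field(default_factory=dict)
    seed: int = 0

    KINDS = (
        "correlated_traj", "adsorption_traj", "water_box", "toy_complex",
        "odor_table",
    )

    def generate(self):
        if self.kind == "correlated_traj":
            return gen_correlated_trajectory(seed=self.seed, **self.parameters)
        if self.kind == "adsorption_traj":
            return gen_adsorption_trajectory(seed=self.seed, **self.parameters)
        if self.kind == "water_box":
            return gen_water_box(seed=self.seed, **self.parameters)
        if self.kind == "toy_complex":
            return gen_toy_complex(seed=self.seed, **self.parameters)
        if self.kind == "odor_table":
            return gen_odor_table(seed=self.seed, **self.parameters)
        raise AnalysisError(f"unknown generator kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Correlated Cα fluctuations
# ---------------------------------------------------------------------------

def block_correlation(
    n_residues: int,
    blocks: Sequence[Tuple[int, int]],
    rho: float = 0.6,
    cross_rho: float = 0.0,
) -> np.ndarray:
    """Block correlation model: ``rho`` within each block, ``cross_rho``
    between blocks, 1 on the diagonal."""
    c = np.full((n_residues, n_residues), cross_rho, dtype=float)
    for lo, hi in blocks:
        c[lo:hi, lo:hi] = rho
    np.fill_diagonal(c, 1.0)
    return c


def gen_correlated_trajectory(
    n_residues: int = 10,
    correlation: Optional[np.ndarray] = None,
    amplitude: float = 0.3,
    n_frames: int = 5000,
    seed: int = 0,
    spacing: float = 3.8,
) -> Tuple[Trajectory, Dict[str, object]]:
    """Cα-like chain with Gaussian fluctuations of known correlation.

    Each Cartesian component of the per-residue displacements is drawn
    i.i.d. over frames from N(0, amplitude²·C) where C is the requested
    residue correlation matrix (two equal blocks with in-block correlation
    0.6 by default). Frames carry no rigid-body motion, so the sample
    correlation estimator can be applied without superposition. The truth
    block contains C.
    """
    if correlation is None:
        half = n_residues // 2
        correlation = block_correlation(
            n_residues, [(0, half), (half, n_residues)], rho=0.6
        )
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (n_residues, n_residues):
        raise AnalysisError("correlation matrix shape mismatch")
    eigvals = np.linalg.eigvalsh(correlation)
    if eigvals.min() < -1e-10:
        raise AnalysisError("correlation model is not positive semidefinite")
    cov = amplitude**2 * correlation
    # PSD-safe factor via eigendecomposition (cholesky fails on semidefinite)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    factor = v @ np.diag(np.sqrt(w))

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, 3, n_residues))
    deltas = z @ factor.T  # (n_frames, 3, n_residues)
    base = np.zeros((n_residues, 3))
    base[:, 0] = np.arange(n_residues) * spacing
    frames = base[None, :, :] + np.transpose(deltas, (0, 2, 1))

    atoms = [
        Atom(index=i, name="CA", element="C", residue_index=i,
             residue_name="ALA", group="receptor", radius=1.7)
        for i in range(n_residues)
    ]
    traj = Trajectory(MolecularSystem(atoms), frames)
    truth = {
        "kind": "correlated_traj",
        "correlation": correlation.tolist(),
        "amplitude": amplitude,
        "n_frames": n_frames,
        "seed": seed,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Staged adsorption of a bundle onto a cylindrical tube
# ---------------------------------------------------------------------------

def _cylinder_lattice(radius: float, length: float, axial_step: float = 2.0,
                      n_circumference: int = 24) -> np.ndarray:
    xs = np.arange(-length / 2, length / 2 + 1e-9, axial_step)
    angles = np.linspace(0, 2 * np.pi, n_circumference, endpoint=False)
    pts = []
    for x in xs:
        for a in angles:
            pts.append((x, radius * np.cos(a), radius * np.sin(a)))
    return np.asarray(pts)


def _helix_bundle(n_helices: int = 4, residues_per_helix: int = 12,
                  helix_radius: float = 2.3, rise: float = 1.5,
                  twist_deg: float = 100.0, bundle_spacing: float = 8.0
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Coarse Cα + pseudo-CB bundle; returns (coords, residue index per atom)."""
    offsets = [
        (0.0, 0.0), (bundle_spacing, 0.0), (0.0, bundle_spacing),
        (bundle_spacing, bundle_spacing),
    ][:n_helices]
    coords = []
    res_of_atom = []
    res = 0
    for oy, oz in offsets:
        for k in range(residues_per_helix):
            angle = np.deg2rad(twist_deg) * k
            ca = np.array(
                [k * rise, oy + helix_radius * np.cos(angle),
                 oz + helix_radius * np.sin(angle)]
            )
            radial = np.array([0.0, np.cos(angle), np.sin(angle)])
            cb = ca + 1.5 * radial
            coords.extend([ca, cb])
            res_of_atom.extend([res, res])
            res += 1
    return np.asarray(coords), np.asarray(res_of_atom)


def gen_adsorption_trajectory(
    approach_schedule: Sequence[Tuple[int, int, float]] = (
        (0, 10, 20.0), (10, 20, 4.0), (20, 30, 1.0),
    ),
    tube_radius: float = 8.0,
    tube_length: float = 60.0,
    cutoff: float = 6.0,
    jitter: float = 0.0,
    seed: int = 0,
    bundle_kwargs: Optional[Dict[str, object]] = None,
) -> Tuple[Trajectory, Dict[str, object]]:
    """Rigid helix bundle held at scheduled separations above a tube.

    ``approach_schedule`` is a list of (start frame, stop frame, separation
    Å) with disjoint, contiguous-from-zero ranges; separation is the gap
    between the lowest bundle atom and the tube surface. Seeded Gaussian
    jitter (sd = ``jitter`` Å) is added to the bundle atoms; the truth
    block holds exact per-frame adsorbed-heavy-atom counts computed by an
    all-pairs brute-force scan of the emitted coordinates.
    """
    schedule = sorted(approach_schedule)
    covered: List[Tuple[int, int]] = []
    for start, stop, sep in schedule:
        if stop <= start:
            raise AnalysisError(f"empty schedule range ({start}, {stop})")
        if sep < 0:
            raise AnalysisError("separations must be >= 0")
        for s0, s1 in covered:
            if start < s1 and stop > s0:
                raise AnalysisError("overlapping schedule ranges")
        covered.append((start, stop))
    n_frames = max(stop for _, stop, _ in schedule)

    tube_xyz = _cylinder_lattice(tube_radius, tube_length)
    bundle_xyz, res_of = _helix_bundle(**(bundle_kwargs or {}))
    # center bundle laterally over the tube axis
    bundle_xyz = bundle_xyz - bundle_xyz.mean(axis=0)
    n_bundle = bundle_xyz.shape[0]
    n_tube = tube_xyz.shape[0]

    atoms: List[Atom] = []
    for i in range(n_bundle):
        name = "CA" if i % 2 == 0 else "CB"
        atoms.append(
            Atom(index=i, name=name, element="C", residue_index=int(res_of[i]),
                 residue_name="ALA", group="receptor", radius=1.7)
        )
    tube_res = int(res_of.max()) + 1
    for j in range(n_tube):
        atoms.append(
            Atom(index=n_bundle + j, name="C", element="C",
                 residue_index=tube_res, residue_name="CNT", group="tube",
                 radius=1.7, lj_epsilon=0.086, lj_sigma=3.4)
        )
    system = MolecularSystem(atoms)

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, n_bundle + n_tube, 3))
    true_counts = np.empty(n_frames, dtype=int)
    separations = np.empty(n_frames)
    for start, stop, sep in schedule:
        for f in range(start, stop):
            placed = bundle_xyz.copy()
            lift = tube_radius + sep - placed[:, 2].min()
            placed[:, 2] += lift
            if jitter > 0:
                placed = placed + rng.normal(scale=jitter, size=placed.shape)
            frames[f, :n_bundle] = placed
            frames[f, n_bundle:] = tube_xyz
            separations[f] = sep
            # brute-force truth on the emitted coordinates
            count = 0
            for a in range(n_bundle):
                dmin = np.min(np.linalg.norm(tube_xyz - placed[a], axis=1))
                if dmin <= cutoff:
                    count += 1
            true_counts[f] = count
    traj = Trajectory(system, frames)
    truth = {
        "kind": "adsorption_traj",
        "true_counts": true_counts.tolist(),
        "separations": separations.tolist(),
        "cutoff": cutoff,
        "jitter": jitter,
        "seed": seed,
        "n_bundle_atoms": n_bundle,
        "n_tube_atoms": n_tube,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Water boxes with a prescribed axial density profile
# ---------------------------------------------------------------------------

def gen_water_box(
    n_waters: int = 200,
    axial_profile: Sequence[Tuple[float, float, float]] = ((0.0, 30.0, 1.0),),
    box: float = 30.0,
    n_frames: int = 10,
    seed: int = 0,
) -> Tuple[Trajectory, Dict[str, object]]:
    """Water oxygens drawn frame-by-frame from a piecewise axial density.

    ``axial_profile`` is a list of (z_lo, z_hi, weight) slabs; weights are
    normalized to a probability profile (negative weights are an error).
    x and y are uniform over [0, box). Four fixed anchor atoms (a pseudo
    backbone residue) are included so rigid-fit workflows have a fit
    selection. The truth block records the normalized slab probabilities.
    """
    profile = [(float(a), float(b), float(w)) for a, b, w in axial_profile]
    if any(w < 0 for _, _, w in profile):
        raise AnalysisError("negative density in axial profile")
    total = sum(w for _, _, w in profile)
    if total <= 0:
        raise AnalysisError("axial profile must have positive total weight")
    probs = np.array([w / total for _, _, w in profile])

    atoms: List[Atom] = []
    anchor = np.array(
        [[1.0, 1.0, 1.0], [3.0, 1.0, 1.0], [1.0, 3.0, 1.0], [1.0, 1.0, 3.0]]
    )
    for i, name in enumerate(("N", "CA", "C", "O")):
        atoms.append(
            Atom(index=i, name=name, element=name[0], residue_index=0,
                 residue_name="ALA", group="receptor", radius=1.6)
        )
    for w in range(n_waters):
        atoms.append(
            Atom(index=4 + w, name="O", element="O", residue_index=1 + w,
                 residue_name="WAT", group="solvent", radius=1.52)
        )
    system = MolecularSystem(atoms)

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, 4 + n_waters, 3))
    for f in range(n_frames):
        frames[f, :4] = anchor
        slabs = rng.choice(len(profile), size=n_waters, p=probs)
        z = np.array(
            [rng.uniform(profile[s][0], profile[s][1]) for s in slabs]
        )
        xy = rng.uniform(0.0, box, size=(n_waters, 2))
        frames[f, 4:, 0] = xy[:, 0]
        frames[f, 4:, 1] = xy[:, 1]
        frames[f, 4:, 2] = z
    traj = Trajectory(system, frames)
    truth = {
        "kind": "water_box",
        "slabs": [(a, b) for a, b, _ in profile],
        "slab_probabilities": probs.tolist(),
        "n_waters": n_waters,
        "n_frames": n_frames,
        "box": box,
        "seed": seed,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Toy charged/LJ complexes with brute-force reference energies
# ---------------------------------------------------------------------------

def gen_toy_complex(
    n_receptor_atoms: int = 8,
    n_ligand_atoms: int = 3,
    charge_range: Tuple[float, float] = (-0.5, 0.5),
    epsilon_range: Tuple[float, float] = (0.05, 0.2),
    sigma_range: Tuple[float, float] = (2.5, 3.5),
    radius_range: Tuple[float, float] = (1.2, 1.9),
    separation: float = 6.0,
    seed: int = 0,
) -> Tuple[Trajectory, ParameterTable, Dict[str, object]]:
    """A fully parameterized two-group toy system with reference energies.

    Receptor atoms are scattered in a 3 Å sphere at the origin (each its
    own residue, for decomposition tests); ligand atoms sit in a 1.5 Å
    sphere at distance ``separation`` on x. Reference gas-phase energies
    in the truth block are computed by explicit double loops over atom
    pairs, independent of the vectorized analysis path.
    """
    rng = np.random.default_rng(seed)

    def _ball(n: int, radius: float, center: np.ndarray) -> np.ndarray:
        pts = []
        while len(pts) < n:
            p = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p) <= radius and all(
                np.linalg.norm(p - q) > 1.2 for q in pts
            ):
                pts.append(p)
        return np.asarray(pts) + center

    rec_xyz = _ball(n_receptor_atoms, 3.0, np.zeros(3))
    lig_xyz = _ball(n_ligand_atoms, 1.5, np.array([separation, 0.0, 0.0]))
    coords = np.vstack([rec_xyz, lig_xyz])
    n_total = coords.shape[0]

    charges = rng.uniform(*charge_range, size=n_total)
    epsilons = rng.uniform(*epsilon_range, size=n_total)
    sigmas = rng.uniform(*sigma_range, size=n_total)
    radii = rng.uniform(*radius_range, size=n_total)

    atoms: List[Atom] = []
    rows = []
    for i in range(n_total):
        is_rec = i < n_receptor_atoms
        name = f"C{i + 1}"
        res_name = "TOY" if is_rec else "LIG"
        res_index = i if is_rec else n_receptor_atoms
        atoms.append(
            Atom(index=i, name=name, element="C", residue_index=res_index,
                 residue_name=res_name, group="receptor" if is_rec else "ligand",
                 radius=float(radii[i]), charge=float(charges[i]),
                 lj_epsilon=float(epsilons[i]), lj_sigma=float(sigmas[i]))
        )
        rows.append(
            {"atom_name": name, "residue_name": res_name,
             "radius": radii[i], "charge": charges[i],
             "epsilon": epsilons[i], "sigma": sigmas[i]}
        )
    system = MolecularSystem(atoms)
    traj = Trajectory(system, coords[None, :, :])
    table = ParameterTable(pd.DataFrame(rows))

    # brute-force references, plain double loops
    k = 332.0637
    ref_ele = 0.0
    ref_vdw = 0.0
    for a in range(n_receptor_atoms):
        for b in range(n_receptor_atoms, n_total):
            r = float(np.linalg.norm(coords[a] - coords[b]))
            ref_ele += k * charges[a] * charges[b] / r
            eps = float(np.sqrt(epsilons[a] * epsilons[b]))
            sig = float(0.5 * (sigmas[a] + sigmas[b]))
            sr6 = (sig / r) ** 6
            ref_vdw += 4.0 * eps * (sr6**2 - sr6)
    truth = {
        "kind": "toy_complex",
        "reference_ele": ref_ele,
        "reference_vdw": ref_vdw,
        "n_receptor_atoms": n_receptor_atoms,
        "n_ligand_atoms": n_ligand_atoms,
        "separation": separation,
        "seed": seed,
    }
    return traj, table, truth


# ---------------------------------------------------------------------------
# Odor score tables
# ---------------------------------------------------------------------------

ODOR_CLASSES = (
    "alcohol", "ketone", "acid", "ester", "aldehyde", "ether", "aromatic",
    "other",
)


def gen_odor_table(
    n: int = 132,
    mw_range: Tuple[float, float] = (42.0, 236.0),
    volume_range: Tuple[float, float] = (45.0, 267.0),
    logp_range: Tuple[float, float] = (0.7, 9.6),
    turnover_volume: Optional[float] = 170.0,
    volume_slope: float = 0.02,     # kcal mol⁻¹ per Å³ strength gain
    decline_slope: float = 0.02,    # strength loss per Å³ past the turnover
    logp_slope: float = 0.3,        # kcal mol⁻¹ per logP unit
    baseline: float = 1.0,          # kcal mol⁻¹ offset
    noise_sd: float = 0.5,          # kcal mol⁻¹ Gaussian score noise
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Synthetic odor set with a size/hydrophobicity score response.

    Volumes and logP are uniform over their ranges; molecular weight
    tracks volume linearly with small scatter (clipped to its range).
    Binding strength rises with volume up to ``turnover_volume`` Å³ and
    declines past it (set ``turnover_volume=None`` for a monotone
    response), and rises with logP; the reported docking score is the
    negated strength plus Gaussian noise, so stronger binders score more
    negative. The truth block records every model parameter.
    """
    for lo, hi in (mw_range, volume_range, logp_range):
        if hi <= lo:
            raise AnalysisError("descriptor ranges must be ordered (lo < hi)")
    rng = np.random.default_rng(seed)
    volume = rng.uniform(*volume_range, size=n)
    frac = (volume - volume_range[0]) / (volume_range[1] - volume_range[0])
    mw = mw_range[0] + frac * (mw_range[1] - mw_range[0]) + rng.normal(
        scale=8.0, size=n
    )
    mw = np.clip(mw, *mw_range)
    logp = rng.uniform(*logp_range, size=n)
    if turnover_volume is None:
        strength_v = volume_slope * volume
    else:
        strength_v = np.where(
            volume <= turnover_volume,
            volume_slope * volume,
            volume_slope * turnover_volume - decline_slope * (volume - turnover_volume),
        )
    strength = baseline + strength_v + logp_slope * logp
    noise = rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    score = -(strength) + noise
    classes = rng.choice(ODOR_CLASSES, size=n)
    table = pd.DataFrame(
        {
            "id": [f"odor{i + 1:03d}" for i in range(n)],
            "score": score,
            "mol_weight": mw,
            "volume": volume,
            "logP": logp,
            "chem_class": classes,
        }
    )
    truth = {
        "kind": "odor_table",
        "turnover_volume": turnover_volume,
        "volume_slope": volume_slope,
        "decline_slope": decline_slope,
        "logp_slope": logp_slope,
        "baseline": baseline,
        "noise_sd": noise_sd,
        "n": n,
        "seed": seed,
    }
    return table, truth
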