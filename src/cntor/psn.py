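"""Protein structure network construction and allosteric pathway search.

Residues are network nodes; an edge between residues i and j exists in a
frame when their normalized side-chain contact strength

    I_ij = n_ij / sqrt(N_i N_j) × 100

is at least ``Imin``, where n_ij counts distinct side-chain heavy-atom
pairs (one atom from each residue) within the distance cutoff (4.5 Å by
default) and N_i, N_j are per-residue-type normalization constants from a
large protein dataset (shipped in ``data/residue_normalization.csv``).
Sequence neighbors (|i − j| ≤ 1) are excluded as covalently connected.

Communication pathways between an adsorbed-residue set and pocket
residues are minimal-hop paths through the network restricted to edges
whose endpoints move in a correlated way (|C(i, j)| ≥ corr_min); a path's
frequency is the percentage of frames in which every edge of the path is
present in that frame's network.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dccm import CorrelationMatrix
from .errors import AnalysisError, ParameterError
from .system import BACKBONE_NAMES, MolecularSystem, Trajectory

DEFAULT_DISTANCE_CUTOFF = 4.5  # Å
DEFAULT_IMIN = 3.0             # dimensionless, percent-like scale
DEFAULT_CORR_MIN = 0.3
DEFAULT_NORMALIZATION = 100.0  # fallback for residue types not in the table


def load_normalization_table() -> Dict[str, float]:
    """Published per-residue-type normalization constants N_i."""
    with resources.files("cntor.data").joinpath("residue_normalization.csv").open() as fh:
        table = pd.read_csv(fh)
    return dict(zip(table["residue_name"], table["normalization"].astype(float)))


def side_chain_heavy_indices(system: MolecularSystem) -> Dict[int, np.ndarray]:
    """Side-chain heavy atoms per residue.

    Backbone atoms N, CA, C, O are excluded; glycine keeps CA as a one-atom
    pseudo-side-chain so it does not vanish from the network.
    """
    out: Dict[int, np.ndarray] = {}
    for ridx, rname, (start, stop) in system.residues:
        idx = []
        ca = None
        for i in range(start, stop):
            atom = system.atoms[i]
            if atom.is_hydrogen:
                continue
            if atom.name == "CA":
                ca = i
            if atom.name in BACKBONE_NAMES or atom.name == "CA":
                continue
            idx.append(i)
        if not idx and ca is not None:
            idx = [ca]
        out[ridx] = np.asarray(idx, dtype=int)
    return out


def interaction_strength_frame(
    frame: np.ndarray,
    system: MolecularSystem,
    residue_indices: Optional[Sequence[int]] = None,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    normalization: Optional[Dict[str, float]] = None,
    default_normalization: Optional[float] = DEFAULT_NORMALIZATION,
    side_chains: Optional[Dict[int, np.ndarray]] = None,
) -> pd.DataFrame:
    """I_ij matrix for one frame, as a DataFrame indexed by residue index.

    ``side_chains`` may be passed to reuse the per-residue atom lists
    across frames. Sequence neighbors (|i − j| ≤ 1) are zero by construction.
    """
    frame = np.asarray(frame, dtype=float)
    if normalization is None:
        normalization = load_normalization_table()
    if side_chains is None:
        side_chains = side_chain_heavy_indices(system)
    if residue_indices is None:
        residue_indices = [r for r, _, _ in system.residues]
    residue_indices = list(residue_indices)

    norms = {}
    for r in residue_indices:
        rname = system.residue_name(r)
        if rname in normalization:
            norms[r] = normalization[rname]
        elif default_normalization is not None:
            norms[r] = default_normalization
        else:
            raise ParameterError(
                f"residue type {rname!r} missing from normalization table "
                "and no default given"
            )
        if norms[r] <= 0:
            raise ParameterError(f"normalization for residue {r} must be > 0")

    n = len(residue_indices)
    values = np.zeros((n, n))
    # flat atom list over all side chains, then one KD-tree pair query
    atom_idx = []
    atom_res = []
    for k, r in enumerate(residue_indices):
        for a in side_chains.get(r, ()):  # residues with no heavy side chain
            atom_idx.append(a)
            atom_res.append(k)
    if atom_idx:
        atom_idx = np.asarray(atom_idx)
        atom_res = np.asarray(atom_res)
        tree = cKDTree(frame[atom_idx])
        pairs = tree.query_pairs(distance_cutoff, output_type="ndarray")
        for p, q in pairs:
            ki, kj = atom_res[p], atom_res[q]
            if ki == kj:
                continue
            ri, rj = residue_indices[ki], residue_indices[kj]
            if abs(ri - rj) <= 1:
                continue
            values[ki, kj] += 1
            values[kj, ki] += 1
    for a, ra in enumerate(residue_indices):
        for b in range(a + 1, n):
            rb = residue_indices[b]
            scale = 100.0 / np.sqrt(norms[ra] * norms[rb])
            values[a, b] *= scale
            values[b, a] = values[a, b]
    return pd.DataFrame(values, index=residue_indices, columns=residue_indices)


def interaction_strength_value(
    n_ij: float, n_i: float, n_j: float
) -> float:
    """I_ij = n_ij / sqrt(N_i N_j) × 100 (scalar form)."""
    if n_i <= 0 or n_j <= 0:
        raise ParameterError("normalization values must be positive")
    return float(n_ij) / np.sqrt(float(n_i) * float(n_j)) * 100.0


@dataclass
class StructureNetwork:
    """Occupancy-filtered residue interaction network over a frame window."""

    nodes: List[int]
    edges: List[Tuple[int, int, float, float]]  # (i, j, mean_strength, occupancy)
    imin: float
    distance_cutoff: float
    occupancy_min: float
    n_frames: int

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, j, strength, occ in self.edges:
            g.add_edge(i, j, mean_strength=strength, occupancy=occ)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["i", "j", "mean_strength", "occupancy"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def per_frame_strengths(
    traj: Trajectory,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    imin: float = DEFAULT_IMIN,
    residue_indices: Optional[Sequence[int]] = None,
    normalization: Optional[Dict[str, float]] = None,
    default_normalization: Optional[float] = DEFAULT_NORMALIZATION,
) -> Tuple[np.ndarray, List[int]]:
    """Stacked I_ij matrices, one per frame: (n_frames, n_res, n_res)."""
    if traj.n_frames == 0:
        raise AnalysisError("empty frame window")
    side_chains = side_chain_heavy_indices(traj.system)
    if normalization is None:
        normalization = load_normalization_table()
    mats = []
    labels: List[int] = []
    for f in range(traj.n_frames):
        df = interaction_strength_frame(
            traj.frames[f],
            traj.system,
            residue_indices=residue_indices,
            distance_cutoff=distance_cutoff,
            normalization=normalization,
            default_normalization=default_normalization,
            side_chains=side_chains,
        )
        labels = list(df.index)
        mats.append(df.to_numpy())
    return np.asarray(mats), labels


def build_network(
    traj_window: Trajectory,
    imin: float = DEFAULT_IMIN,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    occupancy_min: float = 0.5,
    residue_indices: Optional[Sequence[int]] = None,
    normalization: Optional[Dict[str, float]] = None,
    default_normalization: Optional[float] = DEFAULT_NORMALIZATION,
    strengths: Optional[Tuple[np.ndarray, List[int]]] = None,
) -> StructureNetwork:
    """Occupancy network over a frame window.

    A pair is an edge when the fraction of frames with I_ij ≥ Imin reaches
    ``occupancy_min``; its mean strength is averaged over the frames where
    it is present. Precomputed ``strengths`` (from
    :func:`per_frame_strengths`) can be reused across parameter settings.
    """
    if strengths is None:
        strengths = per_frame_strengths(
            traj_window,
            distance_cutoff=distance_cutoff,
            residue_indices=residue_indices,
            normalization=normalization,
            default_normalization=default_normalization,
        )
    mats, labels = strengths
    n_frames = mats.shape[0]
    present = mats >= imin
    occupancy = present.mean(axis=0)
    edges: List[Tuple[int, int, float, float]] = []
    n = len(labels)
    for a in range(n):
        for b in range(a + 1, n):
            occ = occupancy[a, b]
            if occ >= occupancy_min and occ > 0:
                strength = mats[present[:, a, b], a, b].mean()
                edges.append((labels[a], labels[b], float(strength), float(occ)))
    return StructureNetwork(
        nodes=list(labels),
        edges=edges,
        imin=imin,
        distance_cutoff=distance_cutoff,
        occupancy_min=occupancy_min,
        n_frames=n_frames,
    )


@dataclass
class Pathway:
    """A minimal-hop chain of network edges between a source and a sink."""

    nodes: List[int]
    source: int
    sink: int
    frequency: Optional[float] = None  # % of frames containing every edge

    @property
    def length(self) -> int:
        return max(len(self.nodes) - 1, 0)

    @property
    def edges(self) -> List[Tuple[int, int]]:
        return list(zip(self.nodes[:-1], self.nodes[1:]))


def shortest_paths(
    network: StructureNetwork,
    correlation: CorrelationMatrix,
    sources: Iterable[int],
    sinks: Iterable[int],
    corr_min: float = DEFAULT_CORR_MIN,
) -> Tuple[List[Pathway], List[Tuple[int, int]]]:
    """Minimal-hop pathways per source–sink pair on the correlation-filtered
    network.

    An edge qualifies when |C| between its endpoints is ≥ ``corr_min``.
    Among equal-hop alternatives the path with larger total mean edge
    strength wins; remaining ties break lexicographically on the node
    sequence. Returns ``(pathways, unreachable pairs)``. A source equal to
    a sink yields a zero-length path.
    """
    corr_index = {lab: k for k, lab in enumerate(correlation.residue_labels)}
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for i, j, strength, occ in network.edges:
        if i in corr_index and j in corr_index:
            c = correlation.values[corr_index[i], corr_index[j]]
            if abs(c) >= corr_min:
                g.add_edge(i, j, mean_strength=strength)
    paths: List[Pathway] = []
    missing: List[Tuple[int, int]] = []
    for s in sorted(set(sources)):
        if s not in g:
            raise AnalysisError(f"source residue {s} is not a network node")
        lengths = nx.single_source_shortest_path_length(g, s)
        for t in sorted(set(sinks)):
            if t not in g:
                raise AnalysisError(f"sink residue {t} is not a network node")
            if s == t:
                paths.append(Pathway(nodes=[s], source=s, sink=t))
                continue
            if t not in lengths:
                missing.append((s, t))
                continue
            candidates = list(nx.all_shortest_paths(g, s, t))
            def rank(p: List[int]) -> Tuple[float, Tuple[int, ...]]:
                total = sum(
                    g.edges[a, b]["mean_strength"] for a, b in zip(p[:-1], p[1:])
                )
                return (-total, tuple(p))
            best = min(candidates, key=rank)
            paths.append(Pathway(nodes=list(best), source=s, sink=t))
    return paths, missing


def path_frequency(
    path: Pathway,
    strengths: Tuple[np.ndarray, List[int]],
    imin: float = DEFAULT_IMIN,
) -> float:
    """% of frames in which every consecutive pair of the path is an edge
    of that frame's network (I_ij ≥ Imin)."""
    if path.length < 1:
        raise AnalysisError("path frequency needs at least one edge")
    mats, labels = strengths
    index = {lab: k for k, lab in enumerate(labels)}
    ok = np.ones(mats.shape[0], dtype=bool)
    for a, b in path.edges:
        ok &= mats[:, index[a], index[b]] >= imin
    return float(ok.mean() * 100.0)


def annotate_frequencies(
    paths: Sequence[Pathway],
    strengths: Tuple[np.ndarray, List[int]],
    imin: float = DEFAULT_IMIN,
) -> List[Pathway]:
    """Fill in per-frame frequencies for every path with ≥1 edge."""
    out = []
    for p in paths:
        if p.length >= 1:
            p.frequency = path_frequency(p, strengths, imin)
        out.append(p)
    return out


def node_frequency_summary(
    pathways: Sequence[Pathway], k: int = 3
) -> Tuple[List[Tuple[int, float]], List[Tuple[int, float]]]:
    """Top-k starting and ending nodes across a pathway list.

    Occurrences are weighted by path frequency when available (weight 1
    otherwise); ties order by ascending residue index.
    """
    if not pathways:
        raise AnalysisError("empty pathway list")
    starts: Dict[int, float] = {}
    ends: Dict[int, float] = {}
    for p in pathways:
        w = 1.0 if p.frequency is None else p.frequency
        starts[p.source] = starts.get(p.source, 0.0) + w
        ends[p.sink] = ends.get(p.sink, 0.0) + w
    order = lambda d: sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return order(starts), order(ends)


def pathways_to_frame(paths: Sequence[Pathway]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": [p.source for p in paths],
            "sink": [p.sink for p in paths],
            "nodes": ["-".join(str(n) for n in p.nodes) for p in paths],
            "length": [p.length for p in paths],
            "frequency_pct": [p.frequency for p in paths],
        }
    )
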