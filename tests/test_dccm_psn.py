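"""Cross-correlation matrices, structure networks, and pathway search."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cntor
from cntor.dccm import CorrelationMatrix, dccm, fluctuation_matrix
from cntor.errors import AnalysisError
from cntor.psn import (
    StructureNetwork,
    annotate_frequencies,
    build_network,
    interaction_strength_frame,
    interaction_strength_value,
    node_frequency_summary,
    path_frequency,
    shortest_paths,
    Pathway,
)
from cntor.synthetic import block_correlation, gen_correlated_trajectory
from cntor.system import Atom, MolecularSystem, Selection, Trajectory, select

from conftest import make_chain_trajectory


def _ca_traj(deltas):
    """Trajectory of a 3.8 Å chain plus the given (n_frames, n_res, 3) deltas."""
    deltas = np.asarray(deltas, dtype=float)
    base = np.zeros((deltas.shape[1], 3))
    base[:, 0] = np.arange(deltas.shape[1]) * 3.8
    return make_chain_trajectory(base[None] + deltas)


class TestFluctuations:
    def test_static_trajectory_zero(self):
        traj = _ca_traj(np.zeros((4, 5, 3)))
        sel = select(traj.system, "name CA")
        deltas = fluctuation_matrix(traj, sel, align=None)
        assert np.allclose(deltas, 0.0)

    def test_mirrored_frames_opposite(self):
        d = np.zeros((2, 5, 3))
        d[0, :, 1] = 0.5
        d[1, :, 1] = -0.5
        traj = _ca_traj(d)
        sel = select(traj.system, "name CA")
        deltas = fluctuation_matrix(traj, sel, align=None)
        assert np.allclose(deltas[0], -deltas[1], atol=1e-12)

    def test_rigid_rotation_removed_by_alignment(self):
        base = np.random.default_rng(0).normal(size=(6, 3)) * 4
        frames = [base]
        for angle in (5, 10, 15):
            rot = Rotation.from_euler("z", angle, degrees=True).as_matrix()
            frames.append(base @ rot.T)
        traj = make_chain_trajectory(np.stack(frames))
        sel = select(traj.system, "name CA")
        deltas = fluctuation_matrix(traj, sel, align=sel)
        assert np.max(np.abs(deltas)) < 1e-6

    def test_single_frame_rejected(self):
        traj = _ca_traj(np.zeros((1, 4, 3)))
        sel = select(traj.system, "name CA")
        with pytest.raises(AnalysisError):
            fluctuation_matrix(traj, sel)


class TestDccm:
    def test_identical_and_opposite_series(self):
        rng = np.random.default_rng(1)
        series = rng.normal(size=(50, 1, 3))
        d = np.concatenate([series, series, -series], axis=1)
        traj = _ca_traj(d)
        sel = select(traj.system, "name CA")
        m = dccm(traj, sel, align=None)
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert m.values[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_motions_uncorrelated(self):
        rng = np.random.default_rng(2)
        n = 200
        d = np.zeros((n, 2, 3))
        d[:, 0, 0] = rng.normal(size=n)  # x only
        d[:, 1, 1] = rng.normal(size=n)  # y only
        traj = _ca_traj(d)
        m = dccm(traj, select(traj.system, "name CA"), align=None)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_structural_invariants(self):
        traj, _ = gen_correlated_trajectory(n_residues=8, n_frames=300, seed=3)
        m = dccm(traj, select(traj.system, "name CA"), align=None)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.all(m.values >= -1.0) and np.all(m.values <= 1.0)

    def test_recovers_generator_correlation(self):
        traj, truth = gen_correlated_trajectory(
            n_residues=10, n_frames=5000, seed=7
        )
        m = dccm(traj, select(traj.system, "name CA"), align=None)
        err = np.max(np.abs(m.values - np.asarray(truth["correlation"])))
        assert err < 0.05

    def test_zero_variance_flagged_or_dropped(self):
        d = np.zeros((10, 3, 3))
        d[:, :2, 0] = np.random.default_rng(4).normal(size=(10, 2))
        traj = _ca_traj(d)
        sel = select(traj.system, "name CA")
        with pytest.raises(AnalysisError, match="zero-variance"):
            dccm(traj, sel, align=None)
        m = dccm(traj, sel, align=None, drop_zero_variance=True)
        assert m.n_residues == 2


def _residue_system(res_atoms):
    """Build a system from {residue: [(name, xyz), ...]}, all heavy carbons."""
    atoms, coords = [], []
    i = 0
    for r, entries in enumerate(res_atoms):
        for name, xyz in entries:
            atoms.append(
                Atom(index=i, name=name, element="C", residue_index=r,
                     residue_name="LEU", group="receptor")
            )
            coords.append(xyz)
            i += 1
    return MolecularSystem(atoms), np.asarray(coords, dtype=float)


class TestInteractionStrength:
    def test_scalar_arithmetic(self):
        assert interaction_strength_value(4, 64, 100) == pytest.approx(5.0)
        assert interaction_strength_value(np.sqrt(64 * 100), 64, 100) == (
            pytest.approx(100.0)
        )

    def test_no_contacts_zero(self):
        system, coords = _residue_system(
            [[("CB", (0, 0, 0))], [("CB", (0, 0, 50))], [("CB", (0, 0, 100))]]
        )
        df = interaction_strength_frame(coords, system)
        assert np.allclose(df.to_numpy(), 0.0)

    def test_covalent_neighbors_excluded(self):
        system, coords = _residue_system(
            [[("CB", (0, 0, 0))], [("CB", (0, 0, 1.0))]]
        )
        df = interaction_strength_frame(coords, system)
        assert df.loc[0, 1] == 0.0

    def test_pair_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        res_atoms = []
        for r in range(3):
            entries = [("CB", rng.uniform(0, 8, size=3)) for _ in range(4)]
            res_atoms.append(entries)
        system, coords = _residue_system(res_atoms)
        norm = {"LEU": 72.2517}
        df = interaction_strength_frame(coords, system, normalization=norm)
        # brute force over all side-chain atom pairs
        for ri in range(3):
            for rj in range(ri + 2, 3):
                n_ij = 0
                for a in range(4):
                    for b in range(4):
                        d = np.linalg.norm(coords[ri * 4 + a] - coords[rj * 4 + b])
                        if d <= 4.5:
                            n_ij += 1
                expected = n_ij / np.sqrt(norm["LEU"] ** 2) * 100
                assert df.loc[ri, rj] == pytest.approx(expected)

    def test_glycine_pseudo_side_chain(self):
        atoms = [
            Atom(index=0, name="CA", element="C", residue_index=0,
                 residue_name="GLY", group="receptor"),
            Atom(index=1, name="CB", element="C", residue_index=1,
                 residue_name="ALA", group="receptor"),
            Atom(index=2, name="CB", element="C", residue_index=2,
                 residue_name="ALA", group="receptor"),
        ]
        system = MolecularSystem(atoms)
        coords = np.array([[0.0, 0, 0], [0, 0, 20.0], [0, 3.0, 0]])
        df = interaction_strength_frame(coords, system)
        # glycine CA is within 4.5 Å of residue 2's CB
        assert df.loc[0, 2] > 0


class TestNetwork:
    def _two_edge_traj(self):
        # 10 frames: residues 0-2 always close; 2-4 close in 6 frames
        res_atoms = [
            [("CB", (0.0, 0, 0))], [("CB", (0, 0, 30.0))],
            [("CB", (3.0, 0, 0))], [("CB", (0, 0, 60.0))],
            [("CB", (3.0, 3.0, 0))],
        ]
        system, base = _residue_system(res_atoms)
        frames = np.stack([base] * 10)
        for f in range(6, 10):
            frames[f, 4] = (50.0, 50.0, 50.0)  # break 2-4 in last 4 frames
        return Trajectory(system, frames)

    def test_occupancy_thresholds(self):
        traj = self._two_edge_traj()
        net_05 = build_network(traj, imin=1.0, occupancy_min=0.5)
        pairs_05 = {(i, j) for i, j, _, _ in net_05.edges}
        assert (0, 2) in pairs_05 and (2, 4) in pairs_05
        net_07 = build_network(traj, imin=1.0, occupancy_min=0.7)
        pairs_07 = {(i, j) for i, j, _, _ in net_07.edges}
        assert (0, 2) in pairs_07 and (2, 4) not in pairs_07

    def test_raising_imin_never_adds_edges(self):
        traj = self._two_edge_traj()
        low = build_network(traj, imin=0.5, occupancy_min=0.5)
        high = build_network(traj, imin=5.0, occupancy_min=0.5)
        low_pairs = {(i, j) for i, j, _, _ in low.edges}
        high_pairs = {(i, j) for i, j, _, _ in high.edges}
        assert high_pairs <= low_pairs


def _bfs_oracle(n_nodes, edges, source, sink):
    """Hand-written breadth-first search hop count (None if unreachable)."""
    adj = {i: set() for i in range(n_nodes)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    frontier = {source}
    seen = {source}
    hops = 0
    while frontier:
        if sink in frontier:
            return hops
        nxt = set()
        for u in frontier:
            nxt |= adj[u] - seen
        seen |= nxt
        frontier = nxt
        hops += 1
    return None


def _network_from_edges(n_nodes, edges, strengths=None):
    es = []
    for k, (a, b) in enumerate(edges):
        s = 1.0 if strengths is None else strengths[k]
        es.append((a, b, s, 1.0))
    return StructureNetwork(nodes=list(range(n_nodes)), edges=es, imin=1.0,
                            distance_cutoff=4.5, occupancy_min=0.5, n_frames=1)


def _full_corr(n):
    return CorrelationMatrix(np.ones((n, n)), list(range(n)))


class TestShortestPaths:
    def test_single_edge(self):
        net = _network_from_edges(2, [(0, 1)])
        paths, missing = shortest_paths(net, _full_corr(2), [0], [1])
        assert paths[0].nodes == [0, 1] and paths[0].length == 1
        assert not missing

    def test_disconnected_pair(self):
        net = _network_from_edges(3, [(0, 1)])
        paths, missing = shortest_paths(net, _full_corr(3), [0], [2])
        assert missing == [(0, 2)] and not paths

    def test_source_equals_sink(self):
        net = _network_from_edges(2, [(0, 1)])
        paths, _ = shortest_paths(net, _full_corr(2), [0], [0])
        assert paths[0].length == 0

    def test_correlation_filter_blocks_edges(self):
        net = _network_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        corr = np.ones((3, 3))
        corr[0, 2] = corr[2, 0] = 0.1  # direct edge decorrelated
        paths, _ = shortest_paths(net, CorrelationMatrix(corr, [0, 1, 2]),
                                  [0], [2], corr_min=0.3)
        assert paths[0].nodes == [0, 1, 2]

    def test_tie_break_prefers_stronger_then_lexicographic(self):
        # two 2-hop routes 0-1-3 and 0-2-3; make 0-2-3 stronger
        net = _network_from_edges(4, [(0, 1), (1, 3), (0, 2), (2, 3)],
                                  strengths=[1.0, 1.0, 2.0, 2.0])
        paths, _ = shortest_paths(net, _full_corr(4), [0], [3])
        assert paths[0].nodes == [0, 2, 3]
        # equal strengths: lexicographic order wins
        net2 = _network_from_edges(4, [(0, 1), (1, 3), (0, 2), (2, 3)])
        paths2, _ = shortest_paths(net2, _full_corr(4), [0], [3])
        assert paths2[0].nodes == [0, 1, 3]

    def test_hop_counts_match_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(6)
        agree = 0
        for _ in range(100):
            n = int(rng.integers(4, 21))
            density = rng.uniform(0.1, 0.4)
            edges = [
                (a, b)
                for a in range(n)
                for b in range(a + 1, n)
                if rng.random() < density
            ]
            net = _network_from_edges(n, edges)
            s, t = rng.choice(n, size=2, replace=False)
            expected = _bfs_oracle(n, edges, int(s), int(t))
            paths, missing = shortest_paths(net, _full_corr(n), [int(s)], [int(t)])
            if expected is None:
                agree += missing == [(int(s), int(t))]
            else:
                agree += bool(paths) and paths[0].length == expected
        assert agree == 100


class TestPathFrequency:
    def _strengths(self):
        # 100 frames, 4 nodes; edge (1,2) present in 81 frames, others always
        mats = np.zeros((100, 4, 4))
        for a, b in ((0, 1), (2, 3)):
            mats[:, a, b] = mats[:, b, a] = 5.0
        mats[:81, 1, 2] = mats[:81, 2, 1] = 5.0
        return mats, [0, 1, 2, 3]

    def test_always_present_path(self):
        strengths = self._strengths()
        p = Pathway(nodes=[0, 1], source=0, sink=1)
        assert path_frequency(p, strengths, imin=3.0) == pytest.approx(100.0)

    def test_partial_edge_sets_frequency(self):
        strengths = self._strengths()
        p = Pathway(nodes=[0, 1, 2, 3], source=0, sink=3)
        assert path_frequency(p, strengths, imin=3.0) == pytest.approx(81.0)

    def test_subpath_at_least_full_path(self):
        rng = np.random.default_rng(7)
        mats = (rng.random((50, 5, 5)) * 6).round(2)
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        strengths = (mats, list(range(5)))
        full = Pathway(nodes=[0, 1, 2, 3, 4], source=0, sink=4)
        sub = Pathway(nodes=[0, 1, 2], source=0, sink=2)
        assert path_frequency(sub, strengths, imin=3.0) >= path_frequency(
            full, strengths, imin=3.0
        )

    def test_matches_brute_force_conjunction(self):
        rng = np.random.default_rng(8)
        mats = rng.random((30, 4, 4)) * 6
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        strengths = (mats, [0, 1, 2, 3])
        p = Pathway(nodes=[0, 2, 3], source=0, sink=3)
        brute = sum(
            1
            for f in range(30)
            if mats[f, 0, 2] >= 3.0 and mats[f, 2, 3] >= 3.0
        ) / 30 * 100
        assert path_frequency(p, strengths, imin=3.0) == pytest.approx(brute)


class TestNodeSummary:
    def test_common_start_dominates(self):
        paths = [Pathway(nodes=[5, 1, 2], source=5, sink=2),
                 Pathway(nodes=[5, 3], source=5, sink=3),
                 Pathway(nodes=[5, 4], source=5, sink=4)]
        starts, ends = node_frequency_summary(paths)
        assert starts[0] == (5, 3.0)

    def test_tie_orders_by_residue_index(self):
        paths = [Pathway(nodes=[9, 1], source=9, sink=1),
                 Pathway(nodes=[2, 1], source=2, sink=1)]
        starts, _ = node_frequency_summary(paths)
        assert [s[0] for s in starts] == [2, 9]

    def test_weighted_counts_match_oracle(self):
        rng = np.random.default_rng(9)
        paths = []
        for _ in range(42):
            s = int(rng.integers(0, 5))
            t = int(rng.integers(5, 10))
            p = Pathway(nodes=[s, t], source=s, sink=t,
                        frequency=float(rng.integers(1, 101)))
            paths.append(p)
        starts, ends = node_frequency_summary(paths, k=10)
        oracle_starts = {}
        for p in paths:
            oracle_starts[p.source] = oracle_starts.get(p.source, 0.0) + p.frequency
        for node, weight in starts:
            assert weight == pytest.approx(oracle_starts[node])
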