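"""Tests for the shortest-path-map residue-network analysis."""

import networkx as nx
import numpy as np
import pytest

from halocat.errors import DegenerateResidueError, InvalidParameterError
from halocat.spm import (
    CoordinateEnsemble,
    build_spm_graph,
    dccm,
    mean_distance_matrix,
    read_ensemble_table,
    shortest_path_lengths,
    shortest_path_map,
    write_edge_csv,
    write_ensemble_table,
)
from halocat.synthetic_data import EnsembleSpec, simulate_ensemble

from _spm_fixtures import CHAIN_EDGES, brute_force_shortest_lengths, planted_chain_ensemble


def toy_ensemble(n_frames=50, seed=0):
    rng = np.random.default_rng(seed)
    base = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
    return CoordinateEnsemble(frames=base[None] + rng.normal(0, 0.5, (n_frames, 3, 3)))


class TestDccm:
    def test_duplicated_residue_fully_correlated(self):
        ens = toy_ensemble()
        frames = np.concatenate([ens.frames, ens.frames[:, :1, :]], axis=1)
        c = dccm(CoordinateEnsemble(frames=frames))
        assert c[0, 3] == pytest.approx(1.0, abs=1e-12)

    def test_mirrored_displacements_anticorrelated(self):
        rng = np.random.default_rng(1)
        disp = rng.normal(0, 1, (100, 1, 3))
        frames = np.concatenate([disp, -disp + 10.0], axis=1)
        c = dccm(CoordinateEnsemble(frames=frames))
        assert c[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_residues_decorrelate(self):
        spec = EnsembleSpec(
            mean_coordinates=np.zeros((4, 3)),
            correlation_targets=np.eye(4),
            n_frames=5000,
            seed=7,
        )
        c = dccm(simulate_ensemble(spec))
        off = c[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.1)

    def test_symmetric_unit_diagonal_bounded(self):
        c = dccm(toy_ensemble())
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)
        assert np.all(np.abs(c) <= 1.0)

    def test_static_residue_named_in_error(self):
        frames = toy_ensemble().frames
        frames[:, 1, :] = 7.0
        with pytest.raises(DegenerateResidueError, match="1"):
            dccm(CoordinateEnsemble(frames=frames))


class TestMeanDistance:
    def test_static_ensemble_exact(self):
        base = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        ens = CoordinateEnsemble(frames=np.repeat(base[None], 5, axis=0))
        m = mean_distance_matrix(ens)
        assert m[0, 1] == pytest.approx(5.0, abs=1e-12)
        assert np.allclose(np.diag(m), 0.0)

    def test_symmetric_oscillation_averages_out(self):
        # residue 1 oscillates +-1 A along the separation axis around 5 A
        frames = np.array(
            [[[0.0, 0, 0], [4.0, 0, 0]], [[0.0, 0, 0], [6.0, 0, 0]]]
        )
        m = mean_distance_matrix(CoordinateEnsemble(frames=frames))
        assert m[0, 1] == pytest.approx(5.0, abs=1e-12)


class TestBuildGraph:
    M = np.array([[0.0, 4.0, 7.0], [4.0, 0.0, 5.0], [7.0, 5.0, 0.0]])

    def test_perfect_correlation_zero_weight(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 1.0
        g = build_spm_graph(self.M, c, min_abs_corr=0.0)
        assert g.graph[0][1]["weight"] == 0.0

    def test_distance_cutoff_excludes_far_pairs(self):
        c = np.full((3, 3), 0.99)
        g = build_spm_graph(self.M, c)
        assert not g.graph.has_edge(0, 2)  # 7 A >= 6 A
        assert g.graph.has_edge(0, 1)

    def test_log_weight_value(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.5
        g = build_spm_graph(self.M, c)
        assert g.graph[0][1]["weight"] == pytest.approx(np.log(2.0), rel=1e-12)

    def test_weak_correlation_dropped(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.005
        g = build_spm_graph(self.M, c)
        assert not g.graph.has_edge(0, 1)

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidParameterError):
            build_spm_graph(self.M, np.eye(4))


class TestShortestPathMap:
    def path_graph(self):
        m = np.array([[0, 4.0, 9.0], [4.0, 0, 4.0], [9.0, 4.0, 0]])
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.9
        c[1, 2] = c[2, 1] = 0.5
        return build_spm_graph(m, c)

    def test_three_node_path_length(self):
        g = self.path_graph()
        lengths = shortest_path_lengths(g)
        assert lengths[0][2] == pytest.approx(-np.log(0.9) - np.log(0.5), rel=1e-12)

    def test_star_hub_edges_dominate(self):
        n = 5
        m = np.full((n, n), 10.0)
        m[0, :] = m[:, 0] = 4.0
        np.fill_diagonal(m, 0.0)
        c = np.full((n, n), 0.5)
        np.fill_diagonal(c, 1.0)
        mapped = shortest_path_map(build_spm_graph(m, c))
        usages = nx.get_edge_attributes(mapped.graph, "usage")
        # every hub edge carries its leaf's paths to the 3 other leaves + the hub pair
        assert all(u == 4 for u in usages.values())

    def test_single_edge_graph(self):
        m = np.array([[0.0, 4.0], [4.0, 0.0]])
        c = np.array([[1.0, 0.5], [0.5, 1.0]])
        mapped = shortest_path_map(build_spm_graph(m, c))
        assert mapped.graph[0][1]["usage"] == 1
        assert mapped.map_edges == {(0, 1)}

    def test_empty_graph_rejected(self):
        g = build_spm_graph(np.zeros((2, 2)) + 10.0, np.eye(2))
        with pytest.raises(InvalidParameterError):
            shortest_path_map(g)

    def test_disconnected_components_handled(self):
        m = np.full((4, 4), 10.0)
        np.fill_diagonal(m, 0.0)
        m[0, 1] = m[1, 0] = 4.0
        m[2, 3] = m[3, 2] = 4.0
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        mapped = shortest_path_map(build_spm_graph(m, c))
        assert mapped.graph[0][1]["usage"] == 1
        assert mapped.graph[2][3]["usage"] == 1

    def test_usage_bounded_by_pair_count(self):
        mapped = shortest_path_map(build_spm_graph(
            np.where(np.eye(6), 0.0, 4.0), np.where(np.eye(6), 1.0, 0.5)
        ))
        n = 6
        for _, _, u in mapped.graph.edges(data="usage"):
            assert 0 <= u <= n * (n - 1) / 2


class TestOracleEquivalence:
    def random_graph(self, rng, n):
        m = np.full((n, n), 10.0)
        c = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.5:
                    m[i, j] = m[j, i] = rng.uniform(2.0, 5.9)
                    corr = rng.uniform(0.05, 0.99)
                    c[i, j] = c[j, i] = corr
        np.fill_diagonal(m, 0.0)
        return build_spm_graph(m, c)

    def test_dijkstra_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g = self.random_graph(rng, int(rng.integers(4, 9)))
            if g.graph.number_of_edges() == 0:
                continue
            lengths = shortest_path_lengths(g)
            brute = brute_force_shortest_lengths(g.graph)
            for (s, t), expected in brute.items():
                assert lengths[s][t] == pytest.approx(expected, rel=1e-12)

    def test_weight_monotonicity_under_correlation_increase(self):
        rng = np.random.default_rng(3)
        g = self.random_graph(rng, 7)
        before = shortest_path_lengths(g)
        i, j = next(iter(g.graph.edges))
        g.graph[i][j]["weight"] *= 0.5  # |c| increased
        after = shortest_path_lengths(g)
        for s in before:
            for t in before[s]:
                assert after[s][t] <= before[s][t] + 1e-12


class TestEndToEnd:
    def test_planted_chain_recovered(self):
        ens = planted_chain_ensemble(seed=0)
        g = build_spm_graph(mean_distance_matrix(ens), dccm(ens))
        mapped = shortest_path_map(g, usage_quantile=0.8)
        assert CHAIN_EDGES <= mapped.map_edges

    def test_label_permutation_consistency(self):
        ens = planted_chain_ensemble(seed=1, n_frames=500)
        perm = np.random.default_rng(0).permutation(ens.n_residues)
        permuted = CoordinateEnsemble(
            frames=ens.frames[:, perm, :],
            residue_labels=[ens.residue_labels[i] for i in perm],
        )
        c1, c2 = dccm(ens), dccm(permuted)
        assert np.allclose(c2, c1[np.ix_(perm, perm)], atol=1e-12)
        m1, m2 = mean_distance_matrix(ens), mean_distance_matrix(permuted)
        assert np.allclose(m2, m1[np.ix_(perm, perm)], atol=1e-12)


def test_ensemble_table_round_trip(tmp_path):
    ens = planted_chain_ensemble(seed=2, n_frames=20)
    path = tmp_path / "ens.txt"
    write_ensemble_table(path, ens)
    loaded = read_ensemble_table(path)
    assert loaded.frames.shape == ens.frames.shape
    assert np.allclose(loaded.frames, ens.frames, atol=1e-5)


def test_edge_csv_export(tmp_path):
    m = np.array([[0.0, 4.0], [4.0, 0.0]])
    c = np.array([[1.0, 0.5], [0.5, 1.0]])
    mapped = shortest_path_map(build_spm_graph(m, c))
    out = tmp_path / "edges.csv"
    write_edge_csv(out, mapped)
    text = out.read_text()
    assert "res_i" in text and "usage" in text
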