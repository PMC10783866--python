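"""Graph loading, column normalization and random-walk smoothing."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import mutstrat as ms
from mutstrat.errors import ConvergenceError, DataError, ParameterError
from mutstrat.network import TransitionMatrix, _rwr_matrix


def edge_df(rows):
    return pd.DataFrame(rows, columns=["gene1", "gene2", "score"])


class TestLoadNetwork:
    def test_score_filter_drops_low_edges_and_isolated_nodes(self):
        net = ms.load_network(edge_df([("A", "B", 900), ("B", "C", 500)]), 700)
        assert set(net.genes) == {"A", "B"}
        assert net.n_edges == 1

    def test_reciprocal_rows_collapse_to_max_score(self):
        net = ms.load_network(edge_df([("A", "B", 900), ("B", "A", 800)]), 700)
        assert net.n_edges == 1
        assert net.adjacency.max() == 900

    def test_self_loops_dropped_and_empty_graph_errors(self):
        with pytest.raises(DataError):
            ms.load_network(edge_df([("A", "A", 950), ("B", "C", 100)]), 700)

    def test_case_insensitive_gene_ids(self):
        net = ms.load_network(edge_df([("kras", "TP53", 800)]), 700)
        assert set(net.genes) == {"KRAS", "TP53"}

    def test_file_roundtrip(self, tmp_path, small_cohort):
        path = tmp_path / "edges.tsv"
        small_cohort["network"].edge_list().to_csv(path, sep="\t", index=False)
        net = ms.load_network(path, 700)
        assert net.genes == small_cohort["network"].genes
        assert net.n_edges == small_cohort["network"].n_edges


class TestTransitionMatrix:
    def test_two_nodes_unit_edge(self):
        net = ms.load_network(edge_df([("A", "B", 800)]), 700)
        W = ms.build_transition_matrix(net).W.toarray()
        assert np.allclose(W, [[0, 1], [1, 0]])

    def test_equal_weight_triangle_columns(self):
        net = ms.load_network(
            edge_df([("A", "B", 800), ("B", "C", 800), ("A", "C", 800)]), 700
        )
        W = ms.build_transition_matrix(net).W.toarray()
        assert np.allclose(W.sum(axis=0), 1.0)
        assert np.allclose(W[W > 0], 0.5)

    def test_weighted_star_normalizes_center_column(self):
        # center C with leaves weighted 1,2,3 (as 701,702,703 minus offset is
        # awkward; use scores 710, 720, 730 and check proportionality)
        net = ms.load_network(
            edge_df([("C", "L1", 710), ("C", "L2", 720), ("C", "L3", 730)]), 700
        )
        tm = ms.build_transition_matrix(net)
        c = tm.genes.index("C")
        col = tm.W.toarray()[:, c]
        expected = np.array([710, 720, 730]) / (710 + 720 + 730)
        leaves = [tm.genes.index(l) for l in ("L1", "L2", "L3")]
        assert np.allclose(col[leaves], expected)

    def test_binarized_edges_ignore_weights(self):
        net = ms.load_network(edge_df([("C", "L1", 710), ("C", "L2", 900)]), 700)
        tm = ms.build_transition_matrix(net, binarize_edges=True)
        c = tm.genes.index("C")
        col = tm.W.toarray()[:, c]
        assert np.allclose(col[col > 0], 0.5)

    def test_column_sums_validated(self):
        with pytest.raises(DataError):
            TransitionMatrix(W=sp.csr_matrix(np.array([[0.0, 0.5], [1.0, 0.0]])), genes=("A", "B"))


class TestRWR:
    def test_restart_only_limit_returns_seed(self, two_node_transition):
        p0 = np.array([0.3, 0.7])
        p, iters = ms.rwr(p0, two_node_transition, ms.RWRParams(r=1.0))
        assert np.array_equal(p, p0)

    def test_two_node_closed_form(self, two_node_transition):
        # p_inf = r (I - (1-r) W)^-1 p0 = (0.8, 0.2) for r = 0.75
        p, _ = ms.rwr(np.array([1.0, 0.0]), two_node_transition, ms.RWRParams())
        assert np.allclose(p, [0.8, 0.2], atol=1e-5)

    def test_regular_ring_uniform_fixed_point(self):
        n = 8
        g = sp.diags([1, 1], [1, -1], shape=(n, n)).tolil()
        g[0, n - 1] = g[n - 1, 0] = 1
        net = ms.GeneNetwork(genes=tuple(f"g{i}" for i in range(n)), adjacency=g.tocsr())
        tm = ms.build_transition_matrix(net)
        p, _ = ms.rwr(np.full(n, 1 / n), tm, ms.RWRParams())
        assert np.allclose(p, 1 / n, atol=1e-9)

    def test_matches_direct_linear_solve_on_random_graphs(self):
        rng = np.random.default_rng(0)
        params = ms.RWRParams(tol=1e-10)
        for _ in range(10):
            n = int(rng.integers(10, 120))
            import networkx as nx

            g = nx.gnp_random_graph(n, 4 / n, seed=int(rng.integers(2**31)))
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            A = nx.to_scipy_sparse_array(g, format="csr").astype(float)
            m = A.shape[0]
            net = ms.GeneNetwork(genes=tuple(map(str, range(m))), adjacency=A)
            tm = ms.build_transition_matrix(net)
            p0 = rng.dirichlet(np.ones(m))
            p_iter, _ = ms.rwr(p0, tm, params)
            direct = params.r * np.linalg.solve(
                np.eye(m) - (1 - params.r) * tm.W.toarray(), p0
            )
            assert np.max(np.abs(p_iter - direct)) < 1e-8

    def test_convergence_error_carries_residual(self, two_node_transition):
        with pytest.raises(ConvergenceError) as exc:
            ms.rwr(np.array([1.0, 0.0]), two_node_transition, ms.RWRParams(max_iter=1))
        assert exc.value.residual is not None

    def test_seed_validation(self, two_node_transition):
        with pytest.raises(ParameterError):
            ms.rwr(np.array([0.5, 0.6]), two_node_transition)
        with pytest.raises(ParameterError):
            ms.rwr(np.array([1.0, 0.0, 0.0]), two_node_transition)


class TestSmoothProfile:
    def test_single_mutated_gene_equals_unit_seed_rwr(self, small_cohort):
        net = small_cohort["network"]
        tm = ms.build_transition_matrix(net)
        g = net.genes[3]
        mut = pd.DataFrame(0, index=["s1"], columns=list(net.genes))
        mut.loc["s1", g] = 1
        sm = ms.smooth_profile(mut, net)
        e = np.zeros(net.n_genes)
        e[3] = 1.0
        expected, _ = ms.rwr(e, tm)
        assert np.allclose(sm.values.loc["s1"].to_numpy(), expected, atol=1e-9)

    def test_batch_equals_per_sample_rwr(self, small_cohort):
        # at tight tolerance both routes land on the same fixed point
        net, mut = small_cohort["network"], small_cohort["mutations"].iloc[:20]
        params = ms.RWRParams(tol=1e-12)
        tm = ms.build_transition_matrix(net)
        batch = ms.smooth_profile(mut, net, params)
        for sid in mut.index[:5]:
            row = mut.loc[sid].to_numpy().astype(float)
            p0 = (row > 0) / (row > 0).sum()
            single, _ = ms.rwr(p0, tm, params)
            assert np.max(np.abs(batch.values.loc[sid].to_numpy() - single)) < 1e-10

    def test_mass_conservation(self, small_cohort):
        sm = ms.smooth_profile(small_cohort["mutations"], small_cohort["network"])
        assert np.allclose(sm.values.sum(axis=1), 1.0, atol=1e-8)

    def test_path_graph_mass_decreases_with_distance(self):
        n = 12
        A = sp.diags([1, 1], [1, -1], shape=(n, n), format="csr").astype(float)
        net = ms.GeneNetwork(genes=tuple(f"g{i}" for i in range(n)), adjacency=A)
        mut = pd.DataFrame(0, index=["s"], columns=list(net.genes))
        mut.iloc[0, 0] = 1
        sm = ms.smooth_profile(mut, net)
        vals = sm.values.iloc[0].to_numpy()
        assert (np.diff(vals) <= 1e-12).all()

    def test_restart_continuity_to_identity(self, two_node_transition):
        p0 = np.array([1.0, 0.0])
        dists = []
        for r in (0.5, 0.75, 0.9, 0.99):
            p, _ = ms.rwr(p0, two_node_transition, ms.RWRParams(r=r, tol=1e-12))
            dists.append(np.max(np.abs(p - p0)))
        assert all(a > b for a, b in zip(dists, dists[1:]))
        assert dists[-1] < 0.01

    def test_unmapped_sample_error_and_exclude(self, small_cohort):
        net = small_cohort["network"]
        mut = pd.DataFrame(0, index=["ok", "lost"], columns=[*net.genes[:5], "NOT_A_GENE"])
        mut.loc["ok", net.genes[0]] = 1
        mut.loc["lost", "NOT_A_GENE"] = 1
        with pytest.raises(DataError):
            ms.smooth_profile(mut, net)
        sm = ms.smooth_profile(mut, net, on_unmapped_sample="exclude")
        assert list(sm.values.index) == ["ok"]

    def test_vertex_transitive_all_mutated_gives_uniform(self):
        n = 6
        g = sp.diags([1, 1], [1, -1], shape=(n, n)).tolil()
        g[0, n - 1] = g[n - 1, 0] = 1
        net = ms.GeneNetwork(genes=tuple(f"g{i}" for i in range(n)), adjacency=g.tocsr())
        mut = pd.DataFrame(1, index=["s"], columns=list(net.genes))
        sm = ms.smooth_profile(mut, net)
        assert np.allclose(sm.values.iloc[0], 1 / n, atol=1e-9)
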