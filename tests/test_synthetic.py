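"""Cohort generator: determinism, planted structure, survival calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mutstrat as ms
from mutstrat.errors import ParameterError


class TestNetworkGeneration:
    def test_connected_with_expected_nodes_and_scores(self, small_cohort):
        import networkx as nx

        net = small_cohort["network"]
        g = nx.from_scipy_sparse_array(net.adjacency)
        assert net.n_genes == small_cohort["spec"].n_genes
        assert nx.is_connected(g)
        scores = net.adjacency.data
        assert (scores > 700).all() and (scores <= 1000).all()

    def test_same_seed_identical_edge_lists(self, small_spec):
        e1 = ms.generate_network(small_spec).edge_list()
        e2 = ms.generate_network(small_spec).edge_list()
        pd.testing.assert_frame_equal(e1, e2)

    def test_preferential_attachment_degree_heavy_tailed(self):
        spec = ms.SyntheticSpec(n_genes=1000, avg_degree=8, wiring="ba", seed=0)
        net = ms.generate_network(spec)
        deg = np.asarray((net.adjacency > 0).sum(axis=1)).ravel()
        assert deg.max() > 3 * deg.mean()

    def test_minimum_size_and_degree_validated(self):
        with pytest.raises(ParameterError):
            ms.SyntheticSpec(n_genes=5)
        with pytest.raises(ParameterError):
            ms.generate_network(ms.SyntheticSpec(n_genes=10, avg_degree=30))


class TestPathwayGeneration:
    def test_count_and_sizes_within_range(self, small_cohort):
        pw, spec = small_cohort["pathways"], small_cohort["spec"]
        assert len(pw) == spec.n_pathways
        lo, hi = spec.pathway_size_range
        assert all(lo <= len(g) <= hi for g in pw.sets.values())

    def test_single_fixed_size_pathway(self, small_spec):
        from dataclasses import replace

        spec = replace(
            small_spec, n_pathways=1, pathway_size_range=(3, 3), n_informative_pathways=1
        )
        net = ms.generate_network(spec)
        pw = ms.generate_pathways(net, spec)
        assert len(pw) == 1 and len(next(iter(pw.sets.values()))) == 3

    def test_sets_are_network_local(self, small_cohort):
        # mean pairwise shortest-path distance within sets beats the
        # distance of size-matched random sets
        import networkx as nx

        net, pw = small_cohort["network"], small_cohort["pathways"]
        g = nx.from_scipy_sparse_array(net.adjacency)
        pos = {gene: i for i, gene in enumerate(net.genes)}
        rng = np.random.default_rng(0)

        def mean_dist(nodes):
            ds = [
                nx.shortest_path_length(g, a, b)
                for i, a in enumerate(nodes)
                for b in nodes[i + 1 :]
            ]
            return np.mean(ds)

        real = np.mean(
            [mean_dist([pos[x] for x in genes][:8]) for genes in pw.sets.values()]
        )
        random_sets = [
            list(rng.choice(net.n_genes, 8, replace=False)) for _ in range(100)
        ]
        baseline = np.mean([mean_dist(s) for s in random_sets])
        assert real < baseline


class TestCohortGeneration:
    def test_binary_entries_and_no_empty_rows(self, small_cohort):
        M = small_cohort["mutations"].to_numpy()
        assert set(np.unique(M)) <= {0, 1}
        assert (M.sum(axis=1) >= 1).all()

    def test_bitwise_reproducible_with_fixed_seed(self, small_spec):
        net = ms.generate_network(small_spec)
        pw = ms.generate_pathways(net, small_spec)
        m1, c1, l1 = ms.generate_cohort(net, pw, small_spec)
        m2, c2, l2 = ms.generate_cohort(net, pw, small_spec)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_no_enrichment_means_no_burden_difference(self):
        spec = ms.SyntheticSpec(
            n_genes=300, n_samples=500, n_pathways=20, pathway_size_range=(5, 15),
            n_informative_pathways=5, enrichment_factor=1.0, seed=3,
        )
        net = ms.generate_network(spec)
        pw = ms.generate_pathways(net, spec)
        mut, clin, lab = ms.generate_cohort(net, pw, spec)
        burden = mut.sum(axis=1)
        p = stats.mannwhitneyu(burden[lab == "A"], burden[lab == "B"]).pvalue
        assert p > 0.01

    def test_mean_burden_matches_rate_times_genes(self):
        # 468 genes at rate 0.01 -> ~4.7 mutations per sample
        spec = ms.SyntheticSpec(
            n_genes=468, community_size=26, n_samples=400, n_pathways=10,
            pathway_size_range=(5, 15), n_informative_pathways=2,
            baseline_mutation_rate=0.01, enrichment_factor=1.0, seed=4,
        )
        net = ms.generate_network(spec)
        pw = ms.generate_pathways(net, spec)
        mut, _, _ = ms.generate_cohort(net, pw, spec)
        assert mut.sum(axis=1).median() == pytest.approx(4.7, abs=2.0)

    def test_null_hazard_rarely_significant_on_true_labels(self):
        rejections = 0
        for seed in range(50):
            spec = ms.SyntheticSpec(
                n_genes=60, community_size=15, n_samples=150, n_pathways=4,
                pathway_size_range=(4, 8), n_informative_pathways=1,
                hazard_log_ratio=0.0, seed=seed,
            )
            net = ms.generate_network(spec)
            pw = ms.generate_pathways(net, spec)
            _, clin, lab = ms.generate_cohort(net, pw, spec)
            _, _, p = ms.logrank_test(clin, lab)
            rejections += p < 0.05
        assert rejections <= 5  # >= 90% non-significant

    def test_censoring_rate_calibrated(self, small_cohort):
        censored = 1.0 - small_cohort["clinical"]["os_event"].mean()
        assert censored == pytest.approx(small_cohort["spec"].censoring_rate, abs=0.12)

    def test_enrichment_monotone_in_informative_burden_gap(self, small_spec):
        # the plant is symmetric (first half of informative sets enriched in
        # subtype A); common random numbers per seed make the A-side gap
        # exactly monotone in the enrichment factor
        from dataclasses import replace

        gaps = []
        for enr in (1.0, 2.0, 3.0):
            spec = replace(small_spec, enrichment_factor=enr)
            net = ms.generate_network(spec)
            pw = ms.generate_pathways(net, spec)
            mut, _, lab = ms.generate_cohort(net, pw, spec)
            names = list(pw.sets)[: spec.n_informative_pathways]
            a_half = {
                g for name in names[: (len(names) + 1) // 2] for g in pw.sets[name]
            }
            burden = mut[list(a_half)].sum(axis=1)
            gaps.append(burden[lab == "A"].mean() - burden[lab == "B"].mean())
        assert gaps[0] <= gaps[1] <= gaps[2]

    def test_subtype_burden_balanced(self, small_cohort):
        # symmetric enrichment keeps total burden comparable across subtypes
        mut, lab = small_cohort["mutations"], small_cohort["labels"]
        a = mut[lab == "A"].sum(axis=1).mean()
        b = mut[lab == "B"].sum(axis=1).mean()
        assert abs(a - b) / max(a, b) < 0.25

    def test_impossible_rates_rejected(self):
        with pytest.raises(ParameterError):
            ms.SyntheticSpec(baseline_mutation_rate=0.5, enrichment_factor=3.0)


class TestActivityCohort:
    def test_shapes_and_informative_shift(self):
        act, clin, informative = ms.generate_activity_cohort(n_samples=400, seed=1)
        assert act.shape == (400, 114) and len(informative) == 10
        a = clin["subtype_true"] == "A"
        gap = act.loc[a, informative].mean().mean() - act.loc[~a, informative].mean().mean()
        assert gap == pytest.approx(0.8, abs=0.15)


class TestCohortFiles:
    def test_write_cohort_round_trips(self, tmp_path, small_cohort):
        from mutstrat import io
        from mutstrat.synthetic import write_cohort

        paths = write_cohort(
            tmp_path, small_cohort["network"], small_cohort["pathways"],
            small_cohort["mutations"], small_cohort["clinical"],
        )
        assert set(paths) == {"edges", "mutations", "clinical", "gmt"}
        mut = io.read_mutation_matrix(paths["mutations"])
        pd.testing.assert_frame_equal(
            mut, small_cohort["mutations"].astype("int8"), check_names=False
        )
        sets = io.read_gmt(paths["gmt"])
        assert sets == small_cohort["pathways"].sets
        net = ms.load_network(paths["edges"], 700)
        assert net.n_edges == small_cohort["network"].n_edges
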