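"""Single-sample enrichment scoring against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mutstrat as ms
from mutstrat.errors import DataError


def naive_es(values: np.ndarray, mask: np.ndarray, alpha: float) -> float:
    """Direct running-sum implementation of the single-sample statistic."""
    order = np.argsort(-values, kind="stable")
    N = len(values)
    m = int(mask.sum())
    w = [(N - pos) ** alpha for pos in range(N)]
    denom = sum(w[pos] for pos in range(N) if mask[order[pos]])
    run, es = 0.0, 0.0
    for pos in range(N):
        if mask[order[pos]]:
            run += w[pos] / denom
        else:
            run -= 1.0 / (N - m)
        es += run
    return es


class TestRankTransform:
    def test_simple_descending_ranks(self):
        assert list(ms.rank_transform(np.array([5.0, 1.0, 3.0]))) == [1, 3, 2]

    def test_all_equal_stable_ties(self):
        assert list(ms.rank_transform(np.ones(4))) == [1, 2, 3, 4]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_sort_oracle(self, vals):
        ranks = ms.rank_transform(np.array(vals))
        # oracle: position in a stable descending sort, 1-based
        order = sorted(range(len(vals)), key=lambda i: (-vals[i], i))
        expected = np.empty(len(vals), dtype=int)
        for pos, i in enumerate(order):
            expected[i] = pos + 1
        assert np.array_equal(ranks, expected)

    def test_nan_rejected(self):
        with pytest.raises(DataError):
            ms.rank_transform(np.array([1.0, np.nan]))


class TestSsgseaSample:
    def test_top_gene_singleton_matches_oracle(self):
        vals = np.array([4.0, 3.0, 2.0, 1.0])
        mask = np.array([True, False, False, False])
        assert ms.ssgsea_sample(vals, mask, alpha=0.0) == pytest.approx(
            naive_es(vals, mask, 0.0), abs=1e-12
        )

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_naive_oracle_on_random_instances(self, alpha):
        rng = np.random.default_rng(17)
        for _ in range(50):
            N = int(rng.integers(5, 80))
            vals = rng.normal(size=N)
            m = int(rng.integers(1, N))
            mask = np.zeros(N, bool)
            mask[rng.choice(N, m, replace=False)] = True
            got = ms.ssgsea_sample(vals, mask, alpha=alpha)
            assert got == pytest.approx(naive_es(vals, mask, alpha), abs=1e-12)

    def test_random_membership_mean_near_zero(self):
        # alpha=0 makes the statistic symmetric; its mean over random
        # memberships is ~0 relative to its spread
        rng = np.random.default_rng(0)
        vals = rng.normal(size=50)
        es = []
        for _ in range(1000):
            mask = np.zeros(50, bool)
            mask[rng.choice(50, 8, replace=False)] = True
            es.append(ms.ssgsea_sample(vals, mask, alpha=0.0))
        assert abs(np.mean(es)) < 3 * np.std(es) / np.sqrt(len(es)) + 0.5

    def test_out_of_set_value_swap_leaves_score_unchanged(self):
        vals = np.array([4.0, 3.0, 2.0, 1.0, 0.5])
        mask = np.array([True, False, False, True, False])
        swapped = vals.copy()
        swapped[[1, 2]] = swapped[[2, 1]]  # both out of set
        assert ms.ssgsea_sample(vals, mask, 0.25) == pytest.approx(
            ms.ssgsea_sample(swapped, mask, 0.25), abs=1e-12
        )

    def test_raising_in_set_value_never_decreases_score(self):
        # provable for alpha=0 (uniform in-set weights); with alpha>0 the
        # rank-weight denominator can shift, so monotonicity is only
        # guaranteed in the unweighted statistic
        rng = np.random.default_rng(5)
        for _ in range(50):
            vals = rng.normal(size=30)
            mask = np.zeros(30, bool)
            mask[rng.choice(30, 6, replace=False)] = True
            i = rng.choice(np.flatnonzero(mask))
            base = ms.ssgsea_sample(vals, mask, 0.0)
            vals2 = vals.copy()
            vals2[i] += abs(rng.normal()) + 0.1
            assert ms.ssgsea_sample(vals2, mask, 0.0) >= base - 1e-12

    def test_degenerate_sets_rejected(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(DataError):
            ms.ssgsea_sample(vals, ["zzz"])
        with pytest.raises(DataError):
            ms.ssgsea_sample(vals, ["a", "b", "c"])


class TestActivityMatrix:
    def test_column_count_and_order_preserved(self, small_cohort):
        sm = ms.smooth_profile(small_cohort["mutations"].iloc[:10], small_cohort["network"])
        act = ms.activity_matrix(sm.values, small_cohort["pathways"])
        assert list(act.scores.columns) == small_cohort["pathways"].names
        assert act.scores.shape == (10, len(small_cohort["pathways"]))

    def test_identical_samples_get_identical_rows(self, small_cohort):
        sm = ms.smooth_profile(small_cohort["mutations"].iloc[:3], small_cohort["network"])
        dup = pd.concat([sm.values, sm.values.iloc[[0]].set_axis(["copy"])])
        act = ms.activity_matrix(dup, small_cohort["pathways"]).scores
        assert np.allclose(act.iloc[0], act.loc["copy"])

    def test_normalized_span_is_exactly_one(self, small_cohort):
        sm = ms.smooth_profile(small_cohort["mutations"].iloc[:10], small_cohort["network"])
        act = ms.activity_matrix(sm.values, small_cohort["pathways"], normalize=True).scores
        assert act.to_numpy().max() - act.to_numpy().min() == pytest.approx(1.0, abs=1e-12)

    def test_empty_intersection_sets_dropped_with_remainder_kept(self, small_cohort):
        sm = ms.smooth_profile(small_cohort["mutations"].iloc[:5], small_cohort["network"])
        coll = ms.GeneSetCollection(
            sets={"real": small_cohort["pathways"].sets[small_cohort["pathways"].names[0]],
                  "ghost": ["NOPE1", "NOPE2"]}
        )
        act = ms.activity_matrix(sm.values, coll)
        assert list(act.scores.columns) == ["real"]

    def test_gene_relabeling_permutes_scores_consistently(self, small_cohort):
        sm = ms.smooth_profile(small_cohort["mutations"].iloc[:5], small_cohort["network"])
        prof = sm.values
        perm = np.random.default_rng(3).permutation(prof.shape[1])
        relabeled = prof.iloc[:, perm]
        a1 = ms.activity_matrix(prof, small_cohort["pathways"]).scores
        a2 = ms.activity_matrix(relabeled, small_cohort["pathways"]).scores
        assert np.allclose(a1.to_numpy(), a2[a1.columns].to_numpy(), atol=1e-12)


class TestGeneLevelProfile:
    def test_matches_singleton_set_activity_matrix(self, small_cohort):
        sm = ms.smooth_profile(small_cohort["mutations"].iloc[:4], small_cohort["network"])
        prof = sm.values.iloc[:, :30]
        singles = ms.GeneSetCollection(sets={g: [g] for g in prof.columns})
        via_sets = ms.activity_matrix(prof, singles, normalize=False).scores
        direct = ms.gene_level_profile(prof, normalize=False).scores
        assert np.allclose(via_sets.to_numpy(), direct.to_numpy(), atol=1e-9)

    def test_rank_monotone_with_smoothed_values(self, small_cohort):
        from scipy.stats import spearmanr

        sm = ms.smooth_profile(small_cohort["mutations"].iloc[:5], small_cohort["network"])
        gl = ms.gene_level_profile(sm.values).scores
        for sid in gl.index:
            rho = spearmanr(gl.loc[sid], sm.values.loc[sid]).statistic
            assert rho == pytest.approx(1.0, abs=1e-12)

    def test_column_order_equals_profile_order(self, small_cohort):
        sm = ms.smooth_profile(small_cohort["mutations"].iloc[:3], small_cohort["network"])
        gl = ms.gene_level_profile(sm.values)
        assert list(gl.scores.columns) == list(sm.values.columns)

    def test_top_gene_has_largest_singleton_score(self, small_cohort):
        sm = ms.smooth_profile(small_cohort["mutations"].iloc[:3], small_cohort["network"])
        gl = ms.gene_level_profile(sm.values, normalize=False).scores
        for sid in gl.index:
            top = sm.values.loc[sid].idxmax()
            assert gl.loc[sid, top] == gl.loc[sid].max()
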