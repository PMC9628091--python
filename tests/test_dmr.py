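"""Split, bootstrap, Welch/FDR statistics and the DMR selection cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from cfamf.amf import AMFMatrix
from cfamf.dmr import (
    ScreenError,
    SplitSpec,
    SubsetStats,
    candidate_pca_check,
    draw_subsets,
    fdr_qvalues,
    intersect_and_rank,
    screen_subset,
    stratified_split,
    welch_test,
)
from tests.conftest import build_matrix


def cohort_frame(n_good, n_poor):
    n = n_good + n_poor
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group": ["good"] * n_good + ["poor"] * n_poor,
    })


class TestStratifiedSplit:
    def test_85_15_split_of_109_34_gives_93_29_and_16_5(self):
        cohort = cohort_frame(109, 34)
        train, test = stratified_split(cohort, SplitSpec(seed=0))
        groups = cohort.set_index("sample_id")["group"]
        assert (groups.loc[train] == "good").sum() == 93
        assert (groups.loc[train] == "poor").sum() == 29
        assert (groups.loc[test] == "good").sum() == 16
        assert (groups.loc[test] == "poor").sum() == 5

    def test_half_split_of_balanced_cohort(self):
        cohort = cohort_frame(10, 10)
        train, test = stratified_split(
            cohort, SplitSpec(train_fraction=0.5, seed=1))
        assert len(train) == 10 and len(test) == 10

    def test_partition_is_disjoint_and_exhaustive(self):
        cohort = cohort_frame(23, 9)
        train, test = stratified_split(cohort, SplitSpec(seed=5))
        assert set(train) | set(test) == set(cohort["sample_id"])
        assert not set(train) & set(test)

    def test_tiny_group_rejected(self):
        with pytest.raises(ScreenError):
            stratified_split(cohort_frame(10, 1), SplitSpec())


class TestDrawSubsets:
    def test_subsets_preserve_size_and_group_composition(self):
        cohort = cohort_frame(109, 34)
        train, _ = stratified_split(cohort, SplitSpec(seed=0))
        subsets = draw_subsets(train, cohort, n_subsets=3, seed=2)
        groups = cohort.set_index("sample_id")["group"]
        for s in subsets:
            assert len(s) == 122
            assert sum(groups[x] == "good" for x in s) == 93
            assert sum(groups[x] == "poor" for x in s) == 29

    def test_seed_reproducibility(self):
        cohort = cohort_frame(20, 10)
        train, _ = stratified_split(cohort, SplitSpec(seed=0))
        assert draw_subsets(train, cohort, seed=3) == \
            draw_subsets(train, cohort, seed=3)

    def test_single_subset_degenerates_to_one_screen(self):
        cohort = cohort_frame(20, 10)
        train, _ = stratified_split(cohort, SplitSpec(seed=0))
        assert len(draw_subsets(train, cohort, n_subsets=1, seed=0)) == 1


class TestWelch:
    def test_textbook_example(self):
        diff, t, df, p = welch_test([0.2, 0.3, 0.4], [0.8, 0.9, 1.0])
        assert diff == pytest.approx(-0.6)
        assert t == pytest.approx(-7.348469, abs=1e-5)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0018263, abs=1e-6)

    def test_identical_groups(self):
        diff, t, df, p = welch_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert (diff, t, p) == (0.0, 0.0, 1.0)

    def test_zero_variance_different_means_does_not_divide_by_zero(self):
        diff, t, df, p = welch_test([0.2, 0.2], [0.9, 0.9])
        assert np.isinf(t) and p > 0 and p < 1e-300

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            diff, t, df, p = welch_test(a, b)
            ref = sp_stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_equals_pooled_t_with_equal_sizes_and_variances(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        b = a + 0.25  # same spread, shifted
        _, t, df, p = welch_test(a, b)
        ref = sp_stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestFDR:
    def test_bh_step_up_hand_computation(self):
        q = fdr_qvalues([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_equal_pvalues_share_their_value(self):
        np.testing.assert_allclose(fdr_qvalues([0.2] * 5), [0.2] * 5)

    def test_single_pvalue_unchanged(self):
        assert fdr_qvalues([0.3])[0] == pytest.approx(0.3)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan]])
    def test_out_of_range_pvalues_rejected(self, bad):
        with pytest.raises(ScreenError):
            fdr_qvalues(bad)

    def test_matches_statsmodels_bh(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(1e-8, 1, size=rng.integers(2, 60))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(fdr_qvalues(p), ref, atol=1e-12)

    def test_empirical_null_variant_never_exceeds_bh(self):
        rng = np.random.default_rng(12)
        p = np.concatenate([rng.uniform(1e-7, 1e-3, 40),
                            rng.uniform(0, 1, 60).clip(1e-9)])
        assert (fdr_qvalues(p, "empirical-null") <= fdr_qvalues(p) + 1e-12).all()


def stats_table(entries):
    """SubsetStats from (bin_id, q, z) tuples."""
    df = pd.DataFrame(entries, columns=["bin_id", "q", "z"])
    df["direction"] = np.where(df["z"] < 0, "hypo", "hyper")
    return SubsetStats(table=df, dmr_ids=list(df["bin_id"]),
                       n_tested=len(df))


class TestIntersectAndRank:
    def test_intersection_is_set_algebra(self):
        subsets = [
            stats_table([("chr1:0-100", 0.01, -3), ("chr1:100-200", 0.01, -3),
                         ("chr1:200-300", 0.01, -3)]),
            stats_table([("chr1:100-200", 0.01, -3), ("chr1:200-300", 0.01, -3),
                         ("chr1:300-400", 0.01, -3)]),
            stats_table([("chr1:100-200", 0.01, -3), ("chr1:200-300", 0.01, -3)]),
        ]
        out = intersect_and_rank(subsets, top_k=10)
        assert out.intersection_dmrs == ["chr1:100-200", "chr1:200-300"]
        assert out.candidates == out.intersection_dmrs

    def test_rank_filter_on_worked_toy(self):
        # ranks within the intersection: B=(1,1,2), C=(2,3,1), E=(3,2,3);
        # with top_k=2 only B is in the top 2 of every subset
        B, C, E = "chr1:0-100", "chr1:100-200", "chr1:200-300"
        subsets = [
            stats_table([(B, 0.01, -5), (C, 0.02, -4), (E, 0.03, -3)]),
            stats_table([(B, 0.01, -5), (E, 0.02, -3), (C, 0.03, -4)]),
            stats_table([(C, 0.01, -4), (B, 0.02, -5), (E, 0.03, -3)]),
        ]
        out = intersect_and_rank(subsets, top_k=2)
        assert out.candidates == [B]

    def test_generous_top_k_returns_whole_intersection(self):
        subsets = [stats_table([("chr1:0-100", 0.01, -3)])] * 3
        out = intersect_and_rank(subsets, top_k=500)
        assert out.candidates == ["chr1:0-100"]

    def test_empty_intersection_warns(self):
        subsets = [stats_table([("chr1:0-100", 0.01, -3)]),
                   stats_table([("chr1:100-200", 0.01, -3)])]
        with pytest.warns(UserWarning, match="empty"):
            out = intersect_and_rank(subsets)
        assert out.candidates == []


@pytest.fixture(scope="module")
def screened(small_cohort):
    matrix, _ = build_matrix(small_cohort)
    cohort = small_cohort.cohort
    train, _ = stratified_split(cohort, SplitSpec(seed=0))
    subsets = draw_subsets(train, cohort, n_subsets=3, seed=1)
    results = [screen_subset(matrix, s, cohort) for s in subsets]
    return small_cohort, matrix, cohort, train, subsets, results


class TestScreenSubset:

    def test_z_is_standardized_over_tested_bins(self, screened):
        _, _, _, _, _, results = screened
        for r in results:
            z = r.table["z"].to_numpy()
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_planted_dmrs_recovered_with_hypo_direction(self, screened):
        cohort_sim, _, _, _, _, results = screened
        truth = set(cohort_sim.truth.dmr_bin_ids)
        cand = intersect_and_rank(results, top_k=500).candidates
        recall = len(set(cand) & truth) / len(truth)
        assert recall >= 0.8
        directions = pd.concat([r.table.set_index("bin_id")
                                .loc[cand, "direction"] for r in results])
        assert (directions == "hypo").mean() >= 0.9

    def test_threshold_relaxation_never_shrinks_dmr_set(self, screened):
        _, matrix, cohort, _, subsets, _ = screened
        strict = screen_subset(matrix, subsets[0], cohort,
                               z_threshold=2.0, q_threshold=0.05)
        loose = screen_subset(matrix, subsets[0], cohort,
                              z_threshold=1.0, q_threshold=0.20)
        assert set(strict.dmr_ids) <= set(loose.dmr_ids)

    def test_intersection_no_larger_than_smallest_subset(self, screened):
        _, _, _, _, _, results = screened
        out = intersect_and_rank(results, top_k=10 ** 6)
        assert len(out.intersection_dmrs) <= min(
            len(r.dmr_ids) for r in results)

    def test_mean_difference_standardization_example(self):
        # diffs of exactly (-0.5, 0, 0.5) standardize to (-1, 0, 1)
        bins = pd.DataFrame({
            "chrom": ["chr1"] * 3, "start": [0, 100, 200],
            "end": [100, 200, 300], "n_cpgs": [5] * 3,
        })
        good = np.array([[0.1, 0.2], [0.5, 0.6], [0.8, 0.9]])
        poor = good.copy()
        poor[0] += 0.5   # diff -0.5
        poor[2] -= 0.5   # diff +0.5
        values = np.hstack([good + [[0.0], [0.0], [0.0]], poor])
        matrix = AMFMatrix(bins=bins, samples=["g1", "g2", "p1", "p2"],
                           values=np.clip(values, 0, 1))
        cohort = pd.DataFrame({
            "sample_id": ["g1", "g2", "p1", "p2"],
            "group": ["good", "good", "poor", "poor"],
        })
        res = screen_subset(matrix, ["g1", "g2", "p1", "p2"], cohort,
                            coverage_threshold=0.0)
        np.testing.assert_allclose(res.table["z"], [-1.0, 0.0, 1.0],
                                   atol=1e-12)


class TestCandidatePCACheck:
    def test_duplicated_sample_projects_to_identical_coordinates(
            self, small_cohort):
        matrix, _ = build_matrix(small_cohort)
        complete = ~np.isnan(matrix.values).any(axis=0)
        ids = [s for s, ok in zip(matrix.samples, complete) if ok]
        train = ids[:20]
        test = [train[0], ids[20]]
        cands = matrix.bin_ids()[:15]
        tr, te = candidate_pca_check(matrix, cands, train, test)
        np.testing.assert_allclose(te.loc[train[0]].to_numpy(),
                                   tr.loc[train[0]].to_numpy(), atol=1e-9)

    def test_single_candidate_gives_one_dimensional_scores(
            self, small_cohort):
        matrix, _ = build_matrix(small_cohort)
        train = matrix.samples[:10]
        test = matrix.samples[10:14]
        tr, te = candidate_pca_check(matrix, matrix.bin_ids()[:1],
                                     train, test)
        assert tr.shape[1] == 1 and te.shape[1] == 1

    def test_planted_effect_separates_groups_on_pc1_in_train_and_test(
            self, small_cohort):
        matrix, _ = build_matrix(small_cohort)
        cohort = small_cohort.cohort
        train, test = stratified_split(cohort, SplitSpec(seed=3))
        truth = [b for b in small_cohort.truth.dmr_bin_ids
                 if b in set(matrix.bin_ids())]
        tr, te = candidate_pca_check(matrix, truth, train, test)
        groups = cohort.set_index("sample_id")["group"]

        def separation(scores):
            g = scores.loc[[s for s in scores.index
                            if groups[s] == "good"], "PC1"].mean()
            p = scores.loc[[s for s in scores.index
                            if groups[s] == "poor"], "PC1"].mean()
            return g - p

        assert separation(tr) * separation(te) > 0
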