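"""Random-forest marker selection, ROC/AUC, importance and annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from cfamf.dmr import SplitSpec, stratified_split
from cfamf.forest import (
    ModelError,
    RFConfig,
    annotate_markers,
    export_gene_list,
    rank_markers,
    roc_auc,
    train_forest,
)
from tests.conftest import build_matrix

FAST_RF = dict(n_folds=5, n_repeats=1, n_trees=150, mtry_grid=[4])


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_uninformative_constant_scores(self):
        _, auc = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_anti_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.4, 0.3], [0, 0, 1, 1])
        assert auc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_trapezoidal_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if y.all() or not y.any():
                continue
            scores = np.round(rng.random(n), 1)  # force ties
            _, auc = roc_auc(scores, y)
            ranks = rankdata(scores)
            n1, n0 = int(y.sum()), int((1 - y).sum())
            u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)


@pytest.fixture(scope="module")
def trained(small_cohort):
    matrix, _ = build_matrix(small_cohort)
    cohort = small_cohort.cohort
    train, test = stratified_split(cohort, SplitSpec(seed=1))
    truth = [b for b in small_cohort.truth.dmr_bin_ids
             if b in set(matrix.bin_ids())]
    model = train_forest(matrix, truth, cohort, train, test,
                         RFConfig(seed=5, **FAST_RF))
    return small_cohort, matrix, cohort, model


class TestTrainForest:
    def test_planted_effect_classified_on_held_out_samples(self, trained):
        _, _, _, model = trained
        assert model.roc_test["auc"] >= 0.9

    def test_same_seed_reproduces_marker_list(self, small_cohort, trained):
        _, matrix, cohort, model = trained
        train, test = stratified_split(cohort, SplitSpec(seed=1))
        truth = [b for b in small_cohort.truth.dmr_bin_ids
                 if b in set(matrix.bin_ids())]
        again = train_forest(matrix, truth, cohort, train, test,
                             RFConfig(seed=5, **FAST_RF))
        pd.testing.assert_series_equal(model.importance, again.importance)

    def test_single_class_training_rejected(self, small_cohort):
        matrix, _ = build_matrix(small_cohort)
        cohort = small_cohort.cohort
        good_only = list(cohort.loc[cohort["group"] == "good",
                                    "sample_id"][:10])
        with pytest.raises(ModelError, match="single class"):
            train_forest(matrix, matrix.bin_ids()[:5], cohort, good_only,
                         None, RFConfig(seed=0, **FAST_RF))

    def test_duplicated_signal_feature_still_outranks_noise(self):
        """A feature duplicated into two columns splits its importance but
        the pair together still dominates pure-noise features."""
        rng = np.random.default_rng(20)
        n = 60
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        signal = y + rng.normal(0, 0.35, n)
        x = np.column_stack([signal, signal,
                             rng.normal(size=(n, 4))])
        x = (x - x.min()) / (x.max() - x.min())
        bins = pd.DataFrame({
            "chrom": ["chr1"] * 6, "start": np.arange(6) * 100,
            "end": (np.arange(6) + 1) * 100, "n_cpgs": [5] * 6})
        from cfamf.amf import AMFMatrix

        matrix = AMFMatrix(bins=bins,
                           samples=[f"s{i}" for i in range(n)],
                           values=x.T)
        cohort = pd.DataFrame({
            "sample_id": matrix.samples,
            "group": np.where(y == 1, "good", "poor")})
        model = train_forest(matrix, matrix.bin_ids(), cohort,
                             matrix.samples, None,
                             RFConfig(seed=2, n_folds=3, n_repeats=1,
                                      n_trees=200, mtry_grid=[2]))
        imp = model.importance.to_numpy()
        assert imp[0] + imp[1] > imp[2:].max()


class TestRankMarkers:
    def test_top_n_zero_gives_empty_list(self, trained):
        _, matrix, cohort, model = trained
        assert len(rank_markers(model, matrix, cohort, top_n=0)) == 0

    def test_oversized_top_n_truncated_with_warning(self, trained):
        _, matrix, cohort, model = trained
        with pytest.warns(UserWarning, match="truncat"):
            out = rank_markers(model, matrix, cohort, top_n=10 ** 6)
        assert len(out) == len(model.importance)

    def test_equal_importance_broken_by_genomic_coordinate(self, trained):
        _, matrix, cohort, model = trained
        tied = model.importance.copy()
        tied[:] = 1.0
        import dataclasses

        flat = dataclasses.replace(model, importance=tied)
        out = rank_markers(flat, matrix, cohort, top_n=5)
        coords = list(zip(out["chrom"], out["start"]))
        assert coords == sorted(coords)

    def test_group_summaries_attached(self, trained):
        _, matrix, cohort, model = trained
        out = rank_markers(model, matrix, cohort, top_n=5)
        assert {"median_good", "median_poor", "iqr_good",
                "iqr_poor"} <= set(out.columns)
        # planted hypomethylation: good medians sit below poor medians
        assert (out["median_good"] < out["median_poor"]).all()


GENE_MODEL = pd.DataFrame({
    "chrom": ["chr1", "chr1", "chr1"],
    "start": [100, 300, 700],
    "end": [200, 400, 800],
    "gene": ["GENE1", "GENE1", "GENE2"],
    "strand": ["+", "+", "-"],
})  # GENE1 body 100-400 with exons 100-200 and 300-400; GENE2 700-800


class TestAnnotate:
    def markers(self, start, end, chrom="chr1"):
        return pd.DataFrame({"bin_id": [f"{chrom}:{start}-{end}"],
                             "chrom": [chrom], "start": [start],
                             "end": [end]})

    def test_marker_inside_exon(self):
        out = annotate_markers(self.markers(120, 180), GENE_MODEL)
        assert out["region"].iloc[0] == "exon"
        assert out["nearest_gene"].iloc[0] == "GENE1"
        assert out["gene_distance"].iloc[0] == 0

    def test_exon_outranks_intron_on_double_overlap(self):
        out = annotate_markers(self.markers(150, 250), GENE_MODEL)
        assert out["region"].iloc[0] == "exon"

    def test_gene_body_without_exon_is_intron(self):
        out = annotate_markers(self.markers(210, 290), GENE_MODEL)
        assert out["region"].iloc[0] == "intron"

    def test_outside_all_genes_is_intergenic_with_nearest(self):
        out = annotate_markers(self.markers(500, 600), GENE_MODEL)
        assert out["region"].iloc[0] == "intergenic"
        assert out["nearest_gene"].iloc[0] in ("GENE1", "GENE2")

    def test_unknown_chromosome_is_intergenic_without_gene(self):
        out = annotate_markers(self.markers(0, 100, chrom="chrZ"),
                               GENE_MODEL)
        assert out["region"].iloc[0] == "intergenic"
        assert out["nearest_gene"].iloc[0] is None

    def test_malformed_gene_model_rejected(self):
        with pytest.raises(ModelError):
            annotate_markers(self.markers(0, 100),
                             pd.DataFrame({"chrom": [], "start": []}))


class TestGeneList:
    def test_deduplicated_and_sorted(self, tmp_path):
        annotated = pd.DataFrame({
            "region": ["exon", "intron", "exon"],
            "nearest_gene": ["B", "A", "B"],
        })
        path = tmp_path / "genes.txt"
        out = export_gene_list(annotated, path)
        assert out == ["A", "B"]
        assert path.read_text() == "A\nB\n"

    def test_all_intergenic_without_nearest_warns_and_writes_empty(
            self, tmp_path):
        annotated = pd.DataFrame({
            "region": ["intergenic"], "nearest_gene": [None]})
        path = tmp_path / "genes.txt"
        with pytest.warns(UserWarning, match="empty"):
            out = export_gene_list(annotated, path,
                                   include_nearest=False)
        assert out == [] and path.read_text() == ""
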