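"""Random-forest marker selection on candidate-DMR AMF profiles.

A forest is tuned over a small ``mtry`` (max_features) grid by repeated
stratified cross-validation on the training set, refitted on the full
training set, and evaluated on the held-out test set. The training-set ROC
is computed from out-of-fold cross-validation predictions — resubstitution
predictions of a forest are near-perfect by construction and would say
nothing. Variable importance is the mean decrease in Gini impurity; the
top markers are annotated against a gene model with the priority
exon > intron > intergenic.

Missing AMF cells are imputed with training-group means on the training
side and overall training means on the test side, so no label information
leaks into test predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from cfamf.amf import AMFMatrix


class ModelError(ValueError):
    pass


@dataclass
class RFConfig:
    n_folds: int = 10
    n_repeats: int = 10
    n_trees: int = 500
    mtry_grid: list | None = None   # default: {sqrt(p)/2, sqrt(p), 2 sqrt(p)}
    selection_metric: str = "auc"   # or "accuracy"
    top_n_markers: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ModelError("n_folds must be >= 2")
        if self.selection_metric not in ("auc", "accuracy"):
            raise ModelError("selection_metric must be 'auc' or 'accuracy'")

    def resolve_mtry(self, p: int) -> list:
        if self.mtry_grid is not None:
            grid = [m for m in self.mtry_grid if 1 <= m <= p]
            if not grid:
                raise ModelError("mtry_grid has no value <= n_features")
            return sorted(set(grid))
        root = max(1, int(np.sqrt(p)))
        return sorted({max(1, root // 2), root, min(p, 2 * root)})


@dataclass
class MarkerModel:
    forest: RandomForestClassifier
    config: RFConfig
    feature_ids: list
    classes: list                      # [negative, positive] label order
    cv_metric_table: pd.DataFrame      # mtry, cv_auc, cv_accuracy
    best_mtry: int
    roc_train: dict                    # fpr, tpr, thresholds, auc (CV-based)
    roc_test: dict | None
    importance: pd.Series              # per candidate bin, Gini importance
    train_bin_means: np.ndarray = field(repr=False, default=None)


def roc_auc(scores, labels, positive_label=1) -> tuple:
    """Empirical ROC curve and trapezoidal AUC.

    Equals the Mann-Whitney U normalization P(score+ > score-) with ties
    counted half. Returns (curve dict, auc).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_label
    if y.all() or not y.any():
        raise ModelError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # collapse threshold ties
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / y.sum()]
    fpr = np.r_[0.0, fps[distinct] / (~y).sum()]
    thresholds = np.r_[np.inf, scores[order][distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ({"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": auc},
            auc)


def _design(matrix: AMFMatrix, sample_ids: list) -> np.ndarray:
    """samples x bins design block (may contain NaN)."""
    return matrix.subset_samples(sample_ids).values.T


def _impute(x: np.ndarray, fill: np.ndarray) -> np.ndarray:
    x = x.copy()
    nan = np.isnan(x)
    x[nan] = np.broadcast_to(fill, x.shape)[nan]
    return x


def train_forest(matrix: AMFMatrix, candidate_ids: list,
                 cohort: pd.DataFrame, train_ids: list,
                 test_ids: list | None = None,
                 config: RFConfig | None = None,
                 positive_group: str = "good") -> MarkerModel:
    """Tune, fit and evaluate the marker forest.

    ``matrix`` is the cohort AMF matrix; features are ``candidate_ids``
    bins. Predicted probabilities refer to ``positive_group``.
    """
    config = config or RFConfig()
    if not candidate_ids:
        raise ModelError("no candidate features")
    row = {b: i for i, b in enumerate(matrix.bin_ids())}
    cand = matrix.subset_bins(np.array([row[b] for b in candidate_ids]))

    groups = cohort.set_index("sample_id")["group"]
    y_train = (groups.loc[train_ids] == positive_group).to_numpy().astype(int)
    if len(np.unique(y_train)) < 2:
        raise ModelError("training set contains a single class")

    x_train = _design(cand, train_ids)
    # train imputation: per-bin group means (training samples only)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fill_overall = np.nanmean(x_train, axis=0)
        for cls in (0, 1):
            rows = y_train == cls
            gm = np.nanmean(x_train[rows], axis=0)
            gm = np.where(np.isnan(gm), fill_overall, gm)
            x_train[rows] = _impute(x_train[rows], gm)
    if np.isnan(fill_overall).any():
        raise ModelError("a candidate bin has no observed training value")

    p = x_train.shape[1]
    grid = config.resolve_mtry(p)
    rng = np.random.default_rng(config.seed)
    cv_seed = int(rng.integers(0, 2 ** 31 - 1))
    fit_seed = int(rng.integers(0, 2 ** 31 - 1))

    cv_rows = []
    oof_by_mtry = {}
    n_splits = min(config.n_folds, int(np.bincount(y_train).min()))
    if n_splits < 2:
        raise ModelError("too few samples in a class for cross-validation")
    for mtry in grid:
        cv = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=config.n_repeats,
            random_state=cv_seed,
        )
        oof = np.zeros(len(y_train))
        hits = np.zeros(len(y_train))
        correct = 0
        total = 0
        for tr, va in cv.split(x_train, y_train):
            clf = RandomForestClassifier(
                n_estimators=config.n_trees, max_features=mtry,
                random_state=fit_seed, n_jobs=1,
            )
            clf.fit(x_train[tr], y_train[tr])
            prob = clf.predict_proba(x_train[va])[:, list(clf.classes_).index(1)]
            oof[va] += prob
            hits[va] += 1
            correct += int(((prob >= 0.5).astype(int) == y_train[va]).sum())
            total += len(va)
        oof /= hits
        _, cv_auc = roc_auc(oof, y_train)
        cv_rows.append({"mtry": mtry, "cv_auc": cv_auc,
                        "cv_accuracy": correct / total})
        oof_by_mtry[mtry] = oof
    cv_table = pd.DataFrame(cv_rows)
    metric = "cv_auc" if config.selection_metric == "auc" else "cv_accuracy"
    best_mtry = int(cv_table.sort_values([metric, "mtry"],
                                         ascending=[False, True])
                    .iloc[0]["mtry"])

    forest = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=best_mtry,
        random_state=fit_seed, n_jobs=1,
    )
    forest.fit(x_train, y_train)
    roc_train, _ = roc_auc(oof_by_mtry[best_mtry], y_train)

    roc_test = None
    if test_ids:
        y_test = (groups.loc[test_ids] == positive_group).to_numpy().astype(int)
        x_test = _impute(_design(cand, test_ids), fill_overall)
        prob = forest.predict_proba(x_test)[:, list(forest.classes_).index(1)]
        roc_test, _ = roc_auc(prob, y_test)

    importance = pd.Series(forest.feature_importances_, index=candidate_ids,
                           name="gini_importance")
    return MarkerModel(
        forest=forest, config=config, feature_ids=list(candidate_ids),
        classes=[f"not_{positive_group}", positive_group],
        cv_metric_table=cv_table, best_mtry=best_mtry,
        roc_train=roc_train, roc_test=roc_test, importance=importance,
        train_bin_means=fill_overall,
    )


def rank_markers(model: MarkerModel, matrix: AMFMatrix,
                 cohort: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Top markers by Gini importance, ties broken by genomic coordinate.

    Attaches per-group AMF median and IQR over the full cohort.
    """
    top_n = model.config.top_n_markers if top_n is None else top_n
    if top_n > len(model.importance):
        warnings.warn("top_n exceeds candidate count; truncating",
                      stacklevel=2)
        top_n = len(model.importance)
    imp = model.importance

    def coord_key(b):
        chrom, rng_ = b.rsplit(":", 1)
        return (chrom, int(rng_.split("-")[0]))

    order = sorted(imp.index, key=lambda b: (-imp[b], coord_key(b)))
    chosen = order[:top_n]
    row = {b: i for i, b in enumerate(matrix.bin_ids())}
    groups = cohort.set_index("sample_id")["group"]
    rows = []
    for b in chosen:
        vals = matrix.values[row[b]]
        rec = {"bin_id": b, "importance": float(imp[b])}
        for g in sorted(groups.unique()):
            cols = np.flatnonzero(
                np.array([groups[s] == g for s in matrix.samples]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                v = vals[cols]
                rec[f"median_{g}"] = float(np.nanmedian(v))
                q1, q3 = np.nanpercentile(v, [25, 75])
            rec[f"iqr_{g}"] = float(q3 - q1)
        rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=["bin_id", "importance", "chrom",
                                     "start", "end"])
    out = pd.DataFrame(rows)
    coords = out["bin_id"].map(coord_key)
    out["chrom"] = [c for c, _ in coords]
    out["start"] = [s for _, s in coords]
    out["end"] = [int(b.rsplit(":", 1)[1].split("-")[1])
                  for b in out["bin_id"]]
    return out


# ---------------------------------------------------------------------------
# annotation


def annotate_markers(markers: pd.DataFrame,
                     gene_model: pd.DataFrame) -> pd.DataFrame:
    """Classify markers as exon / intron / intergenic and attach the
    nearest gene.

    ``gene_model`` is an exon table (chrom, start, end, gene[, strand]);
    gene bodies are the per-gene exon spans. Priority: any exon overlap ->
    exon; else any gene-body overlap -> intron; else intergenic. The
    nearest gene is attached with a signed distance on the forward axis
    (positive when the gene starts downstream of the marker; 0 on overlap).
    """
    required = {"chrom", "start", "end", "gene"}
    if not required <= set(gene_model.columns):
        raise ModelError(
            f"gene model must carry columns {sorted(required)}")
    exon_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    bodies = (gene_model.groupby(["chrom", "gene"])
              .agg(start=("start", "min"), end=("end", "max"))
              .reset_index())
    for _, r in gene_model.iterrows():
        exon_trees.setdefault(r["chrom"], IntervalTree()).addi(
            int(r["start"]), int(r["end"]), r["gene"])
    for _, r in bodies.iterrows():
        body_trees.setdefault(r["chrom"], IntervalTree()).addi(
            int(r["start"]), int(r["end"]), r["gene"])

    regions, genes, distances = [], [], []
    for _, m in markers.iterrows():
        chrom, start, end = m["chrom"], int(m["start"]), int(m["end"])
        ex = exon_trees.get(chrom, IntervalTree()).overlap(start, end)
        body = body_trees.get(chrom, IntervalTree()).overlap(start, end)
        if ex:
            regions.append("exon")
        elif body:
            regions.append("intron")
        else:
            regions.append("intergenic")
        if body:
            mid = (start + end) // 2
            hit = min(body, key=lambda iv: abs((iv.begin + iv.end) // 2 - mid))
            genes.append(hit.data)
            distances.append(0)
        else:
            sub = bodies[bodies["chrom"] == chrom]
            if sub.empty:
                genes.append(None)
                distances.append(np.nan)
                continue
            mid = (start + end) // 2
            # signed distance to the closest gene edge
            d_start = sub["start"].to_numpy() - end
            d_end = start - sub["end"].to_numpy()
            dist = np.where(d_start > 0, d_start, -d_end)
            i = int(np.abs(dist).argmin())
            genes.append(sub.iloc[i]["gene"])
            distances.append(int(dist[i]))
    out = markers.copy()
    out["region"] = regions
    out["nearest_gene"] = genes
    out["gene_distance"] = distances
    return out


def export_gene_list(annotated: pd.DataFrame, path,
                     include_nearest: bool = True) -> list:
    """Write the deduplicated, alphabetically sorted gene list.

    When ``include_nearest`` is False only genes of exon/intron markers
    are exported.
    """
    if include_nearest:
        genes = annotated["nearest_gene"].dropna()
    else:
        genes = annotated.loc[annotated["region"] != "intergenic",
                              "nearest_gene"].dropna()
    uniq = sorted(set(genes))
    if not uniq:
        warnings.warn("gene list is empty", stacklevel=2)
    with open(path, "w") as fh:
        for g in uniq:
            fh.write(g + "\n")
    return uniq
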