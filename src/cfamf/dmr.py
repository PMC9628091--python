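"""DMR selection cascade.

The cohort is split 85:15 (stratified by group, round-half-up per group)
into training and test sets. Three full-size bootstrap subsets are drawn
with replacement from the training set, stratified within group. In each
subset, every bin with more than ``coverage_threshold`` non-missing AMF
observations is tested with Welch's unequal-variances t-test; p-values are
converted to q-values (Benjamini-Hochberg by default) and the good-minus-
poor mean differences are z-standardized across all tested bins. A bin is
a DMR in a subset when q < 0.05 and |z| > 2, labeled hypomethylated
(z < -2) or hypermethylated (z > 2). Candidates are the bins selected in
every subset that additionally rank in the top ``top_k`` of every subset's
q-ordering.

Bootstrap duplicates count as independent observations in all statistics
(plain bootstrap semantics).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cfamf.amf import AMFMatrix

_TINY = np.nextafter(0.0, 1.0)


class ScreenError(ValueError):
    pass


@dataclass
class SplitSpec:
    train_fraction: float = 0.85
    stratified: bool = True
    seed: int = 0


@dataclass
class CandidateSet:
    intersection_dmrs: list
    top_k: int
    candidates: list


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(cohort: pd.DataFrame, spec: SplitSpec) -> tuple:
    """Stratified train/test partition of sample ids.

    The per-group training count is round-half-up(train_fraction * group
    size); e.g. a 109/34 cohort at 0.85 trains on 93/29 and tests on 16/5.
    """
    rng = np.random.default_rng(spec.seed)
    train_ids, test_ids = [], []
    for g, sub in cohort.groupby("group", sort=True):
        ids = sub["sample_id"].to_numpy()
        if len(ids) < 2:
            raise ScreenError(f"group {g!r} has fewer than 2 samples")
        n_train = _round_half_up(spec.train_fraction * len(ids))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    # stable, reproducible ordering
    order = {s: i for i, s in enumerate(cohort["sample_id"])}
    return (sorted(train_ids, key=order.get), sorted(test_ids, key=order.get))


def draw_subsets(train_ids: list, cohort: pd.DataFrame, n_subsets: int = 3,
                 seed: int = 0) -> list:
    """Full-size with-replacement resamples of the training set,
    stratified within group (group composition preserved exactly).

    Each subset is a list of sample ids with duplicates; a sample drawn
    twice contributes two observations downstream.
    """
    if not train_ids:
        raise ScreenError("training set is empty")
    rng = np.random.default_rng(seed)
    groups = cohort.set_index("sample_id")["group"]
    by_group: dict[str, list] = {}
    for s in train_ids:
        by_group.setdefault(groups[s], []).append(s)
    subsets = []
    for _ in range(n_subsets):
        draw = []
        for g in sorted(by_group):
            ids = by_group[g]
            idx = rng.integers(0, len(ids), size=len(ids))
            draw.extend(ids[i] for i in idx)
        subsets.append(draw)
    return subsets


# ---------------------------------------------------------------------------
# statistics


def welch_test(values_good, values_poor):
    """Welch's unequal-variances t-test (two-sided).

    Returns (diff, t, df, p) with diff = mean(good) - mean(poor) and df by
    Welch-Satterthwaite. Degenerate zero-variance inputs do not divide by
    zero: equal means give p = 1, unequal means give a p-value floored at
    the smallest positive float.
    """
    a = np.asarray(values_good, dtype=float)
    b = np.asarray(values_poor, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ScreenError("Welch test needs >= 2 values per group")
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / len(a) + vb / len(b)
    if se2 == 0.0:
        return (diff, 0.0, float(len(a) + len(b) - 2), 1.0) if diff == 0 \
            else (diff, math.copysign(math.inf, diff),
                  float(len(a) + len(b) - 2), _TINY)
    t = diff / math.sqrt(se2)
    df = se2 ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return diff, t, df, max(float(p), _TINY)


def _welch_matrix(good: np.ndarray, poor: np.ndarray):
    """Row-wise Welch test on bins x observations blocks with NaNs."""
    def moments(x):
        n = (~np.isnan(x)).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(x, axis=1)
            v = np.nanvar(x, axis=1, ddof=1)
        return n, m, v

    n1, m1, v1 = moments(good)
    n2, m2, v2 = moments(poor)
    tested = (n1 >= 2) & (n2 >= 2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    # zero-variance degenerate rows
    degen = tested & (se2 == 0)
    t[degen & (diff == 0)] = 0.0
    t[degen & (diff != 0)] = np.sign(diff[degen & (diff != 0)]) * np.inf
    df[degen] = n1[degen] + n2[degen] - 2
    p = np.full_like(diff, np.nan)
    fin = tested & np.isfinite(t)
    p[fin] = 2.0 * stats.t.sf(np.abs(t[fin]), df[fin])
    p[tested & np.isinf(t)] = 0.0
    p[tested & (t == 0) & (se2 == 0)] = 1.0
    p[tested] = np.maximum(p[tested], _TINY)
    return tested, diff, t, df, p


def fdr_qvalues(p, method: str = "bh") -> np.ndarray:
    """Convert p-values to q-values.

    ``bh``: Benjamini-Hochberg step-up with enforced monotonicity.
    ``empirical-null``: a tail-area variant in the spirit of empirical-null
    FDR tools — the BH q-value rescaled by an estimate of the null
    proportion eta0 (twice the fraction of p-values above 0.5, capped at
    1). The exact output of density-based empirical-null estimators is not
    reproduced; this option only tempers the q-values when signal is
    abundant.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or p.min() <= 0 or p.max() > 1:
        raise ScreenError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "bh":
        return q
    if method in ("empirical-null", "fdrtool-like"):
        eta0 = min(1.0, 2.0 * float(np.mean(p > 0.5)))
        return np.minimum(q * eta0, 1.0)
    raise ScreenError(f"unknown q-value method {method!r}")


@dataclass
class SubsetStats:
    """Per-bin statistics of one bootstrap subset screen."""

    table: pd.DataFrame  # bin_id, mean_good, mean_poor, diff, z, t, df, p, q, direction
    dmr_ids: list = field(default_factory=list)
    n_tested: int = 0


def screen_subset(matrix: AMFMatrix, subset_ids: list, cohort: pd.DataFrame,
                  coverage_threshold: float = 0.90,
                  z_threshold: float = 2.0, q_threshold: float = 0.05,
                  q_method: str = "bh") -> SubsetStats:
    """Welch/FDR screen of one bootstrap subset.

    Bins are tested iff the fraction of non-missing AMF cells across the
    bootstrap observations exceeds ``coverage_threshold``. The mean
    difference is standardized across all tested bins into z; DMRs satisfy
    q < ``q_threshold`` and |z| > ``z_threshold``.
    """
    sub = matrix.subset_samples(subset_ids)
    groups = cohort.set_index("sample_id")["group"]
    glab = np.array([groups[s] for s in subset_ids])
    good = sub.values[:, glab == "good"]
    poor = sub.values[:, glab == "poor"]
    covered = (~np.isnan(sub.values)).mean(axis=1) > coverage_threshold
    tested_w, diff, t, df, p = _welch_matrix(good, poor)
    tested = covered & tested_w
    if not tested.any():
        raise ScreenError("no bin passes the coverage threshold")
    idx = np.flatnonzero(tested)
    d = diff[idx]
    sd = d.std(ddof=1)
    if sd == 0:
        raise ScreenError("mean differences are constant; cannot standardize")
    z = (d - d.mean()) / sd
    q = fdr_qvalues(p[idx], method=q_method)
    bin_ids = np.asarray(matrix.bin_ids(), dtype=object)[idx]
    direction = np.where(
        (q < q_threshold) & (z < -z_threshold), "hypo",
        np.where((q < q_threshold) & (z > z_threshold), "hyper", "none"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pd.DataFrame({
            "bin_id": bin_ids,
            "mean_good": np.nanmean(good, axis=1)[idx],
            "mean_poor": np.nanmean(poor, axis=1)[idx],
            "diff": d, "z": z, "t": t[idx], "df": df[idx], "p": p[idx],
            "q": q, "direction": direction,
        })
    dmr_ids = list(table.loc[table["direction"] != "none", "bin_id"])
    return SubsetStats(table=table, dmr_ids=dmr_ids, n_tested=len(idx))


def intersect_and_rank(subset_results: list, top_k: int = 500) -> CandidateSet:
    """Three-way DMR intersection followed by per-subset q-rank filtering.

    Within the intersection each subset independently orders by ascending
    q, ties broken by descending |z| then genomic coordinate; candidates
    are bins ranked <= ``top_k`` in every subset.
    """
    if len(subset_results) < 2:
        raise ScreenError("need >= 2 subset results to intersect")
    sets = [set(r.dmr_ids) for r in subset_results]
    inter = set.intersection(*sets)
    if not inter:
        warnings.warn("empty DMR intersection", stacklevel=2)
        return CandidateSet(intersection_dmrs=[], top_k=top_k, candidates=[])
    # deterministic genomic order of the intersection
    def coord_key(b):
        chrom, rng_ = b.rsplit(":", 1)
        return (chrom, int(rng_.split("-")[0]))

    inter_sorted = sorted(inter, key=coord_key)
    in_top = np.ones(len(inter_sorted), dtype=bool)
    for r in subset_results:
        tab = r.table.set_index("bin_id").loc[inter_sorted].copy()
        tab["abs_z"] = tab["z"].abs()
        tab["chrom"] = [coord_key(b)[0] for b in tab.index]
        tab["start"] = [coord_key(b)[1] for b in tab.index]
        ordered = tab.sort_values(
            ["q", "abs_z", "chrom", "start"],
            ascending=[True, False, True, True], kind="mergesort",
        )
        rank = pd.Series(np.arange(1, len(ordered) + 1), index=ordered.index)
        in_top &= (rank.loc[inter_sorted] <= top_k).to_numpy()
    candidates = [b for b, ok in zip(inter_sorted, in_top) if ok]
    return CandidateSet(intersection_dmrs=inter_sorted, top_k=top_k,
                        candidates=candidates)


def candidate_pca_check(matrix: AMFMatrix, candidate_ids: list,
                        train_ids: list, test_ids: list,
                        scale: bool = False) -> tuple:
    """PCA of candidate-bin AMF fitted on training samples only; test
    samples are projected with the frozen centering/scaling/rotation.

    Candidate bins with no observed training value are dropped with a
    warning; remaining missing cells are imputed with training bin means.
    Returns (train_scores, test_scores) as DataFrames.
    """
    from cfamf.unsupervised import pca_with_permutation_cutoff

    if not candidate_ids:
        raise ScreenError("candidate set is empty")
    ids = matrix.bin_ids()
    row = {b: i for i, b in enumerate(ids)}
    ridx = np.array([row[b] for b in candidate_ids])
    train = matrix.subset_bins(ridx).subset_samples(train_ids)
    test = matrix.subset_bins(ridx).subset_samples(test_ids)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        train_means = np.nanmean(train.values, axis=1)
    ok = ~np.isnan(train_means)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} candidate bins with no training "
            "observation", stacklevel=2)
        train = train.subset_bins(np.flatnonzero(ok))
        test = test.subset_bins(np.flatnonzero(ok))
        train_means = train_means[ok]

    tv = train.values.copy()
    tv[np.isnan(tv)] = np.broadcast_to(
        train_means[:, None], tv.shape)[np.isnan(tv)]
    sv = test.values.copy()
    sv[np.isnan(sv)] = np.broadcast_to(
        train_means[:, None], sv.shape)[np.isnan(sv)]

    k = min(10, len(train_ids) - 1, tv.shape[0])
    filled = AMFMatrix(bins=train.bins.copy(), samples=list(train_ids),
                       values=tv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pca = pca_with_permutation_cutoff(filled, k=k, n_perm=0, seed=0,
                                          scale=scale)
    test_scores = pd.DataFrame(
        pca.transform(sv.T), index=list(test_ids),
        columns=pca.scores.columns,
    )
    return pca.scores, test_scores
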