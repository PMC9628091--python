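"""Unsupervised cohort structure: variance screen, imputation, PCA with a
permutation-derived component cutoff, and PC-clinical correlations.

The permutation scheme shuffles each bin's values independently across
samples. This preserves every bin's marginal distribution while destroying
inter-bin correlation, so the largest variance proportion of a shuffled
table estimates the noise ceiling; a whole-column (sample-label) shuffle
would leave the covariance spectrum unchanged and provide no cutoff. The
cutoff is the maximum top-component variance proportion across
permutations, and a component is declared significant when its observed
proportion exceeds it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cfamf.amf import AMFMatrix


class DegenerateInputError(ValueError):
    pass


@dataclass
class PCAResult:
    n_components: int
    variance_proportions: np.ndarray   # per retained PC, non-increasing
    scores: pd.DataFrame               # samples x PCs
    loadings: np.ndarray               # bins x PCs
    cutoff: float                      # max permuted top-1 proportion
    significant_pcs: list              # 1-based PC indices above cutoff
    center: np.ndarray
    scale: np.ndarray | None

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project new samples (rows) with the frozen transform."""
        x = values - self.center
        if self.scale is not None:
            x = x / self.scale
        return x @ self.loadings


def variance_screen(matrix: AMFMatrix, z_threshold: float = 2.0) -> AMFMatrix:
    """Keep bins whose across-sample SD is an outlier among all bin SDs.

    SD is computed on observed (non-missing) cells only; the SD vector is
    z-standardized and bins with z > ``z_threshold`` survive, discarding
    background fluctuation bins.
    """
    if matrix.values.shape[1] < 3:
        raise DegenerateInputError("variance screen needs >= 3 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sds = np.nanstd(matrix.values, axis=1, ddof=1)
    sds = np.where(np.isnan(sds), 0.0, sds)
    spread = float(np.std(sds, ddof=1)) if len(sds) > 1 else 0.0
    if spread == 0.0:
        raise DegenerateInputError(
            "all per-bin SDs are identical; z-standardization is degenerate"
        )
    z = (sds - sds.mean()) / spread
    return matrix.subset_bins(np.flatnonzero(z > z_threshold))


def impute_group_means(matrix: AMFMatrix, cohort: pd.DataFrame) -> AMFMatrix:
    """Replace each missing cell with its bin's mean within the sample's
    group. Errors if a bin has no observed value in some group."""
    groups = cohort.set_index("sample_id").loc[matrix.samples, "group"]
    values = matrix.values.copy()
    for g in groups.unique():
        cols = np.flatnonzero((groups == g).to_numpy())
        block = values[:, cols]
        obs = ~np.isnan(block)
        if not obs.any(axis=1).all():
            bad = int(np.flatnonzero(~obs.any(axis=1))[0])
            bid = matrix.bin_ids()[bad]
            raise DegenerateInputError(
                f"bin {bid} has no observed value in group {g!r}; "
                "cannot impute"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(block, axis=1)
        block[~obs] = np.broadcast_to(means[:, None], block.shape)[~obs]
        values[:, cols] = block
    return AMFMatrix(bins=matrix.bins.copy(), samples=list(matrix.samples),
                     values=values)


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Deterministic sign convention: the largest-|loading| entry of each
    component is positive."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores


def pca_with_permutation_cutoff(matrix: AMFMatrix, k: int = 30,
                                n_perm: int = 1000, seed: int = 0,
                                scale: bool = False) -> PCAResult:
    """Centered PCA of samples over bins with a permutation noise cutoff.

    The observed matrix must be complete (impute first). For each of
    ``n_perm`` permutations every bin is independently shuffled across
    samples and the top variance proportion recomputed; the cutoff is the
    maximum across permutations.
    """
    x = matrix.values.T  # samples x bins
    n, p = x.shape
    if n < 3:
        raise DegenerateInputError("PCA needs >= 3 samples")
    if np.isnan(x).any():
        raise DegenerateInputError("PCA input must be complete; impute first")
    kmax = min(n - 1, p)
    if k > kmax:
        warnings.warn(f"k={k} truncated to {kmax}", stacklevel=2)
        k = kmax

    center = x.mean(axis=0)
    xc = x - center
    sd = None
    if scale:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total_var = float((s ** 2).sum())
    if total_var == 0:
        raise DegenerateInputError("matrix has zero total variance")
    proportions = (s[:k] ** 2) / total_var
    loadings, scores = _fix_signs(vt[:k].T.copy(), (u[:, :k] * s[:k]).copy())

    rng = np.random.default_rng(seed)
    cutoff = 0.0
    for _ in range(n_perm):
        order = np.argsort(rng.random((p, n)), axis=1)
        xp = np.take_along_axis(matrix.values, order, axis=1).T  # samples x bins
        xpc = xp - xp.mean(axis=0)
        if scale:
            psd = xpc.std(axis=0, ddof=1)
            psd[psd == 0] = 1.0
            xpc = xpc / psd
        gram = xpc @ xpc.T
        ev = np.linalg.eigvalsh(gram)
        top = float(ev[-1]) / float(np.trace(gram))
        cutoff = max(cutoff, top)

    significant = [i + 1 for i, pr in enumerate(proportions) if pr > cutoff]
    score_df = pd.DataFrame(
        scores, index=list(matrix.samples),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(
        n_components=k, variance_proportions=proportions, scores=score_df,
        loadings=loadings, cutoff=cutoff, significant_pcs=significant,
        center=center, scale=sd,
    )


def correlate_pcs(pca: PCAResult, cohort: pd.DataFrame,
                  variables: list | None = None,
                  pcs: list | None = None) -> pd.DataFrame:
    """Pearson (point-biserial for 0/1-coded binaries) and Spearman
    correlations of PC scores with clinical variables.

    Returns a tidy frame (pc, variable, pearson_r, pearson_p, spearman_rho,
    spearman_p); zero-variance variables yield missing coefficients.
    """
    meta = cohort.set_index("sample_id").loc[pca.scores.index]
    if variables is None:
        variables = [c for c in meta.columns if c != "group"]
        if "group" in meta.columns:
            variables = ["group"] + variables
    if pcs is None:
        pcs = pca.significant_pcs or list(range(1, pca.n_components + 1))
    rows = []
    for pc in pcs:
        x = pca.scores[f"PC{pc}"].to_numpy(dtype=float)
        for var in variables:
            v = meta[var]
            if v.dtype == object:
                levels = sorted(v.unique())
                if len(levels) > 2:
                    continue
                y = (v == levels[-1]).astype(float).to_numpy()
            else:
                y = v.to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0:
                rows.append((pc, var, np.nan, np.nan, np.nan, np.nan))
                continue
            pr = stats.pearsonr(x, y)
            sr = stats.spearmanr(x, y)
            rows.append((pc, var, pr.statistic, pr.pvalue,
                         sr.statistic, sr.pvalue))
    return pd.DataFrame(rows, columns=[
        "pc", "variable", "pearson_r", "pearson_p", "spearman_rho",
        "spearman_p",
    ])
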