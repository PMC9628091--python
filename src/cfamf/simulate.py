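"""Synthetic cfDNA-methylation cohort generator.

Emulates the data a two-group plasma methylation study produces, at the
per-CpG call level, so every downstream stage (binning, QC, PCA, DMR
screening, marker selection, external validation) can be exercised without
patient data.

Generative model
----------------
* The genome is two synthetic chromosomes tiled by ``bin_width`` bins.
  Most bins are CpG-dense (``cpgs_per_bin`` range, >= 5); a configurable
  fraction is sparse (< 5 CpGs) to exercise the density filter.
* Each bin b has a latent mean methylation mu_b ~ Beta(``baseline_beta``),
  concentrated near 1 with narrow spread (the typical cfDNA background).
  Both groups share mu_b in non-DMR bins.
* ``n_dmr`` dense bins are differential: in the *good* group their mean is
  lowered by ``dmr_effect`` and their across-sample spread is widened by
  ``dmr_spread`` (hypomethylation with widened distribution).
* A sample's bin-level methylation theta is drawn from a Beta distribution
  re-parameterized by (mean, sd); CpGs within a bin are conditionally
  independent given theta.
* Per-CpG read depth ~ Poisson(``depth_mean``); zero-depth CpGs are simply
  absent from the call file, which is what produces missing AMF cells.
  P(bin missing) = E[exp(-n_cpgs * depth_mean)], and
  :func:`depth_for_missing_target` inverts this to hit a requested
  missingness fraction.
* CHH records carry a per-read false-methylation probability ``chh_error``,
  so the measured conversion rate is ~ 1 - chh_error.
* Clinical covariates (age, sex, hypertension, diabetes, smoking) are drawn
  independently of group, so group-association tests on them are null.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from cfamf.io import MethylationCallSet, write_calls, write_sample_sheet


class ConfigError(ValueError):
    """A simulation parameter violates its constraints."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults mirror the study design
    (109 good vs 34 poor samples, 100-bp bins, near-1 narrow background
    methylation, a minority of hypomethylated DMRs, low read depth)."""

    n_good: int = 109
    n_poor: int = 34
    n_bins: int = 5000
    bin_width: int = 100
    cpgs_per_bin: tuple = (5, 12)        # dense-bin CpG count range, inclusive
    sparse_bin_fraction: float = 0.20    # bins with < 5 CpGs (density filter)
    n_dmr: int = 100
    baseline_beta: tuple = (50.0, 3.0)   # per-bin background mean ~ Beta(a, b)
    within_spread: float = 0.03          # across-sample sd of bin methylation
    dmr_effect: float = 0.30             # good-group mean AMF decrease in DMRs
    dmr_spread: float = 0.10             # extra good-group sd in DMR bins
    depth_mean: float = 8.0              # mean reads per CpG (Poisson)
    missing_target: float | None = None  # if set, overrides depth_mean
    n_chh: int = 2000                    # CHH positions per sample
    chh_error: float = 0.005             # per-read CHH false-methylation prob
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_good < 1 or self.n_poor < 1:
            raise ConfigError("n_good and n_poor must be >= 1")
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")
        if not 0 <= self.n_dmr < self.n_bins:
            raise ConfigError("n_dmr must satisfy 0 <= n_dmr < n_bins")
        lo, hi = self.cpgs_per_bin
        if lo < 5 or hi < lo:
            raise ConfigError("cpgs_per_bin must be an (lo>=5, hi>=lo) range")
        if hi >= self.bin_width:
            raise ConfigError("cpgs_per_bin upper bound must fit in bin_width")
        for name in ("sparse_bin_fraction", "chh_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.dmr_effect < 0:
            # dmr_effect == 0 is a legitimate pure-null configuration
            raise ConfigError("dmr_effect must be >= 0")
        if self.dmr_spread < 0 or self.within_spread <= 0:
            raise ConfigError("spreads must be positive")
        a, b = self.baseline_beta
        if a <= 0 or b <= 0:
            raise ConfigError("baseline_beta shapes must be positive")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        if self.missing_target is not None and not 0 < self.missing_target < 1:
            raise ConfigError("missing_target must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    dmr_bin_ids: list
    per_bin_group_means: pd.DataFrame  # bin_id, mean_good, mean_poor
    per_sample_conversion_rate: pd.Series


@dataclass
class SyntheticCohort:
    """Bundle of everything :func:`simulate_cohort` produces."""

    config: SimulationConfig
    calls: dict            # sample_id -> MethylationCallSet (CpG context)
    chh_calls: dict        # sample_id -> MethylationCallSet (CHH context)
    cohort: pd.DataFrame   # sample sheet
    truth: SyntheticTruth
    cpg_positions: dict    # chrom -> sorted array of reference CpG starts
    chrom_sizes: dict
    bins: pd.DataFrame     # chrom, bin_index, start, end, n_cpgs, is_dmr

    def write(self, outdir) -> None:
        """Emit the cohort as plain-text files (deterministic given seed)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, cs in self.calls.items():
            write_calls(cs, outdir / f"{sid}_CpG.bedGraph")
        for sid, cs in self.chh_calls.items():
            write_calls(cs, outdir / f"{sid}_CHH.bedGraph")
        write_sample_sheet(self.cohort, outdir / "samples.tsv")
        truth = self.truth.per_bin_group_means.copy()
        truth["is_dmr"] = truth["bin_id"].isin(self.truth.dmr_bin_ids)
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                     float_format="%.10g")
        with open(outdir / "chrom.sizes", "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        cat = pd.concat(
            [pd.DataFrame({"chrom": c, "pos": p})
             for c, p in self.cpg_positions.items()],
            ignore_index=True,
        )
        cat.to_csv(outdir / "cpg_catalog.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# beta re-parameterization


def beta_from_mean_sd(rng: np.random.Generator, mean, sd, size=None):
    """Draw Beta variates given (mean, sd); sd is clipped below the
    feasibility bound sqrt(mean * (1 - mean))."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-4, 1 - 1e-4)
    sd = np.asarray(sd, dtype=float)
    cap = 0.95 * np.sqrt(mean * (1 - mean))
    sd = np.minimum(sd, cap)
    kappa = mean * (1 - mean) / (sd ** 2) - 1.0
    return rng.beta(mean * kappa, (1 - mean) * kappa, size=size)


def expected_missing_fraction(config: SimulationConfig,
                              depth_mean: float | None = None) -> float:
    """Expected fraction of (dense bin, sample) cells with zero coverage.

    With i.i.d. Poisson(d) depth per CpG, a bin of k CpGs is uncovered with
    probability exp(-k d); the CpG count is uniform over the configured
    dense range.
    """
    d = config.depth_mean if depth_mean is None else depth_mean
    lo, hi = config.cpgs_per_bin
    ks = np.arange(lo, hi + 1)
    return float(np.mean(np.exp(-ks * d)))


def depth_for_missing_target(config: SimulationConfig,
                             target: float) -> float:
    """Invert :func:`expected_missing_fraction` for ``depth_mean``."""
    if not 0 < target < 1:
        raise ConfigError("missing_target must lie in (0, 1)")
    f = lambda d: expected_missing_fraction(config, d) - target
    return float(brentq(f, 1e-9, 60.0))


# ---------------------------------------------------------------------------
# cohort simulation


def _layout_genome(config: SimulationConfig, rng: np.random.Generator):
    """Place bins, CpG positions and DMR labels on two chromosomes."""
    n = config.n_bins
    n_a = (n + 1) // 2
    per_chrom = {"chrA": n_a, "chrB": n - n_a}
    chrom_sizes = {c: k * config.bin_width for c, k in per_chrom.items() if k}
    chroms = np.concatenate([
        np.full(k, c, dtype=object) for c, k in per_chrom.items() if k
    ])
    bin_index = np.concatenate([
        np.arange(k) for k in per_chrom.values() if k
    ])
    start = bin_index * config.bin_width
    end = start + config.bin_width

    n_sparse = int(round(config.sparse_bin_fraction * n))
    sparse = np.zeros(n, dtype=bool)
    if n_sparse:
        sparse[rng.choice(n, size=n_sparse, replace=False)] = True
    lo, hi = config.cpgs_per_bin
    n_cpgs = rng.integers(lo, hi + 1, size=n)
    if n_sparse:
        n_cpgs[sparse] = rng.integers(1, 5, size=n_sparse)

    dense_idx = np.flatnonzero(~sparse)
    if config.n_dmr > len(dense_idx):
        raise ConfigError("n_dmr exceeds the number of CpG-dense bins")
    is_dmr = np.zeros(n, dtype=bool)
    if config.n_dmr:
        is_dmr[rng.choice(dense_idx, size=config.n_dmr, replace=False)] = True

    bins = pd.DataFrame({
        "chrom": chroms, "bin_index": bin_index, "start": start, "end": end,
        "n_cpgs": n_cpgs, "is_dmr": is_dmr,
    })

    # CpG offsets: uniform without collision inside each bin
    offsets = [np.sort(rng.choice(config.bin_width, size=k, replace=False))
               for k in n_cpgs]
    cpg_chrom = np.repeat(chroms, n_cpgs)
    cpg_pos = np.concatenate([
        s + off for s, off in zip(start, offsets)
    ]).astype(np.int64)
    cpg_bin_row = np.repeat(np.arange(n), n_cpgs)
    cpg_positions = {
        c: cpg_pos[cpg_chrom == c] for c in chrom_sizes
    }
    return bins, chrom_sizes, cpg_positions, cpg_chrom, cpg_pos, cpg_bin_row


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full two-group cohort of methylation call sets.

    Deterministic given ``config.seed`` (byte-identical files on re-run).
    """
    rng = np.random.default_rng(config.seed)
    depth_mean = config.depth_mean
    if config.missing_target is not None:
        depth_mean = depth_for_missing_target(config, config.missing_target)

    (bins, chrom_sizes, cpg_positions, cpg_chrom, cpg_pos,
     cpg_bin_row) = _layout_genome(config, rng)
    n_bins = len(bins)
    n_cpg_total = len(cpg_pos)

    mu = rng.beta(*config.baseline_beta, size=n_bins)
    mean_poor = mu
    mean_good = mu.copy()
    is_dmr = bins["is_dmr"].to_numpy()
    mean_good[is_dmr] = np.clip(mu[is_dmr] - config.dmr_effect, 0.02, 0.98)
    sd_good = np.where(is_dmr, config.within_spread + config.dmr_spread,
                       config.within_spread)
    sd_poor = np.full(n_bins, config.within_spread)

    groups = ["good"] * config.n_good + ["poor"] * config.n_poor
    sample_ids = [f"S{i + 1:04d}" for i in range(len(groups))]

    calls: dict = {}
    chh_calls: dict = {}
    for sid, group in zip(sample_ids, groups):
        mean_s = mean_good if group == "good" else mean_poor
        sd_s = sd_good if group == "good" else sd_poor
        theta_bin = beta_from_mean_sd(rng, mean_s, sd_s)
        depth = rng.poisson(depth_mean, size=n_cpg_total)
        theta_cpg = theta_bin[cpg_bin_row]
        n_meth = rng.binomial(depth, theta_cpg)
        keep = depth > 0
        df = pd.DataFrame({
            "chrom": cpg_chrom[keep],
            "pos": cpg_pos[keep],
            "n_methylated": n_meth[keep],
            "n_total": depth[keep],
            "context": "CpG",
        })
        calls[sid] = MethylationCallSet(sid, df)
        chh_calls[sid] = _simulate_chh(rng, sid, config, chrom_sizes,
                                       depth_mean)

    cohort = _simulate_covariates(rng, sample_ids, groups)
    bin_ids = [f"{c}:{s}-{e}" for c, s, e in
               zip(bins["chrom"], bins["start"], bins["end"])]
    truth = SyntheticTruth(
        dmr_bin_ids=[b for b, d in zip(bin_ids, is_dmr) if d],
        per_bin_group_means=pd.DataFrame({
            "bin_id": bin_ids, "mean_good": mean_good, "mean_poor": mean_poor,
        }),
        per_sample_conversion_rate=pd.Series(
            1.0 - config.chh_error, index=sample_ids, name="conversion_rate"
        ),
    )
    return SyntheticCohort(
        config=config, calls=calls, chh_calls=chh_calls, cohort=cohort,
        truth=truth, cpg_positions=cpg_positions, chrom_sizes=chrom_sizes,
        bins=bins,
    )


def _simulate_chh(rng, sid, config, chrom_sizes, depth_mean):
    """CHH records: near-zero methylation, rate = chh_error per read."""
    chrom = next(iter(chrom_sizes))
    size = chrom_sizes[chrom]
    n = min(config.n_chh, size)
    pos = np.sort(rng.choice(size, size=n, replace=False))
    depth = rng.poisson(depth_mean, size=n)
    n_meth = rng.binomial(depth, config.chh_error)
    keep = depth > 0
    df = pd.DataFrame({
        "chrom": chrom, "pos": pos[keep],
        "n_methylated": n_meth[keep], "n_total": depth[keep],
        "context": "CHH",
    })
    return MethylationCallSet(sid, df)


def _simulate_covariates(rng, sample_ids, groups) -> pd.DataFrame:
    """Clinical covariates independent of group by construction.

    Marginals follow typical chronic-coronary-occlusion cohorts (age ~ 58,
    ~71% male, ~48% hypertensive, ~24% diabetic, ~13% smokers).
    """
    n = len(sample_ids)
    return pd.DataFrame({
        "sample_id": sample_ids,
        "group": groups,
        "age": np.round(rng.normal(58.0, 10.5, size=n), 1),
        "sex": rng.binomial(1, 0.71, size=n),
        "hypertension": rng.binomial(1, 0.48, size=n),
        "diabetes": rng.binomial(1, 0.24, size=n),
        "smoking": rng.binomial(1, 0.13, size=n),
    })


# ---------------------------------------------------------------------------
# auxiliary tracks: blacklist, gene model, healthy validation cohort


def simulate_blacklist(cohort: SyntheticCohort, fraction: float = 0.01,
                       seed: int | None = None) -> pd.DataFrame:
    """Bin-aligned artifact regions covering ~``fraction`` of non-DMR bins.

    DMR bins are never blacklisted, so planted signal survives masking.
    """
    rng = np.random.default_rng(
        cohort.config.seed + 104729 if seed is None else seed
    )
    bins = cohort.bins
    candidates = np.flatnonzero(~bins["is_dmr"].to_numpy())
    k = int(round(fraction * len(bins)))
    chosen = np.sort(rng.choice(candidates, size=min(k, len(candidates)),
                                replace=False))
    sub = bins.iloc[chosen]
    return pd.DataFrame({
        "chrom": sub["chrom"].to_numpy(),
        "start": sub["start"].to_numpy(),
        "end": sub["end"].to_numpy(),
        "name": "blacklist",
    })


def simulate_gene_model(chrom_sizes: dict, n_genes: int = 40,
                        seed: int = 0) -> pd.DataFrame:
    """A toy exon table (chrom, start, end, gene, strand), BED6-compatible.

    Genes are non-overlapping; each carries 2-5 exons within its body, so
    markers can fall in exon, intron or intergenic space.
    """
    rng = np.random.default_rng(seed)
    rows = []
    chroms = list(chrom_sizes)
    per_chrom = max(1, n_genes // len(chroms))
    g = 0
    for chrom in chroms:
        size = chrom_sizes[chrom]
        slot = size // per_chrom
        for i in range(per_chrom):
            g += 1
            gene = f"GENE{g:03d}"
            lo, hi = i * slot, (i + 1) * slot
            body_len = int(rng.integers(slot // 4, max(slot // 2, slot // 4 + 1)))
            body_start = int(rng.integers(lo, max(hi - body_len, lo + 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(
                np.arange(1, body_len), size=2 * n_exons, replace=False))
            for j in range(n_exons):
                rows.append((chrom, body_start + int(cuts[2 * j]),
                             body_start + int(cuts[2 * j + 1]), gene, strand))
    return pd.DataFrame(rows,
                        columns=["chrom", "start", "end", "gene", "strand"])


def write_gene_model_bed(genes: pd.DataFrame, path) -> None:
    out = genes.copy()
    out["score"] = 0
    out[["chrom", "start", "end", "gene", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_gene_model_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene", "score",
                            "strand"])
    if df[["start", "end"]].isna().any().any():
        raise ValueError(f"malformed gene model BED: {path}")
    return df.drop(columns=["score"])


def simulate_healthy_bedset(config: SimulationConfig,
                            marker_regions: pd.DataFrame,
                            n_samples: int = 12,
                            cpgs_per_region: int = 8,
                            healthy_mean: float | None = None,
                            region_means=None,
                            spread: float | None = None,
                            seed: int | None = None) -> list:
    """Per-sample CpG call sets for an external healthy cohort.

    Healthy cfDNA methylation over the marker regions follows the near-1
    narrow background (poor-group) model — marker hypomethylation is
    condition-specific, so healthy donors keep high methylation there.
    ``region_means`` (one per marker region) pins each region to its
    background mean; otherwise the ``baseline_beta`` mean (or
    ``healthy_mean``) is used everywhere. ``spread`` defaults to
    ``config.within_spread``; healthy reference cohorts are typically
    tighter than patient cohorts, so callers may pass a smaller value.
    """
    if len(marker_regions) == 0:
        raise ConfigError("marker_regions must be non-empty")
    rng = np.random.default_rng(config.seed + 65537 if seed is None else seed)
    a, b = config.baseline_beta
    base_mean = a / (a + b) if healthy_mean is None else healthy_mean
    if region_means is None:
        region_means = np.full(len(marker_regions), base_mean)
    else:
        region_means = np.asarray(region_means, dtype=float)
        if len(region_means) != len(marker_regions):
            raise ConfigError("region_means must match marker_regions")
    if spread is None:
        spread = config.within_spread
    regions = marker_regions.reset_index(drop=True)
    # fixed CpG layout shared by all samples, like a reference genome
    layouts = []
    for _, r in regions.iterrows():
        width = int(r["end"]) - int(r["start"])
        k = min(cpgs_per_region, width)
        off = np.sort(rng.choice(width, size=k, replace=False))
        layouts.append((str(r["chrom"]), int(r["start"]) + off))
    out = []
    for i in range(n_samples):
        sid = f"H{i + 1:03d}"
        frames = []
        for (chrom, pos), mean_r in zip(layouts, region_means):
            theta = beta_from_mean_sd(rng, mean_r, spread)
            depth = rng.poisson(config.depth_mean, size=len(pos))
            n_meth = rng.binomial(depth, theta)
            keep = depth > 0
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos[keep],
                "n_methylated": n_meth[keep], "n_total": depth[keep],
                "context": "CpG",
            }))
        df = (pd.concat(frames, ignore_index=True)
              .sort_values(["chrom", "pos"], kind="mergesort")
              .reset_index(drop=True))
        out.append(MethylationCallSet(sid, df))
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["cpgs_per_bin"] = list(config.cpgs_per_bin)
    d["baseline_beta"] = list(config.baseline_beta)
    return d
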