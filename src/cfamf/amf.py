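"""Sample QC, genome binning and AMF matrix construction.

The genome is tiled into fixed-width bins (default 100 bp). For each sample
and each CpG-dense bin (>= ``min_cpgs`` reference CpGs) the average
methylation fraction (AMF) is

    AMF = (sum of methylated read observations) / (sum of all read
          observations) over reference CpG positions in the bin,

i.e. a depth-weighted fraction over read observations, not an average over
distinct CpGs. A bin with no covered CpG in a sample is missing for that
sample; bins missing in too large a fraction of the cohort are dropped when
the matrix is assembled.

Sample-level QC gates: enzymatic conversion rate (estimated from residual
CHH methylation) must exceed 0.99, and the median over eligible bins of the
per-bin average CpG depth must be >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cfamf.io import MethylationCallSet, ValidationError


class QCError(ValueError):
    """A sample cannot be rated (e.g. no CHH coverage at all)."""


@dataclass(frozen=True)
class BinScheme:
    """Fixed-width tiling of the genome into half-open bins.

    Bins tile each chromosome as [k*w, (k+1)*w); the last bin is truncated
    at the chromosome end. A bin is *eligible* when it contains at least
    ``min_cpgs`` reference CpGs.
    """

    chrom_sizes: Mapping[str, int]
    bin_width: int = 100
    min_cpgs: int = 5

    def bin_of(self, pos: np.ndarray) -> np.ndarray:
        return np.asarray(pos) // self.bin_width

    def bin_id(self, chrom: str, index: int) -> str:
        start = index * self.bin_width
        end = min(start + self.bin_width, self.chrom_sizes[chrom])
        return f"{chrom}:{start}-{end}"


@dataclass
class AMFMatrix:
    """Bins x samples matrix of average methylation fractions.

    ``bins`` carries (chrom, start, end, n_cpgs) per retained bin in row
    order; ``values`` holds AMF in [0, 1] with NaN for missing cells.
    """

    bins: pd.DataFrame
    samples: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bins), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.bins)} bins x {len(self.samples)} samples"
            )
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("AMF values must lie in [0, 1]")

    @property
    def shape(self):
        return self.values.shape

    def bin_ids(self) -> list:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.bins["chrom"], self.bins["start"],
                               self.bins["end"])
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.bin_ids(),
                            columns=self.samples)

    def subset_bins(self, row_indices) -> "AMFMatrix":
        idx = np.asarray(row_indices)
        return AMFMatrix(
            bins=self.bins.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            values=self.values[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "AMFMatrix":
        """Column subset; repeated ids yield repeated columns (bootstrap)."""
        col = {s: i for i, s in enumerate(self.samples)}
        idx = [col[s] for s in sample_ids]
        return AMFMatrix(
            bins=self.bins.copy(),
            samples=list(sample_ids),
            values=self.values[:, idx],
        )


@dataclass
class SampleQCReport:
    sample_id: str
    conversion_rate: float
    depth_summary: float  # median over eligible bins of per-bin average depth
    pass_qc: bool = field(init=False)

    # gate values mirror the study protocol: conversion strictly above 99%,
    # median average depth at least 3
    CONVERSION_MIN = 0.99
    DEPTH_MIN = 3.0

    def __post_init__(self) -> None:
        self.pass_qc = (
            self.conversion_rate > self.CONVERSION_MIN
            and self.depth_summary >= self.DEPTH_MIN
        )


def conversion_rate(chh_calls: MethylationCallSet) -> float:
    """Conversion rate from residual CHH methylation.

    CHH cytosines are essentially unmethylated in human DNA, so any
    methylated CHH read observation reflects conversion failure:
    rate = 1 - (methylated CHH observations / all CHH observations).
    """
    df = chh_calls.records
    df = df[df["context"] == "CHH"]
    total = int(df["n_total"].sum())
    if total == 0:
        raise QCError(
            f"sample {chh_calls.sample_id}: no CHH coverage, conversion "
            "rate cannot be estimated"
        )
    return 1.0 - float(df["n_methylated"].sum()) / total


def count_cpgs_per_bin(cpg_positions: Mapping[str, np.ndarray],
                       scheme: BinScheme) -> pd.DataFrame:
    """Count reference CpGs in every bin that contains at least one.

    ``cpg_positions`` maps chrom -> sorted array of CpG start coordinates.
    Returns a frame (chrom, bin_index, start, end, n_cpgs) sorted by
    (chrom, bin_index).
    """
    frames = []
    for chrom in sorted(cpg_positions):
        pos = np.asarray(cpg_positions[chrom], dtype=np.int64)
        if pos.size == 0:
            continue
        size = scheme.chrom_sizes.get(chrom)
        if size is None:
            raise ValidationError(f"chromosome {chrom} absent from chrom sizes")
        if pos.max() >= size:
            raise ValidationError(
                f"CpG position {int(pos.max())} beyond {chrom} size {size}"
            )
        bins = scheme.bin_of(pos)
        uniq, counts = np.unique(bins, return_counts=True)
        start = uniq * scheme.bin_width
        end = np.minimum(start + scheme.bin_width, size)
        frames.append(pd.DataFrame({
            "chrom": chrom, "bin_index": uniq, "start": start, "end": end,
            "n_cpgs": counts,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "bin_index", "start", "end", "n_cpgs"]
        )
    return pd.concat(frames, ignore_index=True)


def eligible_bins(cpg_positions: Mapping[str, np.ndarray],
                  scheme: BinScheme) -> pd.DataFrame:
    """Bins with at least ``scheme.min_cpgs`` reference CpGs."""
    counts = count_cpgs_per_bin(cpg_positions, scheme)
    return counts[counts["n_cpgs"] >= scheme.min_cpgs].reset_index(drop=True)


def _per_bin_sums(calls: MethylationCallSet, scheme: BinScheme,
                  bins: pd.DataFrame):
    """Sum methylated / total observations of a sample into eligible bins.

    Returns (meth_sum, total_sum, covered_cpgs) aligned with ``bins`` rows.
    """
    meth = np.zeros(len(bins))
    total = np.zeros(len(bins))
    covered = np.zeros(len(bins))
    bin_chrom = bins["chrom"].to_numpy()
    bin_index = bins["bin_index"].to_numpy()
    df = calls.records
    for chrom, sub in df.groupby("chrom", sort=False):
        rows_c = np.flatnonzero(bin_chrom == chrom)
        if rows_c.size == 0:
            continue
        cbins = bin_index[rows_c]  # sorted ascending within a chromosome
        bidx = scheme.bin_of(sub["pos"].to_numpy())
        j = np.searchsorted(cbins, bidx)
        keep = (j < len(cbins))
        keep[keep] &= cbins[j[keep]] == bidx[keep]
        rows = rows_c[j[keep]]
        np.add.at(meth, rows, sub["n_methylated"].to_numpy()[keep])
        np.add.at(total, rows, sub["n_total"].to_numpy()[keep])
        np.add.at(covered, rows, 1)
    return meth, total, covered


def compute_amf(calls: MethylationCallSet, scheme: BinScheme,
                bins: pd.DataFrame) -> np.ndarray:
    """Per-bin AMF vector for one sample over the eligible ``bins`` frame.

    NaN where the bin has no covered CpG. Calls must already be masked and
    restricted to CpG context.
    """
    meth, total, _ = _per_bin_sums(calls, scheme, bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        amf = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    return amf


def sample_qc(cpg_calls: MethylationCallSet, chh_calls: MethylationCallSet,
              scheme: BinScheme, bins: pd.DataFrame) -> SampleQCReport:
    """Rate one sample: conversion rate and median per-bin average depth.

    The depth summary is the median, over eligible bins with any coverage,
    of (total read observations in bin / covered CpGs in bin).
    """
    rate = conversion_rate(chh_calls)
    _, total, covered = _per_bin_sums(cpg_calls, scheme, bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg_depth = np.where(covered > 0, total / np.maximum(covered, 1), np.nan)
    if np.all(np.isnan(avg_depth)):
        depth_summary = 0.0
    else:
        depth_summary = float(np.nanmedian(avg_depth))
    return SampleQCReport(cpg_calls.sample_id, rate, depth_summary)


def assemble_matrix(amf_vectors: Mapping[str, np.ndarray],
                    bins: pd.DataFrame,
                    qc: Mapping[str, SampleQCReport] | None = None,
                    max_null_fraction: float = 0.10) -> tuple:
    """Stack per-sample AMF vectors into a cohort matrix and filter bins.

    Samples failing QC are dropped. A bin is retained iff the fraction of
    missing cells across retained samples is strictly below
    ``max_null_fraction``.

    Returns (AMFMatrix, report dict with dropped-sample and bin counts).
    """
    samples = list(amf_vectors)
    if qc is not None:
        passing = [s for s in samples if qc[s].pass_qc]
    else:
        passing = samples
    if len(passing) < 2:
        raise QCError("fewer than 2 samples pass QC; cannot assemble matrix")
    values = np.column_stack([amf_vectors[s] for s in passing])
    null_frac = np.isnan(values).mean(axis=1)
    keep = null_frac < max_null_fraction
    matrix = AMFMatrix(
        bins=bins.loc[keep, ["chrom", "start", "end", "n_cpgs"]]
                 .reset_index(drop=True),
        samples=passing,
        values=values[keep],
    )
    report = {
        "n_samples_in": len(samples),
        "n_samples_pass_qc": len(passing),
        "n_samples_dropped": len(samples) - len(passing),
        "n_bins_in": int(len(bins)),
        "n_bins_retained": int(keep.sum()),
        "n_bins_dropped": int((~keep).sum()),
    }
    return matrix, report
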