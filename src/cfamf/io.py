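"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: 0-based half-open everywhere. Methylation call files
follow the MethylDackel bedGraph dialect — six tab-separated columns
(chrom, start, end, methylation percentage, count methylated,
count unmethylated) with one file per sample per cytosine context.
Masks are plain BED3; the AMF table is TSV with ``chrom:start-end`` row
keys, an ``n_cpgs`` column and one column per sample, missing cells
serialized as ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "n_methylated", "n_total", "context"]
VALID_CONTEXTS = frozenset({"CpG", "CHH", "CHG"})


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class ValidationError(ValueError):
    """Input parsed but violates a contract (counts, coordinates, keys)."""


@dataclass
class MethylationCallSet:
    """Per-sample per-cytosine methylation counts.

    ``records`` holds one row per (chrom, pos, context) with the number of
    methylated read observations and the total read observations at that
    position. Rows are sorted by (chrom, pos); zero-coverage positions are
    never stored.
    """

    sample_id: str
    records: pd.DataFrame  # columns: chrom, pos, n_methylated, n_total, context

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"call table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.records)

    def restrict(self, context: str) -> "MethylationCallSet":
        """Return the subset of records in a single cytosine context."""
        sub = self.records[self.records["context"] == context]
        return MethylationCallSet(self.sample_id, sub.reset_index(drop=True))

    def total_depth(self) -> int:
        return int(self.records["n_total"].sum())


@dataclass
class RegionMask:
    """A sorted, merged set of half-open genomic intervals.

    ``intervals`` maps chrom -> (starts, ends) as parallel sorted arrays
    with no overlapping or adjacent intervals.
    """

    intervals: dict = field(default_factory=dict)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple]) -> "RegionMask":
        by_chrom: dict[str, list] = {}
        for chrom, start, end in tuples:
            start, end = int(start), int(end)
            if start >= end:
                raise ValidationError(
                    f"mask interval {chrom}:{start}-{end} has start >= end"
                )
            by_chrom.setdefault(str(chrom), []).append((start, end))
        merged = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts, ends = [], []
            for s, e in ivs:
                if ends and s <= ends[-1]:  # overlap or adjacency: coalesce
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            merged[chrom] = (np.asarray(starts, dtype=np.int64),
                             np.asarray(ends, dtype=np.int64))
        return cls(merged)

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self.intervals.values())

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorized membership test for positions on one chromosome."""
        pos = np.asarray(pos)
        if chrom not in self.intervals:
            return np.zeros(pos.shape, dtype=bool)
        starts, ends = self.intervals[chrom]
        # position is inside the interval whose start is the rightmost <= pos
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = idx >= 0
        inside[inside] &= pos[inside] < ends[idx[inside]]
        return inside


def read_calls(path, context_filter: str | None = None,
               context: str = "CpG") -> MethylationCallSet:
    """Read a MethylDackel-style 6-column bedGraph of methylation calls.

    Counts are reconstructed as (count_methylated, count_methylated +
    count_unmethylated); the percentage column is ignored. Zero-coverage
    records are dropped; duplicate (chrom, pos) records raise.

    Parameters
    ----------
    path : file path
    context_filter : optional context to keep (alias for ``context``)
    context : cytosine context label to assign to the records
    """
    path = Path(path)
    if context_filter is not None:
        context = context_filter
    if context not in VALID_CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            chrom, start, end, _pct, n_meth, n_unmeth = parts
            try:
                start_i = int(start)
                int(end)
                n_meth_i = int(n_meth)
                n_unmeth_i = int(n_unmeth)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            if n_meth_i < 0 or n_unmeth_i < 0:
                raise ValidationError(
                    f"{path.name}:{lineno}: negative count at {chrom}:{start}"
                )
            total = n_meth_i + n_unmeth_i
            if total == 0:
                continue
            rows.append((chrom, start_i, n_meth_i, total))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "n_methylated", "n_total"])
    df["context"] = context
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValidationError(
            f"{path.name}: duplicate record at {first['chrom']}:{first['pos']}"
        )
    return MethylationCallSet(sample_id=path.stem, records=df)


def write_calls(calls: MethylationCallSet, path) -> None:
    """Write calls back to the 6-column bedGraph dialect (deterministic)."""
    df = calls.records
    with open(path, "w") as fh:
        for chrom, pos, n_meth, n_total in zip(
            df["chrom"], df["pos"], df["n_methylated"], df["n_total"]
        ):
            pct = 100.0 * n_meth / n_total
            fh.write(
                f"{chrom}\t{pos}\t{pos + 1}\t{pct:.2f}\t{n_meth}\t{n_total - n_meth}\n"
            )


def read_mask(path) -> RegionMask:
    """Read a BED3+ file into a merged :class:`RegionMask`."""
    tuples = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >= 3 BED fields")
            try:
                tuples.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    return RegionMask.from_tuples(tuples)


def apply_mask(calls: MethylationCallSet, mask: RegionMask) -> MethylationCallSet:
    """Drop call records whose position falls inside any mask interval."""
    if len(mask) == 0:
        return calls
    df = calls.records
    drop = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        drop[sub.index] = mask.contains(str(chrom), sub["pos"].to_numpy())
    return MethylationCallSet(calls.sample_id, df[~drop].reset_index(drop=True))


# ---------------------------------------------------------------------------
# AMF table round-trip


def write_amf_table(matrix, path) -> None:
    """Serialize an :class:`cfamf.amf.AMFMatrix` to TSV.

    Row key is ``chrom:start-end``; first data column is the reference CpG
    count of the bin; missing AMF cells are written as ``NA``.
    """
    if matrix.values.shape[0] == 0 or matrix.values.shape[1] == 0:
        raise ValidationError("refusing to write an empty AMF matrix")
    df = pd.DataFrame(matrix.values, index=matrix.bin_ids(),
                      columns=matrix.samples)
    df.insert(0, "n_cpgs", matrix.bins["n_cpgs"].to_numpy())
    df.index.name = "bin"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_amf_table(path, expected_samples: Sequence[str] | None = None):
    """Read an AMF table written by :func:`write_amf_table`.

    If ``expected_samples`` is given, the on-disk column order must match it
    exactly (a permuted layout is rejected rather than silently reordered).
    """
    from cfamf.amf import AMFMatrix  # deferred to avoid an import cycle

    df = pd.read_csv(path, sep="\t", index_col="bin", na_values=["NA"])
    if "n_cpgs" not in df.columns:
        raise ValidationError("AMF table lacks the n_cpgs column")
    samples = [c for c in df.columns if c != "n_cpgs"]
    if not samples or df.shape[0] == 0:
        raise ValidationError("AMF table is empty")
    if expected_samples is not None and list(expected_samples) != samples:
        raise ValidationError(
            "sample columns on disk do not match the declared order"
        )
    bins = parse_bin_ids(df.index)
    bins["n_cpgs"] = df["n_cpgs"].to_numpy(dtype=np.int64)
    return AMFMatrix(bins=bins, samples=list(samples),
                     values=df[samples].to_numpy(dtype=float))


def parse_bin_ids(ids: Iterable[str]) -> pd.DataFrame:
    """Parse ``chrom:start-end`` identifiers into a bins frame."""
    chroms, starts, ends = [], [], []
    for b in ids:
        chrom, rng = b.rsplit(":", 1)
        s, e = rng.split("-")
        chroms.append(chrom)
        starts.append(int(s))
        ends.append(int(e))
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


# ---------------------------------------------------------------------------
# Sample sheet

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "age", "sex", "hypertension",
                        "diabetes", "smoking"]


def write_sample_sheet(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the cohort sample sheet (TSV with a header row).

    Requires unique sample ids and exactly two group levels.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValidationError("sample sheet needs sample_id and group columns")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValidationError(
            f"group must take exactly two levels, found {levels}"
        )
    return df


def read_bed_regions(path) -> pd.DataFrame:
    """Read a BED3+ file of (named) regions, preserving order."""
    rows = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >= 3 BED fields")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed_regions(regions: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    if "name" in regions.columns:
        cols.append("name")
    regions[cols].to_csv(path, sep="\t", header=False, index=False)
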