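"""External validation of selected markers against healthy cfDNA.

Marker-interval AMF is recomputed from external per-CpG bed files with the
same depth-weighted definition used cohort-wide, low-coverage external
samples are excluded, and the healthy AMF distribution per marker is
compared with the study groups. A marker's healthy distribution is called
"stringent" when its IQR is no wider than the poor-group IQR and its
median is not materially below the poor-group median — an explicit
reporting heuristic for "similar to or tighter than the high-methylation
group", not an inferential claim.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from cfamf.io import MethylationCallSet


class ValidationInputError(ValueError):
    pass


def amf_over_regions(calls: MethylationCallSet,
                     regions: pd.DataFrame) -> pd.Series:
    """Depth-weighted AMF of one sample over each half-open region.

    ``regions`` needs columns (chrom, start, end) and optionally ``name``;
    a region with no covered CpG yields NaN (missing, never zero).
    """
    names = regions["name"] if "name" in regions.columns else [
        f"{c}:{s}-{e}" for c, s, e in
        zip(regions["chrom"], regions["start"], regions["end"])
    ]
    out = np.full(len(regions), np.nan)
    df = calls.records
    for i, (_, r) in enumerate(regions.iterrows()):
        sub = df[(df["chrom"] == r["chrom"]) & (df["pos"] >= r["start"])
                 & (df["pos"] < r["end"])]
        total = int(sub["n_total"].sum())
        if total > 0:
            out[i] = float(sub["n_methylated"].sum()) / total
    return pd.Series(out, index=list(names), name=calls.sample_id)


def exclude_low_coverage_samples(callsets: list, regions: pd.DataFrame,
                                 min_covered_fraction: float = 0.5) -> tuple:
    """Drop external samples with too little marker coverage.

    A sample is retained when it has at least one covered CpG in at least
    ``min_covered_fraction`` of the marker regions. Returns
    (retained callsets, report frame sorted by sample id).
    """
    if not callsets:
        raise ValidationInputError("no external samples given")
    rows = []
    retained = []
    for cs in sorted(callsets, key=lambda c: c.sample_id):
        amf = amf_over_regions(cs, regions)
        frac = float((~amf.isna()).mean())
        keep = frac >= min_covered_fraction
        rows.append({"sample_id": cs.sample_id,
                     "covered_region_fraction": frac, "retained": keep})
        if keep:
            retained.append(cs)
    report = pd.DataFrame(rows)
    if not retained:
        raise ValidationInputError("all external samples excluded for low coverage")
    return retained, report


def compare_distributions(study_amf: pd.DataFrame, study_groups: pd.Series,
                          external_amf: pd.DataFrame,
                          tolerance: float = 0.05) -> pd.DataFrame:
    """Per-region comparison of external vs study AMF distributions.

    Parameters
    ----------
    study_amf : regions x study samples AMF frame
    study_groups : sample -> 'good' / 'poor'
    external_amf : regions x external samples AMF frame

    Returns one row per region with per-cohort n/median/IQR/min/max, a
    two-sided Mann-Whitney p (external vs good group), and the stringency
    indicator: external IQR <= poor IQR + ``tolerance`` and external median
    >= poor median - ``tolerance``. The tolerance absorbs read-count
    quantization (a saturated near-1 group can have an exactly-zero IQR).
    Regions uncovered in the external cohort are flagged and excluded from
    the test.
    """
    rows = []
    for region in study_amf.index:
        rec = {"region": region}
        ext = external_amf.loc[region].dropna() \
            if region in external_amf.index else pd.Series(dtype=float)
        cohorts = {
            "good": study_amf.loc[region,
                                  study_groups[study_groups == "good"].index]
            .dropna(),
            "poor": study_amf.loc[region,
                                  study_groups[study_groups == "poor"].index]
            .dropna(),
            "external": ext,
        }
        for name, v in cohorts.items():
            rec[f"n_{name}"] = int(len(v))
            if len(v):
                q1, q3 = np.percentile(v, [25, 75])
                rec[f"median_{name}"] = float(np.median(v))
                rec[f"iqr_{name}"] = float(q3 - q1)
                rec[f"min_{name}"] = float(v.min())
                rec[f"max_{name}"] = float(v.max())
            else:
                for stat_ in ("median", "iqr", "min", "max"):
                    rec[f"{stat_}_{name}"] = np.nan
        covered = len(ext) >= 2 and len(cohorts["good"]) >= 2
        rec["covered"] = bool(covered)
        if covered:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mw = stats.mannwhitneyu(ext, cohorts["good"],
                                        alternative="two-sided")
            rec["mannwhitney_p"] = float(mw.pvalue)
            rec["stringent"] = bool(
                rec["iqr_external"] <= rec["iqr_poor"] + tolerance
                and rec["median_external"]
                >= rec["median_poor"] - tolerance
            )
        else:
            rec["mannwhitney_p"] = np.nan
            rec["stringent"] = None
        rows.append(rec)
    return pd.DataFrame(rows)
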