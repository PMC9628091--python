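"""Cohort characteristics tables and group-association checks.

Reproduces the arithmetic of a clinical characteristics table (prevalence
percentages from counts) and tests whether covariates are associated with
the outcome group — Welch's t-test for continuous variables, Fisher's
exact test for binaries. On the synthetic cohort these associations are
null by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def prevalence_percent(count: int, total: int, ndigits: int = 1) -> float:
    """Prevalence as a percentage rounded half-up to ``ndigits``."""
    if total <= 0:
        raise ValueError("total must be positive")
    scale = 10 ** ndigits
    return float(np.floor(100.0 * count / total * scale + 0.5) / scale)


def characteristics_table(cohort: pd.DataFrame,
                          group_col: str = "group") -> pd.DataFrame:
    """Per-variable summary: mean +/- SD for continuous covariates,
    count (percent) for binaries, overall and per group."""
    groups = sorted(cohort[group_col].unique())
    rows = []
    for var in cohort.columns:
        if var in ("sample_id", group_col):
            continue
        v = cohort[var]
        binary = set(pd.unique(v.dropna())) <= {0, 1}
        rec = {"variable": var, "kind": "binary" if binary else "continuous"}
        frames = [("total", cohort)] + [
            (g, cohort[cohort[group_col] == g]) for g in groups
        ]
        for label, sub in frames:
            x = sub[var].dropna()
            if binary:
                rec[f"{label}_count"] = int(x.sum())
                rec[f"{label}_percent"] = prevalence_percent(
                    int(x.sum()), len(x))
            else:
                rec[f"{label}_mean"] = float(x.mean())
                rec[f"{label}_sd"] = float(x.std(ddof=1))
        rows.append(rec)
    return pd.DataFrame(rows)


def group_association_tests(cohort: pd.DataFrame,
                            group_col: str = "group") -> pd.DataFrame:
    """Association p-value of every covariate with the binary group."""
    groups = sorted(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValueError("group must have exactly two levels")
    a = cohort[cohort[group_col] == groups[0]]
    b = cohort[cohort[group_col] == groups[1]]
    rows = []
    for var in cohort.columns:
        if var in ("sample_id", group_col):
            continue
        x, y = a[var].dropna(), b[var].dropna()
        binary = set(pd.unique(cohort[var].dropna())) <= {0, 1}
        if binary:
            table = [[int(x.sum()), int(len(x) - x.sum())],
                     [int(y.sum()), int(len(y) - y.sum())]]
            p = stats.fisher_exact(table).pvalue
            kind = "fisher"
        else:
            p = stats.ttest_ind(x, y, equal_var=False).pvalue
            kind = "welch"
        rows.append({"variable": var, "test": kind, "p": float(p)})
    return pd.DataFrame(rows)
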