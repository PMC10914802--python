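"""Drought-tolerance phenotyping: RelSY, DRYM, ranking and bulk selection.

RelSY is the relative starch yield of a genotype in one experiment,
SY(stress) / SY(control).  DRYM (Deviation of Relative starch Yield from
the Median) subtracts the experiment-wide median RelSY, so a positive DRYM
marks a genotype more drought tolerant than the population median
independent of its yield potential.  Bulks are built by ranking genotypes
by tolerance within each experiment, averaging ranks across experiments,
and taking the two extreme tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BulkAssignment:
    tolerant_ids: list[str]
    sensitive_ids: list[str]
    mean_rank: pd.Series  # per genotype, averaged over experiments
    outlier_flags: pd.Series  # bool per genotype

    def __post_init__(self) -> None:
        if set(self.tolerant_ids) & set(self.sensitive_ids):
            raise ValueError("tolerant and sensitive bulks overlap")


def compute_relsy(records: pd.DataFrame) -> pd.DataFrame:
    """Per (genotype, experiment) relative starch yield, stress / control.

    Cells with a missing treatment or a zero control yield are excluded
    with a warning (RelSY undefined there).
    """
    wide = records.pivot_table(
        index=["genotype", "experiment"],
        columns="treatment",
        values="starch_yield",
        aggfunc="mean",
    )
    for col in ("stress", "control"):
        if col not in wide:
            wide[col] = np.nan
    bad_missing = wide["stress"].isna() | wide["control"].isna()
    bad_zero = wide["control"] == 0
    n_bad = int((bad_missing | bad_zero).sum())
    if n_bad:
        warnings.warn(
            f"excluded {n_bad} genotype x experiment cells "
            f"({int(bad_missing.sum())} missing a treatment, {int(bad_zero.sum())} zero control)",
            stacklevel=2,
        )
    ok = wide[~(bad_missing | bad_zero)]
    out = (ok["stress"] / ok["control"]).rename("relsy").reset_index()
    return out


def compute_drym(relsy: pd.DataFrame) -> pd.DataFrame:
    """DRYM = RelSY minus the median RelSY of the same experiment."""
    counts = relsy.groupby("experiment")["genotype"].nunique()
    single = counts[counts < 2]
    if len(single):
        raise ValueError(
            f"experiments with a single genotype (median contrast undefined): "
            f"{', '.join(single.index.astype(str))}"
        )
    out = relsy.copy()
    out["drym"] = out["relsy"] - out.groupby("experiment")["relsy"].transform("median")
    return out


def flag_outliers_iqr(drym: pd.DataFrame, k: float = 1.5) -> pd.Series:
    """Genotypes whose DRYM falls outside median +/- k*IQR in any experiment.

    The published analysis flagged outliers with an external method; this
    configurable Tukey-style rule is the package's stand-in and is off by
    default in bulk selection.
    """
    def _flag(g: pd.DataFrame) -> pd.Series:
        q1, q3 = g["drym"].quantile([0.25, 0.75])
        iqr = q3 - q1
        return (g["drym"] < q1 - k * iqr) | (g["drym"] > q3 + k * iqr)

    flags = drym.groupby("experiment", group_keys=False).apply(_flag, include_groups=False)
    flagged = drym.loc[flags[flags].index, "genotype"].unique()
    genos = drym["genotype"].unique()
    return pd.Series(np.isin(genos, flagged), index=genos, name="outlier")


def select_bulks(
    drym: pd.DataFrame, n_bulk: int = 20, outlier_rule: str | None = None
) -> BulkAssignment:
    """Rank genotypes by DRYM within each experiment (average ranks on
    ties), average ranks over the experiments each genotype appears in,
    and take the n_bulk most extreme genotypes at either end.  Orientation
    is fixed so the tolerant bulk is the one with the higher mean DRYM.
    """
    work = drym.copy()
    if outlier_rule == "iqr":
        flags = flag_outliers_iqr(work)
        work = work[~work["genotype"].map(flags)]
    else:
        flags = pd.Series(False, index=pd.Index(work["genotype"].unique()), name="outlier")

    # rank 1 = most tolerant (highest DRYM) within each experiment
    work["rank"] = work.groupby("experiment")["drym"].rank(ascending=False, method="average")
    mean_rank = work.groupby("genotype")["rank"].mean()
    if len(mean_rank) < 2 * n_bulk:
        raise ValueError(
            f"need at least {2 * n_bulk} eligible genotypes, have {len(mean_rank)}"
        )
    ordered = mean_rank.sort_values(kind="mergesort")
    low = list(ordered.index[:n_bulk])  # lowest mean rank = most tolerant
    high = list(ordered.index[-n_bulk:])
    mean_drym = work.groupby("genotype")["drym"].mean()
    if mean_drym[low].mean() >= mean_drym[high].mean():
        tolerant, sensitive = low, high
    else:
        tolerant, sensitive = high, low
    return BulkAssignment(
        tolerant_ids=tolerant,
        sensitive_ids=sensitive,
        mean_rank=mean_rank,
        outlier_flags=flags,
    )


def bulk_separation_test(drym_tol, drym_sen) -> tuple[float, float, float]:
    """Welch two-sample t-test between the bulks' DRYM values.

    Returns (t, Welch-Satterthwaite df, two-sided p).  Two identical
    zero-variance groups yield t = 0, p = 1 by convention.
    """
    a = np.asarray(drym_tol, dtype=float)
    b = np.asarray(drym_sen, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
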