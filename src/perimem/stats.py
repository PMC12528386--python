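"""Group statistics: box-plot summaries, Student's t test, Pearson r.

Quartiles use the linear-interpolation convention (NumPy's default), and
whiskers extend to the most extreme data point within 1.5 interquartile
ranges of the corresponding quartile. The default two-sample test is the
pooled-variance Student t (equal variances assumed, df = n_a + n_b - 2);
Welch's form is available. Group comparisons pool all qc-passing
measurement points per group by default ("points" mode — every 50-nm
segment contributes one observation); a per-cell-mean mode is provided
because point-level pooling ignores within-cell correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .measure import qc_filter


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n_points: int
    n_cells: int
    mean_nm: float
    sd_nm: float
    median_nm: float
    q1_nm: float
    q3_nm: float
    whisker_low_nm: float
    whisker_high_nm: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_two_tailed: float
    method: str  # "student_pooled" | "welch"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_tailed: float
    n: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_group(
    distances, group_label: str = "", cell_ids=None
) -> GroupSummary:
    """Box-plot summary (median, quartiles, 1.5-IQR whiskers) of one group.

    A single-value group reports sd 0. Whiskers are clipped to the most
    extreme data point within 1.5 IQR of the corresponding quartile.
    """
    x = np.asarray(list(distances), dtype=float)
    if x.size == 0:
        raise ParameterError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    in_low = x[x >= q1 - 1.5 * iqr]
    in_high = x[x <= q3 + 1.5 * iqr]
    n_cells = len(set(cell_ids)) if cell_ids is not None else 0
    return GroupSummary(
        group_label=group_label,
        n_points=int(x.size),
        n_cells=n_cells,
        mean_nm=float(x.mean()),
        sd_nm=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median_nm=float(med),
        q1_nm=float(q1),
        q3_nm=float(q3),
        whisker_low_nm=float(in_low.min()),
        whisker_high_nm=float(in_high.max()),
    )


def student_t_two_tailed(a, b, method: str = "student_pooled") -> TTestResult:
    """Two-tailed two-sample t test (pooled-variance Student by default)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs >= 2 values")
    if method == "student_pooled":
        res = sps.ttest_ind(a, b, equal_var=True)
        df = float(a.size + b.size - 2)
    elif method == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    else:
        raise ParameterError(f"unknown t-test method {method!r}")
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):  # identical zero-variance groups
        t, p = 0.0, 1.0
    return TTestResult(t_stat=t, df=df, p_two_tailed=p, method=method)


def pearson_r(x, y) -> CorrelationResult:
    """Sample Pearson correlation with a two-tailed t-based p value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ParameterError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ParameterError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p_two_tailed=float(res.pvalue), n=int(x.size)
    )


def compare_groups(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    label_a: str = "A",
    label_b: str = "B",
    pooling: str = "points",
    method: str = "student_pooled",
) -> tuple[GroupSummary, GroupSummary, TTestResult, float]:
    """Compare pooled intermembrane distances of two measurement tables.

    QC-failing rows are dropped first. ``pooling="points"`` uses every
    passing segment as one observation (the box-plot convention where n is
    the number of measurement points); ``pooling="cells"`` collapses each
    cell to its mean first. Returns both summaries, the two-tailed t test
    and the difference of group means (a - b) in nm.
    """
    vals = []
    for tab, label in ((table_a, label_a), (table_b, label_b)):
        ok = qc_filter(tab)
        if len(ok) == 0:
            raise ParameterError(f"group {label!r} has no qc-passing rows")
        if pooling == "points":
            v = ok["distance_nm"].to_numpy()
            cells = ok["cell_id"]
        elif pooling == "cells":
            per_cell = ok.groupby("cell_id")["distance_nm"].mean()
            v = per_cell.to_numpy()
            cells = per_cell.index
        else:
            raise ParameterError(f"unknown pooling {pooling!r}")
        vals.append((v, cells, label))

    (va, ca, la), (vb, cb, lb) = vals
    summary_a = summarize_group(va, la, ca)
    summary_b = summarize_group(vb, lb, cb)
    test = student_t_two_tailed(va, vb, method=method)
    diff = float(va.mean() - vb.mean())
    return summary_a, summary_b, test, diff
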