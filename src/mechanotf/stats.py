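"""Group statistics for the inhibitor screen.

Each condition is compared to the loaded reference group (2x load) with
an unpaired two-tailed Student t test (pooled variance; a Welch option
exists). Box summaries follow the 1.5*IQR whisker convention with
outliers listed explicitly. No multiple-testing correction is applied
across conditions in the primary columns — each comparison stands alone
— but a Benjamini-Hochberg-adjusted column is printed alongside for
transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mechanotf")


def student_t_test(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Unpaired two-tailed two-sample t test.

    Pooled-variance (Student) by default with df = n_a + n_b - 2;
    ``welch=True`` switches to the unequal-variance form. Raises when
    the pooled variance is zero (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not welch:
        pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        if pooled <= 0:
            raise ValueError("zero pooled variance: t statistic undefined")
        res = sps.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    else:
        if a.var(ddof=1) + b.var(ddof=1) <= 0:
            raise ValueError("zero variance: t statistic undefined")
        res = sps.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class BoxSummary:
    """Five-number box-plot summary with 1.5*IQR whiskers at actual data
    points and explicit outliers."""

    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float | None
    whisker_high: float | None
    outliers: list[float] = field(default_factory=list)
    n: int = 0
    flagged_small_n: bool = False


def box_summary(values) -> BoxSummary:
    """Quartiles by linear interpolation; whiskers at the extreme data
    points inside the 1.5*IQR fences. With fewer than 4 values the
    summary carries no whiskers and is flagged."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    if v.size < 4:
        return BoxSummary(float(q1), float(med), float(q3), float(iqr),
                          None, None, [], int(v.size), True)
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=[float(x) for x in outliers],
        n=int(v.size),
    )


def star_category(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns
    (strict inequalities)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def build_screen_report(
    table: pd.DataFrame,
    reference_label: str,
    welch: bool = False,
    per_field: bool = False,
) -> pd.DataFrame:
    """Per condition x metric statistics against the reference group.

    ``table`` has columns (condition, replicate, metric, value). Each
    non-reference condition with >= 2 replicates is tested against the
    reference; conditions with fewer are excluded and logged. Output
    columns: mean, n, box-summary fields, t, df, p, p_adj_bh, star,
    direction (sign of the mean difference vs reference).

    The unit of replication defaults to the table's rows (e.g. one row
    per nucleus). With ``per_field=True`` a ``field`` column is required
    and rows are averaged within each field of view first, so fields
    become the replicates.
    """
    for col in ("condition", "replicate", "metric", "value"):
        if col not in table.columns:
            raise ValueError(f"screen table missing column {col!r}")
    if per_field:
        if "field" not in table.columns:
            raise ValueError("per_field=True requires a 'field' column")
        table = (
            table.groupby(["condition", "metric", "field"], as_index=False)["value"]
            .mean()
            .rename(columns={"field": "replicate"})
        )
    if reference_label not in set(table["condition"]):
        raise ValueError(f"reference condition {reference_label!r} not in table")
    rows = []
    for metric, sub in table.groupby("metric", sort=True):
        ref = sub.loc[sub["condition"] == reference_label, "value"].to_numpy(float)
        if ref.size < 2:
            raise ValueError(
                f"reference {reference_label!r} has < 2 replicates for {metric!r}"
            )
        for cond, grp in sub.groupby("condition", sort=True):
            vals = grp["value"].to_numpy(float)
            if vals.size < 2:
                logger.info(
                    "build_screen_report: %r excluded for %r (n=%d < 2)",
                    cond, metric, vals.size,
                )
                continue
            if cond == reference_label:
                t, df, p = 0.0, float(2 * ref.size - 2), 1.0
            else:
                t, df, p = student_t_test(vals, ref, welch=welch)
            bs = box_summary(vals)
            rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "n": vals.size,
                    "mean": float(vals.mean()),
                    "q1": bs.q1,
                    "median": bs.median,
                    "q3": bs.q3,
                    "whisker_low": bs.whisker_low,
                    "whisker_high": bs.whisker_high,
                    "n_outliers": len(bs.outliers),
                    "t": t,
                    "df": df,
                    "p": p,
                    "star": star_category(p),
                    "direction": (
                        "ref" if cond == reference_label
                        else ("up" if vals.mean() > ref.mean()
                              else "down" if vals.mean() < ref.mean() else "equal")
                    ),
                }
            )
    report = pd.DataFrame(rows)
    if report.empty:
        raise ValueError("no testable conditions")
    # BH column is advisory only; primary p/star stay uncorrected
    tested = report["condition"] != reference_label
    report["p_adj_bh"] = np.nan
    if tested.any():
        report.loc[tested, "p_adj_bh"] = multipletests(
            report.loc[tested, "p"], method="fdr_bh"
        )[1]
    return report.reset_index(drop=True)
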