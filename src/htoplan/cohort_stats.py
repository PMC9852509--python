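"""Cohort reporting statistics: paired pre/post comparison, rater agreement, summary.

The paired t-test compares each knee's preoperative and postoperative value
of a measure.  Rater agreement uses the intraclass correlation coefficient:
inter-rater reliability is ICC(2,1), the two-way random-effects
absolute-agreement single-measure form; intra-rater (test-retest by one
observer) is ICC(3,1), two-way mixed-effects consistency.  Coefficients are
reported with the conventional qualitative categories: poor (< 0.40), fair
to good (0.40-0.75), excellent (> 0.75); the boundary values 0.40 and 0.75
belong to "fair to good".

Both ICC forms are computed from the classical two-way ANOVA mean squares

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

with MSR the between-subject, MSC the between-rater and MSE the residual
mean square, n subjects and k raters.  The explicit formulas keep degenerate
perfect-agreement tables (MSE = 0) exact at 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .planner import PlanParameters, classify_correction

ICCForm = Literal["inter", "intra"]

#: Measures summarised pre vs post when present in a cohort table.
MEASURE_COLUMNS = ("wbl_ratio", "mfta", "mpta", "wedge_angle")


@dataclass(frozen=True)
class PairedSeries:
    """Pre/post values of one measure, matched by knee identifier."""

    ids: tuple[str, ...]
    pre: tuple[float, ...]
    post: tuple[float, ...]

    def __init__(self, ids: Sequence[str], pre: Sequence[float],
                 post: Sequence[float]) -> None:
        if not (len(ids) == len(pre) == len(post)):
            raise ValueError("ids, pre and post must have equal length")
        if len(ids) < 2:
            raise ValueError("paired series needs at least 2 knees")
        object.__setattr__(self, "ids", tuple(ids))
        object.__setattr__(self, "pre", tuple(float(v) for v in pre))
        object.__setattr__(self, "post", tuple(float(v) for v in post))


def paired_t(series: PairedSeries) -> tuple[float, float, float, float]:
    """Paired t-test of post vs pre.

    Returns ``(t, p, mean_diff, sd_diff)`` where the differences are
    post - pre, t = mean_diff / (sd_diff / sqrt(n)) on n - 1 degrees of
    freedom, and p is two-tailed.
    """
    diff = np.asarray(series.post) - np.asarray(series.pre)
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        if np.all(diff == 0.0):
            return 0.0, 1.0, 0.0, 0.0
        raise ValueError("differences have zero variance; t statistic undefined")
    res = stats.ttest_rel(series.post, series.pre)
    return float(res.statistic), float(res.pvalue), float(np.mean(diff)), sd


def icc_category(value: float) -> str:
    """Qualitative agreement category for an ICC value."""
    if value < 0.40:
        return "poor"
    if value <= 0.75:
        return "fair to good"
    return "excellent"


def icc(table: Sequence[Sequence[float]] | np.ndarray,
        form: ICCForm = "inter") -> tuple[float, str]:
    """Single-measure intraclass correlation of a subjects x raters table.

    ``form="inter"`` gives ICC(2,1) (absolute agreement), ``"intra"`` gives
    ICC(3,1) (consistency).  Requires a complete table with at least 2
    subjects, 2 raters and non-zero between-subject variance.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("rating table must be at least 2 subjects x 2 raters")
    if np.isnan(arr).any():
        raise ValueError("rating table must have no missing cells")
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    if ss_rows == 0.0:
        raise ValueError("between-subject variance is zero; ICC undefined")
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((arr - grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if form == "inter":
        value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    elif form == "intra":
        value = (msr - mse) / (msr + (k - 1) * mse)
    else:
        raise ValueError(f"form must be 'inter' or 'intra', got {form!r}")
    value = float(value)
    return value, icc_category(value)


@dataclass(frozen=True)
class CohortSummary:
    """Per-measure pre/post summary and correction classification of a cohort."""

    table: pd.DataFrame                 # rows = measures; mean/sd pre+post, t, p
    counts: dict[str, int]              # correction class -> knee count
    percentages: dict[str, float]       # correction class -> % of knees (1 dp)
    n_knees: int
    n_unmatched: int
    notes: tuple[str, ...] = field(default=())


def cohort_summary(
    records: pd.DataFrame, params: PlanParameters = PlanParameters()
) -> CohortSummary:
    """Summarise a cohort table of one row per knee x timepoint.

    Expected columns: ``patient_id``, ``side``, ``timepoint`` (pre/post) and
    any of ``wbl_ratio``, ``mfta``, ``mpta``, ``wedge_angle``.  Knees missing
    either timepoint are excluded (their count is reported); postoperative
    WBL ratios are classified as under/acceptable/over against the
    parameters' acceptable band, with percentages rounded to one decimal.
    """
    for col in ("patient_id", "side", "timepoint"):
        if col not in records.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    df = records.copy()
    df["knee"] = df["patient_id"].astype(str) + "/" + df["side"].astype(str)
    pre = df[df["timepoint"] == "pre"].set_index("knee")
    post = df[df["timepoint"] == "post"].set_index("knee")
    matched = pre.index.intersection(post.index)
    n_unmatched = len(pre.index.symmetric_difference(post.index))
    if len(matched) < 1:
        raise ValueError("no knee has both a pre and a post record")
    notes: list[str] = []
    if n_unmatched:
        notes.append(f"{n_unmatched} unmatched knee record(s) excluded")

    measures = [c for c in MEASURE_COLUMNS if c in df.columns]
    rows = []
    for m in measures:
        pre_v = pre.loc[matched, m].astype(float)
        post_v = post.loc[matched, m].astype(float)
        t = p = np.nan
        if len(matched) >= 2 and np.std(post_v - pre_v, ddof=1) > 0:
            t, p, _, _ = paired_t(PairedSeries(matched, pre_v, post_v))
        else:
            notes.append(f"paired t-test skipped for {m} (n < 2 or zero variance)")
        rows.append({
            "measure": m,
            "pre_mean": float(pre_v.mean()), "pre_sd": float(pre_v.std(ddof=1)),
            "post_mean": float(post_v.mean()), "post_sd": float(post_v.std(ddof=1)),
            "t": t, "p": p,
        })
    table = pd.DataFrame(rows).set_index("measure")

    counts = {"under": 0, "acceptable": 0, "over": 0}
    if "wbl_ratio" in measures:
        for ratio in post.loc[matched, "wbl_ratio"].astype(float):
            counts[classify_correction(ratio, params)] += 1
    n = len(matched)
    percentages = {cls: round(100.0 * c / n, 1) for cls, c in counts.items()}
    return CohortSummary(
        table=table,
        counts=counts,
        percentages=percentages,
        n_knees=n,
        n_unmatched=n_unmatched,
        notes=tuple(notes),
    )
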