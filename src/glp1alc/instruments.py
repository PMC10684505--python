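"""Survey instrument scoring and cohort description.

Implements the alcohol-outcome instruments used in the remote survey:

* AUDIT — 10 items; items 1-8 carry option scores 0-4, items 9-10 offer
  three options scored 0/2/4; the total ranges 0-40.
* BAES — 14 items rated 0-10, split into a 7-item stimulative and a
  7-item sedative subscale (each totals 0-70).
* TLFB — 30-day daily drink diary; a day is a binge day at >= 5 drinks
  for males and >= 4 for females.

Group comparisons of cohort characteristics use a one-way equal-variance
ANOVA reconstructed from summary statistics for continuous rows and a
Pearson chi-square (no continuity correction) for categorical rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoringError",
    "score_audit",
    "score_baes",
    "binge_flag",
    "tlfb_summary",
    "anova_from_summary",
    "chisq_from_counts",
    "demographics_table",
    "DEFAULT_WEEKEND_DAYS",
]

# day-of-week numbers (Monday=0): weekend defaults to Fri/Sat/Sun
DEFAULT_WEEKEND_DAYS = frozenset({4, 5, 6})

AUDIT_LAST_TWO_POINTS = {0: 0, 1: 2, 2: 4}


class ScoringError(ValueError):
    """An instrument response is incomplete or out of range."""


def score_audit(items: Sequence[int]) -> int:
    """Total AUDIT score from the 10 option indices.

    Items 1-8 score their index (0-4); items 9-10 are 3-option items
    whose indices 0/1/2 map to 0/2/4 points.  No imputation: a missing
    or out-of-range item raises :class:`ScoringError`.
    """
    if len(items) != 10 or any(v is None for v in items):
        raise ScoringError("AUDIT requires all 10 items")
    items = [int(v) for v in items]
    for i, v in enumerate(items[:8], start=1):
        if not 0 <= v <= 4:
            raise ScoringError(f"AUDIT item {i} index {v} outside 0..4")
    for i, v in enumerate(items[8:], start=9):
        if v not in AUDIT_LAST_TWO_POINTS:
            raise ScoringError(f"AUDIT item {i} index {v} outside 0..2")
    return sum(items[:8]) + sum(AUDIT_LAST_TWO_POINTS[v] for v in items[8:])


def score_baes(items: Sequence[int]) -> tuple[int, int]:
    """(stimulative, sedative) subscale totals from the 14 BAES items.

    Items 1-7 are the stimulative subscale, items 8-14 the sedative one;
    every item must lie in 0..10.
    """
    if len(items) != 14 or any(v is None for v in items):
        raise ScoringError("BAES requires all 14 items")
    items = [int(v) for v in items]
    for i, v in enumerate(items, start=1):
        if not 0 <= v <= 10:
            raise ScoringError(f"BAES item {i} value {v} outside 0..10")
    return sum(items[:7]), sum(items[7:])


def binge_flag(drinks: int, sex: str) -> int:
    """Sex-specific binge classification: >= 5 drinks (male) / >= 4 (female)."""
    if drinks < 0:
        raise ValueError("drinks must be nonnegative")
    threshold = 5 if sex == "male" else 4
    return int(drinks >= threshold)


def tlfb_summary(
    diary: pd.DataFrame,
    sex_by_participant: dict[str, str],
    weekend_days: frozenset[int] = DEFAULT_WEEKEND_DAYS,
    n_days: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-day binge/weekend flags and per-participant weekday/weekend means.

    ``diary`` must hold columns ``participant``, ``date``, ``drinks`` with
    ``n_days`` rows per participant; missing days raise an error listing
    the dates concerned.
    """
    df = diary.copy()
    df["date"] = pd.to_datetime(df["date"])
    problems = []
    for pid, grp in df.groupby("participant"):
        if len(grp) != n_days:
            expected = pd.date_range(grp["date"].min(), periods=n_days)
            missing = sorted(set(expected) - set(grp["date"]))
            problems.append(f"{pid}: {len(grp)} days, missing {[str(d.date()) for d in missing]}")
    if problems:
        raise ValueError("incomplete diaries: " + "; ".join(problems))
    df["is_weekend"] = df["date"].dt.dayofweek.isin(weekend_days)
    df["binge"] = [
        binge_flag(int(d), sex_by_participant[p])
        for d, p in zip(df["drinks"], df["participant"])
    ]
    means = (
        df.groupby(["participant", "is_weekend"])["drinks"]
        .mean()
        .unstack(fill_value=np.nan)
        .rename(columns={False: "weekday_mean", True: "weekend_mean"})
        .reset_index()
    )
    return df, means


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, float]:
    """One-way equal-variance ANOVA reconstructed from per-group summaries.

    Between-group sum of squares is taken about the weighted grand mean
    and the within-group sum of squares is sum (n_i - 1) s_i^2; exactly
    the classic F when the summaries come from the raw data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    g = means.size
    if g < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw == 0:
        if ssb == 0:
            raise ValueError("zero within-group variance with equal means: F undefined")
        return float("inf"), 0.0
    F = (ssb / (g - 1)) / (ssw / (N - g))
    p = float(stats.f.sf(F, g - 1, N - g))
    return float(F), p


def chisq_from_counts(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class Table1Row:
    label: str
    kind: str  # {continuous, categorical}
    cells: dict  # group -> "mean (sd)" or {level: (n, pct)}
    p: float | None
    note: str | None = None


def demographics_table(
    participants: pd.DataFrame,
    continuous: Sequence[str] = ("age", "education", "bmi"),
    categorical: Sequence[str] = ("sex", "ethnicity", "race"),
    group_col: str = "group",
) -> list[Table1Row]:
    """Cohort-characteristics table: mean (SD) with ANOVA p for continuous
    rows, n (%) with chi-square p for categorical rows.  With fewer than
    two groups (or any single-participant group) comparisons are omitted
    with a note."""
    groups = list(participants[group_col].unique())
    rows: list[Table1Row] = []
    can_compare = len(groups) >= 2 and all(
        (participants[group_col] == g).sum() >= 2 for g in groups
    )
    note = None if can_compare else "comparisons omitted: need >= 2 groups of >= 2"

    for col in continuous:
        cells = {}
        means, sds, ns = [], [], []
        for g in groups:
            vals = participants.loc[participants[group_col] == g, col].astype(float)
            cells[g] = f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})"
            means.append(vals.mean())
            sds.append(vals.std(ddof=1))
            ns.append(len(vals))
        p = anova_from_summary(means, sds, ns)[1] if can_compare else None
        rows.append(Table1Row(label=col, kind="continuous", cells=cells, p=p, note=note))

    for col in categorical:
        levels = list(participants[col].unique())
        counts = np.array(
            [
                [((participants[group_col] == g) & (participants[col] == lv)).sum() for lv in levels]
                for g in groups
            ]
        )
        cells = {
            g: {
                lv: (int(c), 100.0 * c / max(c_row.sum(), 1))
                for lv, c in zip(levels, c_row)
            }
            for g, c_row in zip(groups, counts)
        }
        p = None
        row_note = note
        if can_compare:
            keep = counts.sum(axis=0) > 0
            try:
                p = chisq_from_counts(counts[:, keep])[2]
            except ValueError as exc:
                row_note = f"chi-square unavailable: {exc}"
        rows.append(Table1Row(label=col, kind="categorical", cells=cells, p=p, note=row_note))
    return rows
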