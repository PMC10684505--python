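"""Theme dynamics: per-period theme-proportion time series and the
full-order partial-correlation matrix between theme series.

The "full order" partial correlation between two theme series is their
correlation after regressing both on *all* remaining theme series.  On
row-normalised proportions the full control set is rank-deficient by
construction (each row lies on the simplex), so in proportion mode the
smallest theme is removed from every control set; count mode uses all
g - 2 controls.  See the methods note for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .characterize import _key
from .corpus import Corpus

__all__ = [
    "ThemeTimeSeries",
    "PartialCorrMatrix",
    "bin_series",
    "partial_correlation",
    "partial_corr_matrix",
]


@dataclass
class ThemeTimeSeries:
    periods: list[str]  # included (non-empty) periods, ordered
    counts: np.ndarray  # T x g integers
    proportions: np.ndarray  # T x g, each row on the simplex
    theme_ids: list[int]
    empty_periods: list[str]  # calendar periods in range with zero posts
    degenerate: bool = False  # single theme: constant column 1.0


@dataclass
class PartialCorrMatrix:
    rho: np.ndarray  # g x g symmetric, unit diagonal
    p: np.ndarray  # g x g two-sided p-values
    n_controls: int  # controls per pair
    T_effective: int
    dropped_from_controls: int | None = None  # theme id, proportion mode only

    def __post_init__(self) -> None:
        if np.any(np.abs(self.rho) > 1 + 1e-9):
            raise ValueError("|rho| must be <= 1")


def bin_series(corpus: Corpus, labels, bin: str = "month") -> ThemeTimeSeries:
    """Counts and row-normalised proportions of posts per (period, theme).

    Calendar periods between the first and last post with zero posts are
    excluded from the series and reported in ``empty_periods``.
    """
    freq = {"month": "M", "week": "W"}.get(bin)
    if freq is None:
        raise ValueError("bin must be 'month' or 'week'")
    labels = np.asarray(labels)
    if len(corpus) != labels.size:
        raise ValueError("labels must align with the corpus")
    ts = pd.DatetimeIndex([p.timestamp for p in corpus.posts]).tz_localize(None)
    periods = ts.to_period(freq)
    df = pd.DataFrame({"period": periods, "theme": labels})
    table = df.groupby(["period", "theme"], observed=True).size().unstack(fill_value=0)
    table = table.sort_index()

    full_range = pd.period_range(table.index.min(), table.index.max(), freq=freq)
    empty = [str(p) for p in full_range if p not in table.index]

    counts = table.to_numpy(dtype=int)
    totals = counts.sum(axis=1, keepdims=True)
    proportions = counts / totals
    theme_ids = [_key(t) for t in table.columns]
    return ThemeTimeSeries(
        periods=[str(p) for p in table.index],
        counts=counts,
        proportions=proportions,
        theme_ids=theme_ids,
        empty_periods=empty,
        degenerate=len(theme_ids) < 2,
    )


def _residualise(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    if Z.shape[1] == 0:
        return y - y.mean()
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ coef


def partial_corr_matrix(
    X: np.ndarray,
    drop_priority: list[int] | None = None,
) -> PartialCorrMatrix:
    """Full-order partial correlations of the columns of ``X`` (T x g).

    For each pair (i, j), both columns are regressed (with intercept) on
    every other column and the residuals are correlated.  Two-sided
    p-values come from t = rho * sqrt(df / (1 - rho^2)) with
    df = T - 2 - n_controls.

    If ``drop_priority`` is given (simplex-constrained proportions), one
    column is removed from each pair's control set — the first column in
    ``drop_priority`` that is not a member of the pair — so the closure
    identity sum(columns) = 1 cannot force the residuals into exact
    anti-collinearity.
    """
    X = np.asarray(X, dtype=float)
    T, g = X.shape
    sd = X.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(f"constant column(s) {const.tolist()}: degenerate series")
    dropping = bool(drop_priority) and g > 2
    n_controls = max(g - 2 - (1 if dropping else 0), 0)
    if T < g + 3:
        raise ValueError(f"need at least g + 3 = {g + 3} periods, got {T}")
    df = T - 2 - n_controls
    ones = np.ones((T, 1))
    rho = np.eye(g)
    pmat = np.zeros((g, g))
    dropped_any: int | None = None
    for i in range(g):
        for j in range(i + 1, g):
            drop = None
            if dropping:
                drop = next(c for c in drop_priority if c not in (i, j))
                if dropped_any is None:
                    dropped_any = drop
            ctrl_idx = [c for c in range(g) if c not in (i, j) and c != drop]
            Z = np.hstack([ones, X[:, ctrl_idx]])
            if np.linalg.matrix_rank(Z) < Z.shape[1]:
                raise ValueError(
                    f"control matrix for pair ({i},{j}) is rank-deficient"
                )
            ri = _residualise(X[:, i], Z)
            rj = _residualise(X[:, j], Z)
            r = float(np.dot(ri, rj) / np.sqrt(np.dot(ri, ri) * np.dot(rj, rj)))
            rho[i, j] = rho[j, i] = r
            if abs(r) >= 1.0:
                pv = 0.0
            else:
                t = r * np.sqrt(df / (1.0 - r * r))
                pv = float(2 * stats.t.sf(abs(t), df))
            pmat[i, j] = pmat[j, i] = pv
    return PartialCorrMatrix(
        rho=rho,
        p=pmat,
        n_controls=n_controls,
        T_effective=T,
        dropped_from_controls=dropped_any,
    )


def partial_correlation(
    series: ThemeTimeSeries,
    values: str = "proportions",
) -> PartialCorrMatrix:
    """Full-order partial correlations between theme series.

    ``values='proportions'`` analyses the simplex-constrained shares and
    drops the smallest available theme (by total count) from each pair's
    control set to restore full rank; ``values='counts'`` analyses raw
    counts with all g - 2 controls.
    """
    if values not in ("proportions", "counts"):
        raise ValueError("values must be 'proportions' or 'counts'")
    if series.degenerate:
        raise ValueError("single-theme series: partial correlation undefined")
    if values == "counts":
        return partial_corr_matrix(series.counts.astype(float))
    priority = list(np.argsort(series.counts.sum(axis=0), kind="stable"))
    return partial_corr_matrix(series.proportions, drop_priority=[int(c) for c in priority])
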