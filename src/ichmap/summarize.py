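"""Temporal summaries and knockout-series comparisons.

Per-time summaries are the mean with a seeded percentile bootstrap
confidence interval, a loess curve (tricube-weighted local linear
regression) with a t-based pointwise band, and a peak time defined as
the observed time point closest to the argmax of the loess fit.  The
knockout series is summarized per group as animal-level boxplot
statistics (type-7 quartiles, 1.5 IQR whiskers) with exact two-sided
rank-sum comparisons corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GroupSummary, TimeCourse
from .temporal import bh_adjust, wilcoxon_rank_sum

log = logging.getLogger(__name__)

__all__ = [
    "bootstrap_ci",
    "loess_fit",
    "peak_time",
    "build_time_course",
    "group_summary",
    "group_compare",
]


def bootstrap_ci(values: np.ndarray, level: float = 0.95,
                 n_boot: int = 10_000, seed: int = 0
                 ) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean; deterministic given seed."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("no values")
    if n == 1:
        log.warning("bootstrap CI of a single value is degenerate")
        return float(values[0]), float(values[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# loess


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _local_linear_weights(x: np.ndarray, x0: float, span: float
                          ) -> np.ndarray:
    """Row of the smoother matrix: fitted value at x0 = l(x0) . y."""
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    d = np.abs(x - x0)
    d_sorted = np.sort(d)
    h = d_sorted[min(k, n) - 1]
    # tricube weight vanishes exactly at h; widen the window until at
    # least two points carry positive weight (ties at the k-th distance
    # would otherwise leave a degenerate one-point fit)
    kk = min(k, n)
    while kk < n and (d < h).sum() < 2:
        h = d_sorted[kk]
        kk += 1
    if h <= 0:
        h = max(d.max(), 1.0) * 1e-8
    w = _tricube(d / h)
    if (w > 0).sum() < 2:
        raise ValueError(
            "span too small for a local linear fit; increase span to at "
            f"least {2.0 / n:.2f}"
        )
    # weighted least squares for [1, (x - x0)]; fitted value at x0 is
    # the intercept
    xc = x - x0
    s0 = w.sum()
    s1 = (w * xc).sum()
    s2 = (w * xc * xc).sum()
    denom = s0 * s2 - s1 * s1
    if denom <= np.finfo(float).tiny * max(1.0, s0 * s2):
        return w / s0  # degenerate design: weighted mean
    return w * (s2 - s1 * xc) / denom


def loess_fit(times: np.ndarray, values: np.ndarray, span: float = 0.75,
              grid: np.ndarray | None = None, ci_level: float = 0.95,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tricube local linear regression with a t-based pointwise band.

    Returns (grid, fit, half_band).  The error df uses the smoother's
    trace approximation delta1 = n - 2 tr(L) + tr(L L^T).
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct time values for loess")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 101)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < x.min() - 1e-9 or grid.max() > x.max() + 1e-9:
        raise ValueError("loess grid must span observed times only")

    smoother = np.vstack([_local_linear_weights(x, xi, span) for xi in x])
    resid = y - smoother @ y
    nu1 = np.trace(smoother)
    nu2 = np.trace(smoother @ smoother.T)
    delta1 = max(len(x) - 2 * nu1 + nu2, 1.0)
    sigma2 = float(resid @ resid) / delta1
    tval = stats.t.ppf(0.5 + ci_level / 2.0, df=delta1)

    fit = np.empty(len(grid))
    half = np.empty(len(grid))
    for i, g in enumerate(grid):
        li = _local_linear_weights(x, g, span)
        fit[i] = li @ y
        half[i] = tval * np.sqrt(sigma2 * (li @ li))
    return grid, fit, half


def peak_time(times: np.ndarray, estimates: np.ndarray, span: float = 0.5,
              flat_tol: float = 1e-9,
              ) -> tuple[float | None, list[float]]:
    """Peak of a time course: observed time closest to the loess argmax.

    The default span here is tighter than the display curve's: with a
    handful of time points a wide-span local-linear fit pulls the
    argmax toward the densely-sampled side, so peak localization uses
    half-span windows.  Also returns the list of local maxima of the
    per-time estimate sequence (for biphasic courses, which any wide
    smoother would merge into one hump).  A flat course yields
    ``(None, [])``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(estimates, dtype=float)
    order = np.argsort(t)
    t, e = t[order], e[order]
    if e.max() - e.min() < flat_tol * max(1.0, np.abs(e).max()):
        return None, []
    grid, fit, _ = loess_fit(t, e, span=span)
    t_star = grid[int(np.argmax(fit))]
    nearest = t[np.argmin(np.abs(t - t_star))]  # ties: argmin takes earlier
    # interior local maxima of the estimate sequence (a wide-span loess
    # would smooth a biphasic course into one hump, so the raw sequence
    # is what identifies secondary peaks)
    maxima = [
        float(t[i]) for i in range(1, len(t) - 1)
        if e[i] > e[i - 1] and e[i] > e[i + 1]
    ]
    return float(nearest), maxima


def build_time_course(values_by_time: dict[float, np.ndarray],
                      grouping: str = "", level: float = 0.95,
                      n_boot: int = 10_000, seed: int = 0,
                      span: float = 0.75, peak_span: float = 0.5,
                      min_n: int = 3) -> TimeCourse:
    """Assemble a TimeCourse: per-time mean + bootstrap CI, loess, peak."""
    rows = []
    for i, t in enumerate(sorted(values_by_time)):
        vals = np.asarray(values_by_time[t], dtype=float)
        lo, hi = bootstrap_ci(vals, level=level, n_boot=n_boot,
                              seed=seed + i)
        rows.append(
            {
                "time_h": t,
                "n": len(vals),
                "estimate": float(vals.mean()),
                "ci_lo": lo,
                "ci_hi": hi,
                "reliable": len(vals) >= min_n,
            }
        )
    table = pd.DataFrame(rows)
    tc = TimeCourse(
        grouping=grouping, table=table,
        values={float(t): np.asarray(v, dtype=float)
                for t, v in values_by_time.items()},
        ci_level=level,
    )
    if len(table) >= 4:
        grid, fit, half = loess_fit(
            table["time_h"].to_numpy(), table["estimate"].to_numpy(),
            span=span,
        )
        tc.loess_grid, tc.loess_fit, tc.loess_band = grid, fit, half
        peak, maxima = peak_time(
            table["time_h"].to_numpy(), table["estimate"].to_numpy(),
            span=peak_span,
        )
        tc.peak_time_h, tc.local_maxima_h = peak, maxima
    return tc


# ---------------------------------------------------------------------------
# knockout-series group comparison


def group_summary(group: str, values: np.ndarray) -> GroupSummary:
    """Boxplot statistics: type-7 quartiles, whiskers at the most
    extreme values within 1.5 IQR of the box."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return GroupSummary(
        group=group, values=v, n=len(v), median=float(med),
        q1=float(q1), q3=float(q3),
        whisker_lo=float(in_lo.min()), whisker_hi=float(in_hi.max()),
    )


def group_compare(values_by_group: dict[str, np.ndarray],
                  comparisons: list[tuple[str, str]],
                  min_n: int = 3) -> tuple[dict[str, GroupSummary],
                                           pd.DataFrame]:
    """Animal-level group summaries plus exact rank-sum comparisons.

    ``comparisons`` lists (group_a, group_b) pairs; p values are
    two-sided exact rank-sum, BH-adjusted over the comparison family.
    Groups below ``min_n`` get summaries but no tests.
    """
    summaries = {g: group_summary(g, v) for g, v in values_by_group.items()}
    rows = []
    for a, b in comparisons:
        va = np.asarray(values_by_group[a], dtype=float)
        vb = np.asarray(values_by_group[b], dtype=float)
        if len(va) < min_n or len(vb) < min_n:
            log.warning("comparison %s vs %s skipped: group too small", a, b)
            p = np.nan
        else:
            p = wilcoxon_rank_sum(va, vb)
        rows.append({"group_a": a, "group_b": b,
                     "n_a": len(va), "n_b": len(vb), "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return summaries, table
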