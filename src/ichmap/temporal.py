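"""Region-stratified temporal differential expression and enrichment.

Each post-injection time point is compared against the no-injection
control within one anatomical region using a two-sided Wilcoxon
rank-sum test per gene (tie-corrected normal approximation; exact
enumeration of the rank-sum distribution when both groups have at most
eight spots).  Benjamini-Hochberg controls the FDR, top-k tables
collect the induced markers, and gene-set enrichment of a query list is
hypergeometric against a detected-gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCatalog
from .spatial import NormalizedExpression, score_gene_set

log = logging.getLogger(__name__)

EXACT_MAX_N = 8
LOG2FC_EPS = 1e-9


def _time_match(times: pd.Series, time_h: float | None) -> np.ndarray:
    """Row mask for a time point; ``None`` matches the control (NaN)."""
    if time_h is None:
        return times.isna().to_numpy()
    return (times == time_h).to_numpy()


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _ranksum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p: P(|W - E[W]| >= |w_obs - E[W]|) under the
    permutation distribution of the rank sum of the first group."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    e_w = n1 * (len(pooled) + 1) / 2.0
    d_obs = abs(w_obs - e_w) - 1e-12  # guard against float round-off
    hits = 0
    total = 0
    for comb in combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - e_w) >= d_obs:
            hits += 1
    return hits / total


def _ranksum_exact_p_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact enumeration for all genes at once: a (n_comb, n) indicator
    matrix of group-1 assignments turns the rank sums of every
    permutation into one matrix product per expression block."""
    n1, n2 = x.shape[0], y.shape[0]
    n = n1 + n2
    idx = np.fromiter(
        (i for c in combinations(range(n), n1) for i in c), dtype=np.intp
    ).reshape(-1, n1)
    indicator = np.zeros((idx.shape[0], n))
    indicator[np.arange(idx.shape[0])[:, None], idx] = 1.0
    ranks = stats.rankdata(np.vstack([x, y]), axis=0)  # (n, g)
    w_all = indicator @ ranks  # (n_comb, g)
    e_w = n1 * (n + 1) / 2.0
    d_obs = np.abs(ranks[:n1].sum(axis=0) - e_w) - 1e-12
    return (np.abs(w_all - e_w) >= d_obs).mean(axis=0)


def _ranksum_normal_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal approximation; inputs are
    (n1, g) and (n2, g) arrays, output one p per column."""
    n1, n2 = x.shape[0], y.shape[0]
    n = n1 + n2
    pooled = np.vstack([x, y])
    ranks = stats.rankdata(pooled, axis=0)
    w = ranks[:n1].sum(axis=0)
    e_w = n1 * (n + 1) / 2.0
    # tie correction per column
    tie_term = np.zeros(pooled.shape[1])
    for j in range(pooled.shape[1]):
        _, counts = np.unique(pooled[:, j], return_counts=True)
        tie_term[j] = np.sum(counts ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w - e_w) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[var == 0] = 1.0  # constant gene: no evidence either way
    return np.minimum(p, 1.0)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p for two 1-D samples (exact for small n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return _ranksum_exact_p(x, y)
    return float(_ranksum_normal_p(x[:, None], y[:, None])[0])


def rank_genes_wilcoxon(expr: NormalizedExpression,
                        region_labels: pd.Series,
                        region: str,
                        time_h: float,
                        control_time: float | None = None,
                        min_spots: int = 3) -> pd.DataFrame | None:
    """Per-gene rank-sum test of one region/time against the control.

    Returns a frame with ``gene``, ``stat`` (rank-biserial-like shift
    statistic: rank sum minus expectation), ``p``, ``p_adj``,
    ``log2fc`` and the group sizes, or ``None`` (with a warning) when
    the region is missing at either time point.
    """
    labels = np.asarray(region_labels)
    times = expr.spots["time_h"]
    in_region = labels == region
    grp = in_region & _time_match(times, time_h)
    ctl = in_region & _time_match(times, control_time)
    if grp.sum() < min_spots or ctl.sum() < min_spots:
        log.warning(
            "region %r has too few spots at t=%s (%d) or control (%d)",
            region, time_h, int(grp.sum()), int(ctl.sum()),
        )
        return None
    x = expr.matrix[grp]
    y = expr.matrix[ctl]
    if x.shape[0] <= EXACT_MAX_N and y.shape[0] <= EXACT_MAX_N:
        p = _ranksum_exact_p_matrix(x, y)
    else:
        p = _ranksum_normal_p(x, y)
    mean_x = np.expm1(x).mean(axis=0)
    mean_y = np.expm1(y).mean(axis=0)
    log2fc = np.log2((mean_x + LOG2FC_EPS) / (mean_y + LOG2FC_EPS))
    n1 = x.shape[0]
    ranks = stats.rankdata(np.vstack([x, y]), axis=0)
    stat = ranks[:n1].sum(axis=0) - n1 * (n1 + y.shape[0] + 1) / 2.0
    return pd.DataFrame(
        {
            "gene": expr.genes,
            "region": region,
            "time_h": time_h,
            "stat": stat,
            "p": p,
            "p_adj": bh_adjust(p),
            "log2fc": log2fc,
            "n_group": n1,
            "n_control": y.shape[0],
        }
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs propagate and are excluded
    from the ranking."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def top_k_table(dge_by_time: dict[float, pd.DataFrame], k: int = 5
                ) -> pd.DataFrame:
    """Top-k up-regulated genes per time point by adjusted p.

    Ties on adjusted p break by descending ``|log2fc|``, then by gene
    symbol.  Fewer than ``k`` significant up-regulated genes at a time
    point yields a short, flagged column.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    for time_h in sorted(dge_by_time):
        dge = dge_by_time[time_h]
        up = dge[dge["log2fc"] > 0].copy()
        up["abs_lfc"] = up["log2fc"].abs()
        up = up.sort_values(
            ["p_adj", "abs_lfc", "gene"], ascending=[True, False, True],
            kind="stable",
        )
        picked = up.head(k)
        if len(picked) < k:
            log.warning(
                "only %d up-regulated genes at t=%s (asked for %d)",
                len(picked), time_h, k,
            )
        for rank, (_, r) in enumerate(picked.iterrows(), start=1):
            rows.append(
                {
                    "time_h": time_h,
                    "rank": rank,
                    "gene": r["gene"],
                    "region": r["region"],
                    "p_adj": r["p_adj"],
                    "log2fc": r["log2fc"],
                    "short": len(picked) < k,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment


def enrich_hypergeometric(query: list[str], catalog: GeneSetCatalog
                          ) -> pd.DataFrame:
    """Over-representation p = P[X >= k] for each catalog set.

    Query genes outside the universe are dropped with a warning; BH is
    applied across the catalog's sets.
    """
    uni = set(catalog.universe)
    filtered = [g for g in dict.fromkeys(query) if g in uni]
    dropped = len(set(query)) - len(filtered)
    if dropped:
        log.warning("%d query genes outside the universe dropped", dropped)
    if not filtered:
        raise ValueError("query empty after restriction to the universe")
    n = len(filtered)
    n_uni = len(uni)
    qset = set(filtered)
    rows = []
    for name in catalog.names():
        members = catalog.restrict(name)
        big_k = len(members)
        k = len(qset & set(members))
        p = float(stats.hypergeom.sf(k - 1, n_uni, big_k, n))
        rows.append(
            {"set": name, "k": k, "n": n, "K": big_k, "N": n_uni, "p": p}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# gene-set time course


def gene_set_time_course(expr: NormalizedExpression,
                         gene_set: list[str],
                         region_labels: pd.Series,
                         region: str,
                         n_bins: int = 25, n_ctrl: int = 50,
                         seed: int = 0,
                         min_spots: int = 3) -> pd.DataFrame:
    """Per-spot gene-set scores collected by time point in one region.

    Returns a tidy frame (time_h, score) with an ``unreliable`` flag on
    time points carrying fewer than ``min_spots`` spots; summary
    statistics (bootstrap CI, loess peak) are layered on by the
    reporting stage.
    """
    scores = score_gene_set(expr, gene_set, n_bins=n_bins, n_ctrl=n_ctrl,
                            seed=seed)
    labels = np.asarray(region_labels)
    in_region = labels == region
    times = expr.spots["time_h"]
    rows = []
    uniq = list(pd.unique(times.dropna()))
    if times.isna().any():
        uniq = [None] + uniq
    for t in uniq:
        sel = in_region & _time_match(times, t)
        vals = scores[sel]
        for v in vals:
            rows.append({"time_h": t, "score": float(v),
                         "unreliable": len(vals) < min_spots})
    return pd.DataFrame(rows)
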