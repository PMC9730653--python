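"""Spot normalization, gene-set scoring, constrained Leiden clustering,
and cluster-to-region assignment.

The anatomical annotation strategy: log-normalize each sample, merge,
score one gene set per candidate anatomical region against
expression-matched control genes, cluster the merged expression matrix
with the community count constrained to the number of expected main
clusters, then label each cluster by the region(s) whose mean score
comes within a dominance ratio of the best region.  A cluster matching
several regions gets a composite label (the deep-brain case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datatypes import GeneSetCatalog, RegionAssignment, SpatialDataset

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedExpression",
    "normalize_counts",
    "merge_samples",
    "score_gene_set",
    "cluster_spots",
    "assign_clusters_to_regions",
]


@dataclass
class NormalizedExpression:
    """Log-normalized expression with provenance.

    ``matrix`` is spots x genes, ``log1p`` of median-total-scaled
    counts.  ``low_detection`` flags genes detected in fewer than three
    spots (kept in the matrix).  ``spots`` carries barcode, sample and
    metadata columns aligned with the matrix rows.
    """

    matrix: np.ndarray
    genes: list[str]
    spots: pd.DataFrame
    low_detection: np.ndarray
    median_total: float

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]


def normalize_counts(dataset: SpatialDataset,
                     min_detection_spots: int = 3) -> NormalizedExpression:
    """Scale each spot to the median total count, then ``log1p``.

    Spots with zero total count are dropped with a logged warning;
    genes detected in fewer than ``min_detection_spots`` spots are
    flagged but retained.
    """
    counts = np.asarray(dataset.counts, dtype=float)
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        log.warning("dropping %d zero-count spots", int((~keep).sum()))
    counts = counts[keep]
    totals = totals[keep]
    if counts.shape[0] == 0:
        raise ValueError("no spots left after dropping zero-count spots")
    median_total = float(np.median(totals))
    scaled = counts * (median_total / totals)[:, None]
    matrix = np.log1p(scaled)
    low = (counts > 0).sum(axis=0) < min_detection_spots
    barcodes = [b for b, k in zip(dataset.barcodes, keep) if k]
    spots = pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": dataset.meta.get("sample_id", ""),
            "time_h": (np.nan if dataset.meta.get("time_h") is None
                       else float(dataset.meta["time_h"])),
            "genotype": dataset.meta.get("genotype", ""),
        }
    )
    return NormalizedExpression(
        matrix=matrix, genes=list(dataset.genes), spots=spots,
        low_detection=low, median_total=median_total,
    )


def merge_samples(samples: list[SpatialDataset]) -> NormalizedExpression:
    """Per-sample normalization, then concatenation (no batch correction)."""
    if not samples:
        raise ValueError("no samples to merge")
    genes = samples[0].genes
    parts = []
    for ds in samples:
        if ds.genes != genes:
            raise ValueError("samples have different gene lists")
        parts.append(normalize_counts(ds))
    matrix = np.vstack([p.matrix for p in parts])
    spots = pd.concat([p.spots for p in parts], ignore_index=True)
    low = np.vstack([p.low_detection for p in parts]).all(axis=0)
    return NormalizedExpression(
        matrix=matrix, genes=list(genes), spots=spots, low_detection=low,
        median_total=float(np.mean([p.median_total for p in parts])),
    )


def score_gene_set(expr: NormalizedExpression | np.ndarray,
                   gene_set: list[str],
                   genes: list[str] | None = None,
                   n_bins: int = 25, n_ctrl: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Per-spot gene-set score against expression-matched controls.

    Genes are ranked by mean expression and cut into ``n_bins`` equal-
    size bins; for every set gene, ``n_ctrl`` control genes are sampled
    from its bin (set genes excluded; with replacement when the bin is
    small).  The score is the mean over set genes minus the mean over
    the pooled controls, per spot.  Deterministic given ``seed``.
    """
    if isinstance(expr, NormalizedExpression):
        matrix, universe = expr.matrix, expr.genes
    else:
        matrix, universe = np.asarray(expr, dtype=float), list(genes)
    index = {g: i for i, g in enumerate(universe)}
    set_idx = [index[g] for g in gene_set if g in index]
    if not set_idx:
        raise ValueError(
            f"gene set has no members in the universe: {gene_set[:5]}..."
        )
    rng = np.random.default_rng(seed)
    mean_expr = matrix.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    n_genes = len(universe)
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // n_genes, n_bins - 1
    )
    in_set = np.zeros(n_genes, dtype=bool)
    in_set[set_idx] = True

    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.nonzero((bin_of == bin_of[gi]) & ~in_set)[0]
        if pool.size == 0:
            log.warning("no control genes available in bin %d", bin_of[gi])
            continue
        replace = pool.size < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    if not ctrl_idx:
        raise ValueError("no control genes could be sampled for the set")
    controls = np.concatenate(ctrl_idx)
    return matrix[:, set_idx].mean(axis=1) - matrix[:, controls].mean(axis=1)


def score_all_regions(expr: NormalizedExpression,
                      catalog: GeneSetCatalog,
                      region_sets: dict[str, str],
                      n_bins: int = 25, n_ctrl: int = 50,
                      seed: int = 0) -> pd.DataFrame:
    """Score one anatomical set per region; spots x regions frame."""
    out = {}
    for region, set_name in region_sets.items():
        out[region] = score_gene_set(
            expr, catalog.restrict(set_name),
            n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
        )
    return pd.DataFrame(out, index=expr.spots.index)


# ---------------------------------------------------------------------------
# constrained clustering


class ResolutionSearchError(RuntimeError):
    pass


def _knn_graph(embedding: np.ndarray, k_neighbors: int) -> igraph.Graph:
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return igraph.Graph(n=embedding.shape[0], edges=sorted(edges))


def _leiden_count(graph: igraph.Graph, resolution: float, seed: int
                  ) -> np.ndarray:
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    return np.asarray(part.membership)


def cluster_spots(expr: NormalizedExpression | np.ndarray,
                  n_pcs: int = 30, k_neighbors: int = 15,
                  target_clusters: int = 5, seed: int = 0,
                  resolution_range: tuple[float, float] = (0.001, 2.0),
                  max_iter: int = 60) -> np.ndarray:
    """Leiden clustering with the community count constrained by a
    bisection search over the resolution parameter.

    Returns labels ``0..target_clusters-1`` ordered by decreasing
    cluster size.  Among resolutions hitting the target the search
    keeps moving toward the smallest one (reproducibility on plateaus).
    The search trace is checked for monotonicity of the community count
    in the resolution; a violated bracket is re-evaluated with a
    perturbed partition seed before the search continues.
    """
    matrix = expr.matrix if isinstance(expr, NormalizedExpression) else expr
    n_spots = matrix.shape[0]
    if n_spots < target_clusters:
        raise ValueError("fewer spots than target clusters")
    if target_clusters == 1:
        return np.zeros(n_spots, dtype=int)

    n_comp = min(n_pcs, n_spots - 1, matrix.shape[1])
    emb = PCA(n_components=n_comp, svd_solver="full").fit_transform(
        matrix - matrix.mean(axis=0)
    )
    graph = _knn_graph(emb, k_neighbors)

    trace: list[tuple[float, int]] = []

    def count_at(res: float, attempt: int = 0) -> tuple[int, np.ndarray]:
        labels = _leiden_count(graph, res, seed + attempt)
        return int(labels.max()) + 1, labels

    r_lo, r_hi = resolution_range
    c_lo, lab_lo = count_at(r_lo)
    c_hi, lab_hi = count_at(r_hi)
    trace += [(r_lo, c_lo), (r_hi, c_hi)]
    best: np.ndarray | None = None
    if c_lo == target_clusters:
        best = lab_lo  # smallest resolution in range already hits the target
    elif c_hi == target_clusters:
        best = lab_hi
    elif not (c_lo < target_clusters < c_hi):
        raise ResolutionSearchError(
            f"target {target_clusters} not bracketed: "
            f"{c_lo} clusters at r={r_lo}, {c_hi} at r={r_hi}"
        )

    if best is not lab_lo:
        # bisect; on a target hit keep shrinking toward smaller resolutions
        lo, hi, cl, ch = r_lo, r_hi, c_lo, c_hi
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            c_mid, lab_mid = count_at(mid)
            if not (cl <= c_mid <= ch):
                # community count not monotone on this bracket: re-run the
                # partition with a perturbed seed before continuing
                c_mid, lab_mid = count_at(mid, attempt=1)
            trace.append((mid, c_mid))
            if c_mid == target_clusters:
                best = lab_mid
                hi, ch = mid, c_mid
            elif c_mid < target_clusters:
                lo, cl = mid, c_mid
            else:
                hi, ch = mid, c_mid
            if hi - lo < 1e-4:
                break
    if best is None:
        counts = sorted(set(c for _, c in trace))
        raise ResolutionSearchError(
            f"resolution search never reached {target_clusters} clusters; "
            f"achievable counts seen: {counts}"
        )
    # relabel by decreasing cluster size
    sizes = np.bincount(best)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return remap[best]


def assign_clusters_to_regions(cluster: np.ndarray,
                               region_scores: pd.DataFrame,
                               dominance_ratio: float = 0.75,
                               ) -> RegionAssignment:
    """Label each cluster with the region(s) scoring near the maximum.

    Per cluster and region the mean score and positive fraction are
    computed; every region whose positive mean score is at least
    ``dominance_ratio`` times the best region's is kept.  Several
    surviving regions yield a composite label joined with ``+``; no
    positive region yields ``unassigned``.
    """
    if not 0 < dominance_ratio <= 1:
        raise ValueError("dominance_ratio must be in (0, 1]")
    cluster = np.asarray(cluster)
    regions = list(region_scores.columns)
    cluster_ids = np.unique(cluster)
    means = pd.DataFrame(index=cluster_ids, columns=regions, dtype=float)
    posfrac = pd.DataFrame(index=cluster_ids, columns=regions, dtype=float)
    for cid in cluster_ids:
        sel = region_scores.loc[cluster == cid]
        if sel.empty:
            raise ValueError(f"cluster {cid} has no spots")
        means.loc[cid] = sel.mean(axis=0)
        posfrac.loc[cid] = (sel > 0).mean(axis=0)

    mapping: dict[int, str] = {}
    for cid in cluster_ids:
        row = means.loc[cid]
        s_max = row.max()
        if s_max <= 0:
            mapping[int(cid)] = "unassigned"
            continue
        hits = [r for r in regions if row[r] >= dominance_ratio * s_max]
        mapping[int(cid)] = "+".join(hits)

    labels = pd.Series([mapping[int(c)] for c in cluster],
                       index=region_scores.index, name="region_label")
    return RegionAssignment(
        cluster=pd.Series(cluster, index=region_scores.index, name="cluster"),
        score_matrix=means,
        positive_fraction=posfrac,
        cluster_to_region=mapping,
        region_label=labels,
    )
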