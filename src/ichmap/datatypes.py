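"""Core data containers shared across the pipeline stages.

The pipeline moves three kinds of objects around: spot-level spatial
transcriptomics samples (:class:`SpatialDataset`), named gene-set
collections (:class:`GeneSetCatalog`), and multichannel fluorescence
sections with compartment label masks (:class:`SectionImage`).  Results
are carried in :class:`RegionAssignment`, :class:`IntensityMap`,
:class:`TimeCourse` and :class:`GroupSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpatialDataset",
    "GeneSetCatalog",
    "RegionAssignment",
    "SectionImage",
    "IntensityMap",
    "TimeCourse",
    "GroupSummary",
]


@dataclass
class SpatialDataset:
    """One spatial transcriptomics sample: spot x gene counts with positions.

    Parameters
    ----------
    counts
        Integer matrix of shape (n_spots, n_genes), non-negative.
    genes
        Gene symbols, length n_genes.
    barcodes
        Spot barcodes, length n_spots, unique within the sample.
    positions
        Frame indexed like ``barcodes`` with columns ``in_tissue``,
        ``array_row``, ``array_col``, ``pxl_row_in_fullres``,
        ``pxl_col_in_fullres``.
    meta
        Sample metadata: ``sample_id``, ``animal``, ``time_h`` (``None``
        for the no-injection control), ``genotype``.
    """

    counts: np.ndarray
    genes: list[str]
    barcodes: list[str]
    positions: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        n_spots, n_genes = self.counts.shape
        if len(self.barcodes) != n_spots:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {n_spots} count rows"
            )
        if len(self.genes) != n_genes:
            raise ValueError(f"{len(self.genes)} genes for {n_genes} count columns")
        if len(set(self.barcodes)) != n_spots:
            raise ValueError("duplicate barcodes within sample")
        if not np.isfinite(self.counts).all() or (self.counts < 0).any():
            raise ValueError("counts must be finite and non-negative")
        missing = set(self.barcodes) - set(self.positions.index)
        if missing:
            raise ValueError(
                f"barcodes missing from positions: {sorted(missing)[:5]}"
            )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class GeneSetCatalog:
    """Named gene sets plus the scorable gene universe.

    ``sets`` maps a set name to its member symbols; members are stored
    unique with first-occurrence order preserved.  ``universe`` is the
    list of genes that can be scored (typically all detected genes).
    """

    sets: dict[str, list[str]]
    universe: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        cleaned = {}
        for name, members in self.sets.items():
            seen: dict[str, None] = {}
            for m in members:
                if m:
                    seen.setdefault(m, None)
            cleaned[name] = list(seen)
        self.sets = cleaned

    def restrict(self, name: str) -> list[str]:
        """Members of ``name`` intersected with the universe (order kept)."""
        uni = set(self.universe)
        hits = [g for g in self.sets[name] if g in uni]
        if not hits:
            raise ValueError(
                f"gene set {name!r} has no members in the universe"
            )
        return hits

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class RegionAssignment:
    """Cluster labels and their anatomical interpretation.

    ``cluster`` gives the per-spot cluster id; ``score_matrix`` the mean
    gene-set score per (cluster, region) with ``positive_fraction`` the
    share of spots scoring above zero; ``cluster_to_region`` maps each
    cluster to its final label (single region, composite joined with
    ``+``, or ``unassigned``); ``region_label`` is the per-spot result.
    """

    cluster: pd.Series
    score_matrix: pd.DataFrame
    positive_fraction: pd.DataFrame
    cluster_to_region: dict[int, str]
    region_label: pd.Series


@dataclass
class SectionImage:
    """One multichannel fluorescence section with compartment masks.

    ``channels`` maps marker name to a 2-D float image.  ``labels`` is an
    unsigned-integer parcel image (0 = background) and ``label_table`` a
    frame with columns ``label`` and ``compartment`` covering every
    nonzero label.  ``section_position_um`` is measured posterior to the
    anterior commissure (positive posterior).
    """

    channels: dict[str, np.ndarray]
    labels: np.ndarray
    label_table: pd.DataFrame
    px_size_um: float
    section_position_um: float
    animal: str
    time_h: float | None
    genotype: str
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.px_size_um <= 0:
            raise ValueError("px_size_um must be positive")
        shape = self.labels.shape
        for name, img in self.channels.items():
            if img.shape != shape:
                raise ValueError(
                    f"channel {name!r} shape {img.shape} != mask shape {shape}"
                )
        present = set(np.unique(self.labels)) - {0}
        known = set(self.label_table["label"].astype(int))
        orphan = present - known
        if orphan:
            raise ValueError(f"labels missing from label table: {sorted(orphan)}")

    def parcel_mask(self, compartment: str) -> np.ndarray:
        """Boolean mask of the named parcel (exact label-table match)."""
        rows = self.label_table.loc[
            self.label_table["compartment"] == compartment, "label"
        ]
        if rows.empty:
            raise KeyError(f"compartment {compartment!r} not in label table")
        return np.isin(self.labels, rows.to_numpy())


@dataclass
class IntensityMap:
    """Cross-animal average-intensity map on the template grid."""

    marker: str
    time_h: float | None
    genotype: str
    image: np.ndarray  # NaN outside coverage
    coverage: np.ndarray  # int counts of contributing sections
    n_sections: int
    n_animals: int


@dataclass
class TimeCourse:
    """Per-time summaries of one quantity in one compartment.

    ``table`` has one row per time point with columns ``time_h``, ``n``,
    ``estimate`` (mean of the per-unit values), ``ci_lo``, ``ci_hi``,
    ``reliable``.  ``loess_grid`` / ``loess_fit`` / ``loess_band`` hold
    the smoother evaluated on a dense grid spanning the observed times.
    """

    grouping: str
    table: pd.DataFrame
    values: dict[float, np.ndarray]
    ci_level: float
    loess_grid: np.ndarray | None = None
    loess_fit: np.ndarray | None = None
    loess_band: np.ndarray | None = None
    peak_time_h: float | None = None
    local_maxima_h: list[float] = field(default_factory=list)


@dataclass
class GroupSummary:
    """Animal-level box summary for one genotype/condition group."""

    group: str
    values: np.ndarray
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
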