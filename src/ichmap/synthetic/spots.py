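"""Negative-binomial spot-count generation on the section template.

Spots sit on a square grid (100 µm pitch by default, 55 µm nominal spot
diameter recorded in metadata).  Counts follow a negative-binomial
model: ``mean = library_size * relative_expression / Z`` where relative
expression is the baseline table times the spot-region marker fold
times the product of the active temporal-program folds at the sample's
time point, and ``Z`` is a fixed normalizing constant so that planted
fold-changes translate exactly into mean-count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datatypes import SpatialDataset
from .layout import SectionLayout
from .programs import CohortDesign, TemporalProgram, program_fold

NB_DISPERSION = 0.2  # var = mu + dispersion * mu^2
LIBSIZE_LOG_MEAN = 9.2
LIBSIZE_LOG_SD = 0.3
SPOT_PITCH_UM = 100.0
SPOT_DIAMETER_UM = 55.0

_BASES = "ACGT"


def _barcode(index: int, length: int = 16) -> str:
    """Deterministic 10x-style barcode from a spot index."""
    chars = []
    for _ in range(length):
        chars.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(chars)) + "-1"


@dataclass
class SpotCohort:
    """Generated samples plus the planted ground truth.

    ``truth`` has one row per (sample, spot) with the true region label
    (``region`` keeps the lesion distinct; ``region5`` folds the lesion
    into STR, the label set the five-cluster annotation can recover)
    and the per-program fold that acted on the spot.
    """

    samples: list[SpatialDataset]
    truth: pd.DataFrame
    programs: list[TemporalProgram]
    design: CohortDesign
    layout: SectionLayout


def spot_grid(layout: SectionLayout,
              pitch_um: float = SPOT_PITCH_UM) -> pd.DataFrame:
    """In-tissue spot grid with array and pixel coordinates."""
    step = max(1, int(round(pitch_um / layout.px_size_um)))
    rows = np.arange(0, layout.height_px, step)
    cols = np.arange(0, layout.width_px, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    region = layout.region_of(rr, cc)
    keep = region != ""
    grid = pd.DataFrame(
        {
            "array_row": (rr[keep] / step).astype(int),
            "array_col": (cc[keep] / step).astype(int),
            "pxl_row_in_fullres": rr[keep],
            "pxl_col_in_fullres": cc[keep],
            "region": region[keep].astype(str),
        }
    )
    grid["region5"] = grid["region"].replace({"lesion": "STR"})
    # spots falling on CSF (ventricle lumen) carry no tissue: drop them
    grid = grid[~grid["region"].str.startswith("ventricle")]
    return grid.reset_index(drop=True)


def _validate_inputs(layout: SectionLayout, baseline: pd.DataFrame) -> None:
    layout.validate()
    need = {"symbol", "baseline"}
    if not need <= set(baseline.columns):
        raise ValueError("baseline table needs symbol and baseline columns")
    for region in ("CTX", "STR", "TH", "CP", "DEEP"):
        if region in baseline.columns:
            if (baseline[region] > 1).sum() < 5:
                raise ValueError(f"region {region} has fewer than 5 marker genes")
        else:
            raise ValueError(f"baseline table lacks fold column for {region}")
        if not layout.region_masks[region].any():
            raise ValueError(f"region {region} is empty in the layout")


def generate_spot_cohort(layout: SectionLayout, design: CohortDesign,
                         programs: list[TemporalProgram],
                         baseline: pd.DataFrame) -> SpotCohort:
    """Generate one spot-level sample per cohort design entry.

    Deterministic given ``design.seed``.  The no-injection control
    reuses the lesion geometry but relabels lesion spots as STR and has
    every program fold at 1.
    """
    _validate_inputs(layout, baseline)
    rng = np.random.default_rng(design.seed)
    grid = spot_grid(layout)
    genes = baseline["symbol"].tolist()
    base = baseline["baseline"].to_numpy(float)
    # fixed normalizer: library size is the nominal expected depth of a
    # housekeeping-only spot; program folds then shift means exactly
    z_norm = base.sum()

    spot_regions = ("CTX", "STR", "TH", "CP", "DEEP", "lesion")
    region_fold = {
        r: baseline[r].to_numpy(float) if r in baseline.columns
        else np.ones(len(genes))
        for r in spot_regions
    }

    samples: list[SpatialDataset] = []
    truth_rows: list[pd.DataFrame] = []
    size_nb = 1.0 / NB_DISPERSION

    for sample_id, animal, time_h, genotype in design.samples():
        n_spots = len(grid)
        region = grid["region"].to_numpy()
        if time_h is None:
            region = np.where(region == "lesion", "STR", region)

        rel = np.empty((n_spots, len(genes)))
        folds_by_region: dict[str, np.ndarray] = {}
        program_folds: dict[str, dict[str, float]] = {}
        for r in np.unique(region):
            f = base * region_fold[r]
            pf = {}
            for prog in programs:
                if r in prog.compartments and time_h is not None:
                    x = program_fold(prog, time_h, genotype)
                else:
                    x = 1.0
                pf[prog.name] = x
                if x != 1.0:
                    gi = np.isin(baseline["symbol"], prog.genes)
                    f = np.where(gi, f * x, f)
            folds_by_region[r] = f
            program_folds[r] = pf
        for r, f in folds_by_region.items():
            rel[region == r] = f

        libsize = rng.lognormal(LIBSIZE_LOG_MEAN, LIBSIZE_LOG_SD, n_spots)
        mu = libsize[:, None] * rel / z_norm
        p = 1.0 / (1.0 + NB_DISPERSION * mu)
        counts = rng.negative_binomial(size_nb, p).astype(np.int32)

        barcodes = [_barcode(i) for i in range(n_spots)]
        positions = grid[
            ["array_row", "array_col",
             "pxl_row_in_fullres", "pxl_col_in_fullres"]
        ].copy()
        positions.insert(0, "in_tissue", 1)
        positions.index = pd.Index(barcodes, name="barcode")
        meta = {
            "sample_id": sample_id,
            "animal": animal,
            "time_h": time_h,
            "genotype": genotype,
            "spot_diameter_um": SPOT_DIAMETER_UM,
            "px_size_um": layout.px_size_um,
        }
        samples.append(
            SpatialDataset(counts=counts, genes=list(genes),
                           barcodes=barcodes, positions=positions, meta=meta)
        )
        tr = pd.DataFrame(
            {
                "sample_id": sample_id,
                "barcode": barcodes,
                "time_h": np.nan if time_h is None else float(time_h),
                "genotype": genotype,
                "region": region,
                "region5": np.where(region == "lesion", "STR", region),
            }
        )
        for prog in programs:
            tr[f"fold_{prog.name}"] = [
                program_folds[r][prog.name] for r in region
            ]
        truth_rows.append(tr)

    return SpotCohort(
        samples=samples,
        truth=pd.concat(truth_rows, ignore_index=True),
        programs=programs,
        design=design,
        layout=layout,
    )
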