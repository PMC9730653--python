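"""End-to-end pipeline stages shared by the CLI, the analysis drivers,
and the acceptance checks.

Each stage is a plain function from configuration (plus optional
pre-generated inputs) to tidy tables / result objects; the CLI
subcommands and the numbered analysis scripts are thin wrappers.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import histology as hist
from . import summarize
from .config import RunConfig
from .datatypes import SectionImage
from .spatial import (
    NormalizedExpression,
    assign_clusters_to_regions,
    cluster_spots,
    merge_samples,
    score_all_regions,
)
from .synthetic import (
    CohortDesign,
    anatomical_set_names,
    build_layout,
    default_baseline,
    default_gene_sets,
    default_knockout_design,
    default_programs,
    default_spot_design,
    generate_section_cohort,
    generate_spot_cohort,
    template_section,
)
from .synthetic.spots import SpotCohort
from .temporal import (
    enrich_hypergeometric,
    gene_set_time_course,
    rank_genes_wilcoxon,
    top_k_table,
)

log = logging.getLogger(__name__)

GO_TLR_SET = "GO:0002755 MyD88-dependent toll-like receptor signaling"
CP_COMPARTMENTS = ("CP", "CP_ipsi", "CP_contra", "CP_third",
                   "perilesional_STR", "hemisphere_ipsi", "hemisphere_contra")


def canonical_region(label: str) -> str:
    """Collapse a composite cluster label to a canonical region name."""
    if "+" in label:
        return "DEEP"
    return label


# ---------------------------------------------------------------------------
# transcriptomics


def simulate_spot_cohort(cfg: RunConfig, seed: int | None = None
                         ) -> SpotCohort:
    seed = cfg.seed if seed is None else seed
    layout = build_layout(cfg.spot_layout_px, cfg.px_size_um)
    return generate_spot_cohort(
        layout, default_spot_design(seed), default_programs(),
        default_baseline(),
    )


def annotate_cohort(samples, cfg: RunConfig, seed: int | None = None):
    """Normalize + merge, score regions, cluster, assign regions.

    Returns (expr, scores, assignment).
    """
    seed = cfg.seed if seed is None else seed
    expr = merge_samples(list(samples))
    catalog = default_gene_sets(universe=expr.genes)
    scores = score_all_regions(
        expr, catalog, anatomical_set_names(),
        n_bins=cfg.n_bins, n_ctrl=cfg.n_ctrl, seed=seed,
    )
    labels = cluster_spots(
        expr, n_pcs=cfg.n_pcs, k_neighbors=cfg.k_neighbors,
        target_clusters=cfg.target_clusters, seed=seed,
        resolution_range=cfg.resolution_range,
    )
    assignment = assign_clusters_to_regions(
        labels, scores, dominance_ratio=cfg.dominance_ratio
    )
    return expr, scores, assignment


def run_dge(expr: NormalizedExpression, assignment, cfg: RunConfig,
            regions: Sequence[str] | None = None
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-stratified DE of every post-injection time vs control.

    Returns (all results concatenated, top-k marker table).
    """
    region_per_spot = assignment.region_label.map(canonical_region)
    times = sorted(
        t for t in expr.spots["time_h"].dropna().unique() if t is not None
    )
    if regions is None:
        regions = sorted(region_per_spot.unique())
    all_rows, top_rows = [], []
    for region in regions:
        by_time = {}
        for t in times:
            res = rank_genes_wilcoxon(
                expr, region_per_spot, region, float(t),
                control_time=None, min_spots=cfg.min_spots,
            )
            if res is not None:
                by_time[float(t)] = res
                all_rows.append(res)
        if by_time:
            top_rows.append(top_k_table(by_time, k=cfg.top_k))
    dge = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    top = pd.concat(top_rows, ignore_index=True) if top_rows else pd.DataFrame()
    return dge, top


def run_enrichment(dge: pd.DataFrame, expr: NormalizedExpression,
                   region: str, time_h: float,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of the significant up-regulated genes
    of one region/time against the detected-gene universe."""
    detected = [
        g for g, low in zip(expr.genes, expr.low_detection) if not low
    ]
    catalog = default_gene_sets(universe=detected)
    sel = dge[(dge["region"] == region) & (dge["time_h"] == time_h)
              & (dge["p_adj"] < alpha) & (dge["log2fc"] > 0)]
    query = [g for g in sel["gene"] if g in set(detected)]
    out = enrich_hypergeometric(query, catalog)
    out.insert(0, "region", region)
    out.insert(1, "time_h", time_h)
    return out


def run_score_timecourse(expr: NormalizedExpression, assignment,
                         cfg: RunConfig, set_name: str = GO_TLR_SET,
                         region: str = "CP", seed: int | None = None):
    """Gene-set-score time course of one region (spot-level values)."""
    seed = cfg.seed if seed is None else seed
    catalog = default_gene_sets(universe=expr.genes)
    region_per_spot = assignment.region_label.map(canonical_region)
    tidy = gene_set_time_course(
        expr, catalog.restrict(set_name), region_per_spot, region,
        n_bins=cfg.n_bins, n_ctrl=cfg.n_ctrl, seed=seed,
        min_spots=cfg.min_spots,
    )
    # the no-injection control sits at t = 0 on the time axis
    by_time = {
        (0.0 if pd.isna(t) else float(t)): g["score"].to_numpy()
        for t, g in tidy.groupby("time_h", dropna=False)
    }
    tc = summarize.build_time_course(
        by_time, grouping=f"{set_name} score in {region}",
        level=cfg.ci_level, n_boot=cfg.bootstrap_b, seed=seed,
        span=cfg.loess_span, min_n=cfg.min_spots,
    )
    return tidy, tc


# ---------------------------------------------------------------------------
# histology


def _iter_standard_sections(design: CohortDesign, markers: Sequence[str],
                            cfg: RunConfig) -> Iterable[SectionImage]:
    """Generate animal stacks and keep only the standardized selection."""
    stack: list[SectionImage] = []
    current = None
    sections = generate_section_cohort(
        design, list(markers), size_px=cfg.histology_layout_px,
        px_size_um=cfg.px_size_um, n_stack=cfg.n_stack_sections,
    )
    def flush(stack):
        if not stack:
            return []
        positions = [s.section_position_um for s in stack]
        idx = hist.select_standard_sections(
            positions, start_um=cfg.section_start_um,
            step_sections=cfg.section_step,
            n_sections=cfg.n_standard_sections,
        )
        return [stack[i] for i in idx]

    for sec in sections:
        if current is not None and sec.animal != current:
            yield from flush(stack)
            stack = []
        current = sec.animal
        stack.append(sec)
    yield from flush(stack)


def _section_measurements(sec: SectionImage, markers: Sequence[str],
                          cfg: RunConfig) -> list[dict]:
    """Compartment means and (for dextran channels) leakage per section."""
    rows = []
    for marker in markers:
        if marker not in sec.channels:
            continue
        means = hist.compartment_mean_intensity(
            sec, marker, CP_COMPARTMENTS, normalize=True
        )
        row = {
            "animal": sec.animal, "time_h": sec.time_h,
            "genotype": sec.genotype,
            "section_position_um": sec.section_position_um,
            "marker": marker,
        }
        row.update({f"mean_{k}": v for k, v in means.items()})
        if marker.startswith("dextran"):
            lesion = hist.compartment_mask(
                sec.labels, sec.label_table, "lesion"
            )
            if lesion.any():
                ys, xs = np.nonzero(lesion)
                site = (float(ys.mean()), float(xs.mean()))
                bg = hist.compartment_mask(
                    sec.labels, sec.label_table, "STR_contra"
                )
                img = hist.normalize_section(sec, marker)
                area, inten = hist.quantify_leakage(
                    img, site, bg, sec.px_size_um,
                    k_sigma=cfg.k_sigma, site_radius_um=cfg.site_radius_um,
                )
                row["leakage_area_mm2"] = area
                row["leakage_mean_intensity"] = inten
        rows.append(row)
    return rows


def run_histology_temporal(cfg: RunConfig, seed: int | None = None,
                           markers: Sequence[str] = ("dextran70", "CD45",
                                                     "ICAM1"),
                           time_points_h: Sequence[float] = (2., 12., 24.,
                                                             36., 48., 96.),
                           with_maps: bool = False) -> dict:
    """Temporal imaging series: per-section quantification streamed over
    the cohort, aggregated to animal level, summarized per time point."""
    seed = cfg.seed if seed is None else seed
    design = CohortDesign(
        time_points_h=tuple(time_points_h),
        animals_per_timepoint=cfg.animals_per_timepoint_histology,
        genotypes=("wildtype",), seed=seed,
    )
    template = template_section(cfg.histology_layout_px, cfg.px_size_um)
    rows = []
    map_acc = {}
    for sec in _iter_standard_sections(design, markers, cfg):
        rows.extend(_section_measurements(sec, markers, cfg))
        if with_maps:
            tform, _, _ = hist.estimate_registration(sec, template)
            for marker in markers:
                img = hist.warp_to_template(
                    hist.normalize_section(sec, marker), tform,
                    template.labels.shape,
                )
                key = (marker, sec.time_h, sec.genotype)
                slot = map_acc.setdefault(
                    key, [np.zeros(img.shape), np.zeros(img.shape, int),
                          0, set()]
                )
                ok = np.isfinite(img)
                slot[0][ok] += img[ok]
                slot[1] += ok
                slot[2] += 1
                slot[3].add(sec.animal)
    per_section = pd.DataFrame(rows)
    animal = (per_section
              .groupby(["marker", "genotype", "time_h", "animal"],
                       dropna=False)
              .mean(numeric_only=True)
              .reset_index())

    def course(marker: str, column: str, label: str):
        sel = animal[(animal["marker"] == marker)
                     & animal[column].notna()]
        by_time = {
            float(t): g[column].to_numpy()
            for t, g in sel.groupby("time_h")
        }
        return summarize.build_time_course(
            by_time, grouping=label, level=cfg.ci_level,
            n_boot=cfg.bootstrap_b, seed=seed, span=cfg.loess_span,
        )

    timecourses = {}
    if "CD45" in markers:
        timecourses["CD45_CP"] = course("CD45", "mean_CP",
                                        "CD45 CP mean intensity")
        timecourses["CD45_perilesional"] = course(
            "CD45", "mean_perilesional_STR", "CD45 perilesional intensity"
        )
    if "ICAM1" in markers:
        timecourses["ICAM1_CP"] = course("ICAM1", "mean_CP",
                                         "ICAM1 CP mean intensity")
    for marker in markers:
        if marker.startswith("dextran"):
            timecourses[f"{marker}_leakage_area"] = course(
                marker, "leakage_area_mm2", f"{marker} leakage area mm2"
            )
            timecourses[f"{marker}_leakage_intensity"] = course(
                marker, "leakage_mean_intensity",
                f"{marker} leakage intensity"
            )
    maps = {}
    from .datatypes import IntensityMap

    for (marker, t, g), (tot, cnt, n_sec, animals) in map_acc.items():
        maps[(marker, t, g)] = IntensityMap(
            marker=marker, time_h=t, genotype=g,
            image=np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan),
            coverage=cnt, n_sections=n_sec, n_animals=len(animals),
        )
    return {
        "per_section": per_section,
        "per_animal": animal,
        "timecourses": timecourses,
        "maps": maps,
    }


def run_knockout_series(cfg: RunConfig, genotype: str,
                        seed: int | None = None,
                        markers: Sequence[str] = ("ICAM1", "F480")) -> dict:
    """Knockout series at 24 h: sham vs wildtype-blood vs knockout-blood."""
    seed = cfg.seed if seed is None else seed
    design = default_knockout_design(genotype, seed)
    rows = []
    for sec in _iter_standard_sections(design, markers, cfg):
        rows.extend(_section_measurements(sec, markers, cfg))
    per_section = pd.DataFrame(rows)
    animal = (per_section
              .groupby(["marker", "genotype", "animal"], dropna=False)
              .mean(numeric_only=True)
              .reset_index())
    out = {}
    for marker in markers:
        sel = animal[animal["marker"] == marker]
        groups = {
            g: d["mean_CP"].to_numpy() for g, d in sel.groupby("genotype")
        }
        comparisons = [("wildtype", genotype), ("wildtype", "sham"),
                       (genotype, "sham")]
        out[marker] = summarize.group_compare(groups, comparisons,
                                              min_n=cfg.min_spots)
    return {"per_animal": animal, "comparisons": out}
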