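"""Report assembly: figures and their backing tables plus a manifest.

Every figure written has a CSV with the exact numbers plotted.  Missing
upstream results do not fail the build; the skipped sections are listed
in the manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import GroupSummary, IntensityMap, TimeCourse
from .io import write_float_map

log = logging.getLogger(__name__)


def _timecourse_frame(tc: TimeCourse) -> pd.DataFrame:
    df = tc.table.copy()
    df.insert(0, "grouping", tc.grouping)
    df["peak_time_h"] = tc.peak_time_h
    df["local_maxima_h"] = ";".join(f"{m:g}" for m in tc.local_maxima_h)
    return df


def _plot_timecourse(tc: TimeCourse, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 3.0))
    t = tc.table["time_h"].to_numpy(float)
    for _, row in tc.table.iterrows():
        ax.add_patch(
            plt.Rectangle(
                (row["time_h"] * 0.92, row["ci_lo"]),
                row["time_h"] * 0.16 + 0.4,
                max(row["ci_hi"] - row["ci_lo"], 1e-12),
                fill=False, edgecolor="k", linewidth=0.8,
            )
        )
    ax.plot(t, tc.table["estimate"], "k.", ms=5)
    if tc.loess_grid is not None:
        ax.plot(tc.loess_grid, tc.loess_fit, "-", color="crimson", lw=1.2)
        ax.fill_between(tc.loess_grid, tc.loess_fit - tc.loess_band,
                        tc.loess_fit + tc.loess_band, color="crimson",
                        alpha=0.15, lw=0)
    ax.set_xscale("log")
    ax.set_xticks(t)
    ax.set_xticklabels([f"{x:g}" for x in t])
    ax.set_xlabel("time after injection (h)")
    ax.set_ylabel(tc.grouping)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_groups(summaries: dict[str, GroupSummary], path: Path,
                 ylabel: str) -> None:
    fig, ax = plt.subplots(figsize=(3.6, 3.0))
    names = list(summaries)
    data = [summaries[g].values for g in names]
    ax.boxplot(data, tick_labels=names, whis=1.5)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def build_report(results: dict, outdir: str | Path) -> Path:
    """Write all available result sections; see module docstring.

    Recognized keys: ``timecourses`` (list of TimeCourse), ``maps``
    (dict key -> IntensityMap), ``dge_top`` (DataFrame), ``enrichment``
    (DataFrame), ``leakage`` (DataFrame), ``groups`` (dict name ->
    (summaries, comparison table)), ``manifest_extra`` (dict).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    skipped: list[str] = []

    tcs: list[TimeCourse] = results.get("timecourses") or []
    if tcs:
        pd.concat([_timecourse_frame(tc) for tc in tcs],
                  ignore_index=True).to_csv(
            outdir / "timecourses.csv", index=False
        )
        written.append("timecourses.csv")
        for tc in tcs:
            stem = tc.grouping.replace(" ", "_").replace("/", "-")
            _plot_timecourse(tc, outdir / f"timecourse_{stem}.png")
            written.append(f"timecourse_{stem}.png")
    else:
        skipped.append("timecourses")

    maps: dict = results.get("maps") or {}
    if maps:
        rows = []
        for key, m in maps.items():
            stem = "map_" + "_".join(str(k) for k in np.atleast_1d(key))
            write_float_map(m.image, outdir / f"{stem}.tif")
            rows.append(
                {
                    "key": str(key), "marker": m.marker, "time_h": m.time_h,
                    "genotype": m.genotype, "n_sections": m.n_sections,
                    "n_animals": m.n_animals,
                    "mean_on_coverage":
                        float(np.nanmean(m.image)),
                }
            )
            written.append(f"{stem}.tif")
        pd.DataFrame(rows).to_csv(outdir / "maps.csv", index=False)
        written.append("maps.csv")
    else:
        skipped.append("maps")

    for key, fname in (("dge_top", "dge_top_genes.csv"),
                       ("enrichment", "enrichment.csv"),
                       ("leakage", "leakage.csv")):
        df = results.get(key)
        if df is not None and len(df):
            df.to_csv(outdir / fname, index=False)
            written.append(fname)
        else:
            skipped.append(key)

    groups: dict = results.get("groups") or {}
    if groups:
        srows, crows = [], []
        for name, (summaries, comp) in groups.items():
            for g, s in summaries.items():
                srows.append(
                    {
                        "series": name, "group": g, "n": s.n,
                        "median": s.median, "q1": s.q1, "q3": s.q3,
                        "whisker_lo": s.whisker_lo, "whisker_hi": s.whisker_hi,
                    }
                )
            comp = comp.copy()
            comp.insert(0, "series", name)
            crows.append(comp)
            _plot_groups(summaries, outdir / f"groups_{name}.png", name)
            written.append(f"groups_{name}.png")
        pd.DataFrame(srows).to_csv(outdir / "group_summaries.csv", index=False)
        pd.concat(crows, ignore_index=True).to_csv(
            outdir / "group_comparisons.csv", index=False
        )
        written += ["group_summaries.csv", "group_comparisons.csv"]
    else:
        skipped.append("groups")

    lines = ["[report]"]
    lines += [f"written = {name}" for name in written]
    lines += [f"skipped = {name}" for name in skipped]
    for k, v in (results.get("manifest_extra") or {}).items():
        lines.append(f"{k} = {v}")
    (outdir / "manifest.txt").write_text("\n".join(lines) + "\n")
    return outdir
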