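"""Write a generated cohort to disk as a self-contained fixture bundle."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from ..datatypes import GeneSetCatalog, SectionImage
from ..io import write_gmt, write_section, write_spatial_bundle
from .spots import SpotCohort


def _prepare_outdir(outdir: str | Path, force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"{outdir} exists and is not empty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def write_fixture_bundle(cohort: SpotCohort,
                         catalog: GeneSetCatalog,
                         outdir: str | Path,
                         force: bool = False) -> Path:
    """Emit MTX bundles (one subdirectory per sample), the gene-set GMT,
    a sample metadata table, and the planted-truth table."""
    outdir = _prepare_outdir(outdir, force)
    meta_rows = []
    for ds in cohort.samples:
        sid = ds.meta["sample_id"]
        write_spatial_bundle(ds, outdir / sid)
        t = ds.meta["time_h"]
        meta_rows.append(
            {
                "sample_id": sid,
                "animal": ds.meta["animal"],
                "time_h": "" if t is None else t,
                "genotype": ds.meta["genotype"],
                "section_position_um": 0.0,
            }
        )
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.csv", index=False)
    write_gmt(catalog, outdir / "gene_sets.gmt")
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
    return outdir


def write_section_fixture(sections: Iterable[SectionImage],
                          outdir: str | Path,
                          force: bool = False) -> Path:
    """Emit channel TIFFs, label-mask TIFFs + tables, and metadata."""
    outdir = _prepare_outdir(outdir, force)
    rows = []
    for i, sec in enumerate(sections):
        stem = f"{sec.animal}_p{int(sec.section_position_um):04d}_{i:04d}"
        rows.append(write_section(sec, outdir / "sections", stem))
    pd.DataFrame(rows).to_csv(outdir / "metadata.csv", index=False)
    return outdir
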