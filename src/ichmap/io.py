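"""Readers and writers for the on-disk formats.

Spot bundles follow the 10x convention: ``matrix.mtx`` in MatrixMarket
coordinate integer format with dimensions (n_genes, n_spots),
``features.tsv`` (id, symbol, type; no header), ``barcodes.tsv``, and a
``tissue_positions.csv``.  Gene sets travel as GMT, images as 16-bit
grayscale TIFF with an unsigned-integer label-mask TIFF plus a sidecar
label table CSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .datatypes import GeneSetCatalog, SectionImage, SpatialDataset

log = logging.getLogger(__name__)

POSITION_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col",
    "pxl_row_in_fullres", "pxl_col_in_fullres",
]


def write_spatial_bundle(dataset: SpatialDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(dataset.counts).T)  # genes x spots
    spio.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    feats = pd.DataFrame(
        {
            "id": [f"SYN{i:05d}" for i in range(len(dataset.genes))],
            "symbol": dataset.genes,
            "type": "Gene Expression",
        }
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(dataset.barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pos = dataset.positions.reset_index()
    pos.columns = POSITION_COLUMNS
    pos.to_csv(outdir / "tissue_positions.csv", index=False)


def read_spatial_bundle(indir: str | Path, meta: dict | None = None
                        ) -> SpatialDataset:
    """Read a 10x-style bundle back into a :class:`SpatialDataset`.

    Genes are deduplicated by symbol (first occurrence wins, logged);
    a barcode absent from the positions table or an empty matrix is an
    error.
    """
    indir = Path(indir)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv",
                  "tissue_positions.csv"):
        if not (indir / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {indir}")
    try:
        mat = spio.mmread(indir / "matrix.mtx")
    except ValueError as exc:
        raise ValueError(f"malformed MTX header in {indir}: {exc}") from exc
    mat = sparse.csr_matrix(mat)
    if mat.nnz == 0 and mat.shape[0] * mat.shape[1] == 0:
        raise ValueError("empty count matrix")
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None,
                        names=["id", "symbol", "type"])
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None
                           )[0].astype(str).tolist()
    if mat.shape != (len(feats), len(barcodes)):
        raise ValueError(
            f"dimension mismatch: matrix {mat.shape}, "
            f"{len(feats)} features, {len(barcodes)} barcodes"
        )
    if len(feats) == 0 or len(barcodes) == 0:
        raise ValueError("empty count matrix")
    counts = np.asarray(mat.todense()).T  # spots x genes
    symbols = feats["symbol"].astype(str).tolist()
    dup = pd.Index(symbols).duplicated()
    if dup.any():
        log.warning("dropping %d duplicate gene symbols (first wins)",
                    int(dup.sum()))
        counts = counts[:, ~dup]
        symbols = [s for s, d in zip(symbols, dup) if not d]
    pos = pd.read_csv(indir / "tissue_positions.csv")
    missing = [c for c in POSITION_COLUMNS if c not in pos.columns]
    if missing:
        raise ValueError(f"positions CSV lacks columns {missing}")
    pos = pos.set_index("barcode")
    absent = [b for b in barcodes if b not in pos.index]
    if absent:
        raise ValueError(
            f"barcode missing from positions: {absent[0]!r}"
            + (f" (+{len(absent) - 1} more)" if len(absent) > 1 else "")
        )
    return SpatialDataset(
        counts=counts.astype(np.int32), genes=symbols, barcodes=barcodes,
        positions=pos.loc[barcodes], meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# GMT


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in catalog.sets.items():
            fh.write("\t".join([name, catalog.provenance] + members) + "\n")


def read_gmt(path: str | Path, universe: list[str] | None = None
             ) -> GeneSetCatalog:
    """Parse a GMT file (set name, description, members per line).

    Trailing tabs yield empty member strings, which are discarded.
    Duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    provenance = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line!r}")
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = [m for m in members if m]
            provenance = provenance or desc
    members_union: list[str] = []
    for m in sets.values():
        members_union.extend(m)
    return GeneSetCatalog(
        sets=sets,
        universe=universe if universe is not None
        else list(dict.fromkeys(members_union)),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# images and masks


def write_mask(labels: np.ndarray, table: pd.DataFrame,
               tiff_path: str | Path, table_path: str | Path) -> None:
    tifffile.imwrite(tiff_path, labels.astype(np.uint16))
    table.to_csv(table_path, index=False)


def read_mask(tiff_path: str | Path, table_path: str | Path
              ) -> tuple[np.ndarray, pd.DataFrame]:
    """Label image + table; every nonzero label must appear in the table."""
    labels = tifffile.imread(tiff_path)
    table = pd.read_csv(table_path)
    if not {"label", "compartment"} <= set(table.columns):
        raise ValueError("label table needs 'label' and 'compartment' columns")
    present = set(np.unique(labels)) - {0}
    known = set(table["label"].astype(int))
    orphan = present - known
    if orphan:
        raise ValueError(f"mask labels absent from table: {sorted(orphan)}")
    return labels, table


def write_channel_image(image: np.ndarray, path: str | Path) -> None:
    """Store an intensity image as 16-bit grayscale TIFF (clipped)."""
    img = np.clip(np.asarray(image, dtype=float), 0, 65535)
    tifffile.imwrite(path, img.astype(np.uint16))


def read_channel_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float32)


def write_float_map(image: np.ndarray, path: str | Path) -> None:
    """Average-intensity maps keep full precision: 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_section(section: SectionImage, outdir: str | Path,
                  stem: str) -> dict:
    """Write one section's channels + mask; returns its metadata row."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for marker, img in section.channels.items():
        write_channel_image(img, outdir / f"{stem}_{marker}.tif")
    write_mask(section.labels, section.label_table,
               outdir / f"{stem}_mask.tif", outdir / f"{stem}_mask.csv")
    return {
        "stem": stem,
        "animal": section.animal,
        "time_h": "" if section.time_h is None else section.time_h,
        "genotype": section.genotype,
        "section_position_um": section.section_position_um,
        "px_size_um": section.px_size_um,
        "channels": ",".join(sorted(section.channels)),
    }


def read_section(indir: str | Path, row: pd.Series) -> SectionImage:
    indir = Path(indir)
    stem = row["stem"]
    channels = {
        marker: read_channel_image(indir / f"{stem}_{marker}.tif")
        for marker in str(row["channels"]).split(",")
    }
    labels, table = read_mask(indir / f"{stem}_mask.tif",
                              indir / f"{stem}_mask.csv")
    t = row["time_h"]
    time_h = None if (pd.isna(t) or t == "") else float(t)
    return SectionImage(
        channels=channels, labels=labels, label_table=table,
        px_size_um=float(row["px_size_um"]),
        section_position_um=float(row["section_position_um"]),
        animal=str(row["animal"]), time_h=time_h,
        genotype=str(row["genotype"]),
    )
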