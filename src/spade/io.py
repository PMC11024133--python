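"""Readers and writers for the standard on-disk formats.

Spatial counts come either as a 10x-style Matrix Market triplet directory
(``matrix.mtx[.gz]`` plus ``features.tsv``/``genes.tsv`` and
``barcodes.tsv``) or as a dense gene x spot CSV; spot coordinates, cell
metadata, domain labels and proportion matrices are plain CSV tables.
"""

from __future__ import annotations

import gzip
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .model import SingleCellDataset, SpatialDataset

logger = logging.getLogger("spade")

__all__ = [
    "load_spatial",
    "load_single_cell",
    "write_proportions",
    "read_proportions",
    "write_spatial_mtx",
]


def _find_file(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / (stem + suffix)
            if cand.is_file():
                return cand
    raise FileNotFoundError(
        f"none of {stems} found in {directory} (searched with and without .gz)"
    )


def _read_tsv_column(path: Path, column: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[column] for line in fh if line.strip()]


def _load_counts(path: str | os.PathLike) -> tuple[list[str], list[str], np.ndarray]:
    """Read genes x columns counts from an MTX triplet directory or dense CSV."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"counts input not found: {p}")
    if p.is_dir():
        mtx = _find_file(p, ["matrix.mtx"])
        feat = _find_file(p, ["features.tsv", "genes.tsv"])
        bars = _find_file(p, ["barcodes.tsv"])
        counts = np.asarray(mmread(str(mtx)).todense(), dtype=float)
        gene_ids = _read_tsv_column(feat)
        col_ids = _read_tsv_column(bars)
        if counts.shape != (len(gene_ids), len(col_ids)):
            raise ValueError(
                f"matrix shape {counts.shape} does not match features/barcodes "
                f"({len(gene_ids)}, {len(col_ids)})"
            )
    else:
        df = pd.read_csv(p, index_col=0)
        gene_ids = [str(g) for g in df.index]
        col_ids = [str(c) for c in df.columns]
        counts = df.to_numpy(dtype=float)
    dup = pd.Index(gene_ids).duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene ids in {p}: first duplicate "
                         f"{gene_ids[int(np.flatnonzero(dup)[0])]!r}")
    return gene_ids, col_ids, counts


def load_spatial(path: str | os.PathLike, coords_path: str | os.PathLike) -> SpatialDataset:
    """Load a spatial dataset from counts plus a barcode -> coordinate table.

    The coordinate CSV needs a barcode column followed by two numeric
    columns; columns named ``x``/``y`` (pixel convention) are mapped to
    array (row, col) as y->row, x->col. Spots without a coordinate row are
    dropped with a warning; gene order is preserved from the counts file.
    """
    gene_ids, spot_ids, counts = _load_counts(path)
    cpath = Path(coords_path)
    if not cpath.is_file():
        raise FileNotFoundError(f"coordinates file not found: {cpath}")
    coords_df = pd.read_csv(cpath)
    if coords_df.shape[1] < 3:
        raise ValueError("coordinates file needs barcode plus two numeric columns")
    cols = [c.strip().lower() for c in coords_df.columns]
    barcode_col = coords_df.columns[0]
    if "x" in cols and "y" in cols:
        row_col = coords_df.columns[cols.index("y")]
        col_col = coords_df.columns[cols.index("x")]
    else:
        row_col, col_col = coords_df.columns[1], coords_df.columns[2]
    for name in (row_col, col_col):
        vals = pd.to_numeric(coords_df[name], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna())[0])
            raise ValueError(
                f"non-numeric coordinate in column {name!r} at data row {bad + 1}"
            )
    coord_map = {
        str(r[barcode_col]): (float(r[row_col]), float(r[col_col]))
        for _, r in coords_df.iterrows()
    }
    keep = [i for i, s in enumerate(spot_ids) if s in coord_map]
    dropped = len(spot_ids) - len(keep)
    if dropped:
        logger.warning("dropped %d spot(s) with no coordinate row", dropped)
    if not keep:
        raise ValueError("no spot barcode matches the coordinates file")
    spot_ids = [spot_ids[i] for i in keep]
    return SpatialDataset(
        gene_ids=gene_ids,
        spot_ids=spot_ids,
        counts=counts[:, keep],
        coords=np.array([coord_map[s] for s in spot_ids], dtype=float),
    )


def load_single_cell(
    path: str | os.PathLike, metadata_path: str | os.PathLike
) -> SingleCellDataset:
    """Load scRNA-seq counts plus a (cell id, cell type, sample id) table.

    Cells absent from the metadata are dropped with a warning; metadata rows
    for unknown cells are ignored silently.
    """
    gene_ids, cell_ids, counts = _load_counts(path)
    mpath = Path(metadata_path)
    if not mpath.is_file():
        raise FileNotFoundError(f"cell metadata file not found: {mpath}")
    meta = pd.read_csv(mpath)
    lower = {c.strip().lower(): c for c in meta.columns}
    type_col = next(
        (lower[k] for k in ("cell_type", "celltype", "type") if k in lower), None
    )
    if type_col is None:
        raise ValueError("metadata is missing a cell_type column")
    id_col = meta.columns[0]
    sample_col = next(
        (lower[k] for k in ("sample_id", "sample", "orig.ident") if k in lower), None
    )
    meta = meta.set_index(meta[id_col].astype(str))
    keep = [i for i, c in enumerate(cell_ids) if c in meta.index]
    dropped = len(cell_ids) - len(keep)
    if dropped:
        logger.warning("%d cell(s) dropped: missing from metadata", dropped)
    if not keep:
        raise ValueError("no overlap between count columns and metadata cell ids")
    cell_ids = [cell_ids[i] for i in keep]
    sample = (
        meta.loc[cell_ids, sample_col].astype(str).tolist()
        if sample_col is not None
        else ["sample0"] * len(cell_ids)
    )
    return SingleCellDataset(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=counts[:, keep],
        cell_type=meta.loc[cell_ids, type_col].astype(str).tolist(),
        sample_id=sample,
    )


def write_proportions(P, path: str | os.PathLike) -> None:
    """Write a ProportionMatrix to CSV with >= 6 significant digits."""
    df = pd.DataFrame(P.P, index=P.spot_ids, columns=P.cell_types)
    df.index.name = "spot_id"
    df.to_csv(path, float_format="%.10g")


def read_proportions(path: str | os.PathLike):
    """Read a proportion CSV written by :func:`write_proportions`."""
    from .deconvolve import ProportionMatrix

    df = pd.read_csv(path, index_col=0)
    return ProportionMatrix(
        spot_ids=[str(s) for s in df.index],
        cell_types=[str(c) for c in df.columns],
        P=df.to_numpy(dtype=float),
        objective_value=np.zeros(df.shape[0]),
    )


def write_spatial_mtx(ds: SpatialDataset, directory: str | os.PathLike) -> None:
    """Write a SpatialDataset as a 10x-style MTX triplet plus coords CSV."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mmwrite(str(d / "matrix.mtx"), coo_matrix(ds.counts))
    (d / "features.tsv").write_text("".join(f"{g}\n" for g in ds.gene_ids))
    (d / "barcodes.tsv").write_text("".join(f"{s}\n" for s in ds.spot_ids))
    pd.DataFrame(
        {"barcode": ds.spot_ids, "row": ds.coords[:, 0], "col": ds.coords[:, 1]}
    ).to_csv(d / "coords.csv", index=False)
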