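"""Readers and writers for Visium-style inputs.

Supported inputs: a MatrixMarket directory (matrix.mtx + barcodes.tsv +
features.tsv, 10x orientation genes × spots), a 10x-style HDF5
feature-barcode matrix, or plain CSV matrices; each paired with a
tissue_positions table (headered or legacy headerless dialect).
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .datasets import SpatialDataset


class FormatError(ValueError):
    """Missing or ill-formed input file."""


class AlignmentError(ValueError):
    """Barcode mismatch between the count matrix and the positions table."""


POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                    "pxl_row_in_fullres", "pxl_col_in_fullres"]


def _read_positions(path: Path) -> pd.DataFrame:
    """Read a tissue_positions CSV, headered or legacy headerless."""
    if not path.exists():
        raise FormatError(f"positions file not found: {path}")
    head = pd.read_csv(path, nrows=1, header=None)
    has_header = any(str(v).strip().lower() == "barcode" for v in head.iloc[0])
    if has_header:
        pos = pd.read_csv(path)
        pos.columns = [c.strip().lower() for c in pos.columns]
    else:
        pos = pd.read_csv(path, header=None)
        if pos.shape[1] != len(POSITION_COLUMNS):
            raise FormatError(
                f"headerless positions file {path} has {pos.shape[1]} columns, "
                f"expected {len(POSITION_COLUMNS)}")
        pos.columns = POSITION_COLUMNS
    if "barcode" not in pos.columns:
        raise FormatError(f"positions file {path} lacks a barcode column")
    pos["barcode"] = pos["barcode"].astype(str)
    return pos


def _find(path: Path, names: list[str], kind: str) -> Path:
    for name in names:
        cand = path / name
        if cand.exists():
            return cand
    raise FormatError(f"no {kind} file found in {path} (looked for {names})")


def _align(counts: sp.csr_matrix, barcodes: list[str], gene_ids: list[str],
           pos: pd.DataFrame) -> SpatialDataset:
    pos = pos.set_index("barcode")
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} barcode(s) in the count matrix are absent from "
            f"the positions table (first: {missing[:5]})")
    pos = pos.loc[barcodes]
    if {"pxl_row_in_fullres", "pxl_col_in_fullres"} <= set(pos.columns):
        coords = pos[["pxl_row_in_fullres", "pxl_col_in_fullres"]].to_numpy(float)
    elif {"x", "y"} <= set(pos.columns):
        coords = pos[["x", "y"]].to_numpy(float)
    else:
        raise FormatError("positions table has no recognized coordinate columns")
    in_tissue = (pos["in_tissue"].to_numpy(int).astype(bool)
                 if "in_tissue" in pos.columns else None)
    ds = SpatialDataset(counts=counts, coords=coords, spot_ids=barcodes,
                        gene_ids=gene_ids, in_tissue=in_tissue)
    if in_tissue is not None:
        ds = ds.subset(spot_mask=in_tissue)
        ds.in_tissue = np.ones(ds.n_spots, dtype=bool)
    return ds


def _read_tsv_column(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, dtype=str)


def load_visium(path, format: str = "mtx_dir",
                positions: str | os.PathLike | None = None) -> SpatialDataset:
    """Load a Visium-style dataset.

    Parameters
    ----------
    path
        Directory (``mtx_dir``), HDF5 file (``h5``), or CSV matrix (``csv``).
    format
        One of ``mtx_dir``, ``h5``, ``csv``.
    positions
        Path to the tissue positions CSV; defaults to
        ``<path dir>/tissue_positions.csv`` (or ``..._list.csv``).
    """
    path = Path(path)
    if format == "mtx_dir":
        if not path.is_dir():
            raise FormatError(f"not a directory: {path}")
        mtx = _find(path, ["matrix.mtx"], "matrix")
        bc = _find(path, ["barcodes.tsv"], "barcodes")
        ft = _find(path, ["features.tsv", "genes.tsv"], "features")
        try:
            mat = sp.csr_matrix(mmread(mtx))
        except Exception as exc:
            raise FormatError(f"could not parse MatrixMarket file {mtx}: {exc}")
        barcodes = _read_tsv_column(bc)[0].tolist()
        gene_ids = _read_tsv_column(ft)[0].tolist()
        if mat.shape != (len(gene_ids), len(barcodes)):
            raise FormatError(
                f"matrix {mtx} is {mat.shape}, expected "
                f"(genes={len(gene_ids)}, spots={len(barcodes)})")
        counts = mat.T.tocsr()  # 10x stores genes x spots
        base = path
    elif format == "h5":
        if not path.exists():
            raise FormatError(f"file not found: {path}")
        counts, barcodes, gene_ids = _read_10x_h5(path)
        base = path.parent
    elif format == "csv":
        if not path.exists():
            raise FormatError(f"file not found: {path}")
        df = pd.read_csv(path, index_col=0)
        counts = sp.csr_matrix(df.to_numpy(float))
        barcodes = [str(b) for b in df.index]
        gene_ids = [str(g) for g in df.columns]
        base = path.parent
    else:
        raise ValueError(f"unknown format: {format!r}")

    if positions is None:
        pos_path = None
        for name in ["tissue_positions.csv", "tissue_positions_list.csv",
                     "positions.csv"]:
            if (base / name).exists():
                pos_path = base / name
                break
        if pos_path is None:
            raise FormatError(f"no tissue positions CSV found under {base}")
    else:
        pos_path = Path(positions)
    pos = _read_positions(pos_path)
    return _align(counts, barcodes, gene_ids, pos)


# ---------------------------------------------------------------------------
# 10x-style HDF5


def _read_10x_h5(path: Path):
    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise FormatError(f"{path} lacks a 'matrix' group")
        grp = f["matrix"]
        shape = tuple(grp["shape"][:])  # genes x spots
        mat = sp.csc_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]), shape=shape)
        barcodes = [b.decode() for b in grp["barcodes"][:]]
        feat = grp["features"]["name" if "name" in grp["features"] else "id"]
        gene_ids = [g.decode() for g in feat[:]]
    return sp.csr_matrix(mat.T), barcodes, gene_ids


def write_10x_h5(ds: SpatialDataset, path) -> None:
    """Write counts in the 10x feature-barcode HDF5 layout (genes × spots CSC)."""
    m = sp.csc_matrix(ds.counts.T)
    with h5py.File(path, "w") as f:
        grp = f.create_group("matrix")
        grp.create_dataset("data", data=m.data.astype(np.int64))
        grp.create_dataset("indices", data=m.indices.astype(np.int64))
        grp.create_dataset("indptr", data=m.indptr.astype(np.int64))
        grp.create_dataset("shape", data=np.asarray(m.shape, dtype=np.int64))
        grp.create_dataset("barcodes",
                           data=np.array([s.encode() for s in ds.spot_ids]))
        ft = grp.create_group("features")
        ft.create_dataset("name",
                          data=np.array([g.encode() for g in ds.gene_ids]))


def write_mtx_dir(ds: SpatialDataset, path) -> None:
    """Write a MatrixMarket directory plus tissue_positions.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(ds.counts.T), field="integer")
    pd.Series(ds.spot_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                  index=False, header=False)
    pd.Series(ds.gene_ids).to_csv(path / "features.tsv", sep="\t",
                                  index=False, header=False)
    write_positions(ds, path / "tissue_positions.csv")


def write_positions(ds: SpatialDataset, path) -> None:
    n = ds.n_spots
    pos = pd.DataFrame({
        "barcode": ds.spot_ids,
        "in_tissue": (np.ones(n, dtype=int) if ds.in_tissue is None
                      else np.asarray(ds.in_tissue, dtype=int)),
        "array_row": np.zeros(n, dtype=int),
        "array_col": np.zeros(n, dtype=int),
        "pxl_row_in_fullres": ds.coords[:, 0],
        "pxl_col_in_fullres": ds.coords[:, 1],
    })
    pos.to_csv(path, index=False)


def write_csv(ds: SpatialDataset, matrix_path, positions_path=None) -> None:
    """Write the counts as a spots × genes CSV (plus positions)."""
    pd.DataFrame(np.asarray(ds.counts.todense(), dtype=int),
                 index=ds.spot_ids, columns=ds.gene_ids).to_csv(matrix_path)
    if positions_path is not None:
        write_positions(ds, positions_path)


def save_dataset(ds: SpatialDataset, path) -> None:
    """Persist a (possibly processed) dataset as .h5ad."""
    ds.to_anndata().write_h5ad(path)


def load_dataset(path) -> SpatialDataset:
    import anndata as ad

    return SpatialDataset.from_anndata(ad.read_h5ad(path))
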