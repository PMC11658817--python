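"""Core in-memory containers for spatial transcriptomics data."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp


def _to_csr(m) -> sp.csr_matrix:
    if sp.issparse(m):
        return m.tocsr()
    return sp.csr_matrix(np.asarray(m))


@dataclass
class SpatialDataset:
    """Spots × genes UMI counts plus spot coordinates.

    ``counts`` holds raw UMI counts (always retained); ``expr`` holds the
    log-normalized expression produced by :func:`spagae.preprocess.normalize_log`
    and is the model input.  Both are stored as CSR sparse matrices.
    """

    counts: sp.csr_matrix
    coords: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    expr: Optional[sp.csr_matrix] = None
    in_tissue: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = _to_csr(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = list(self.spot_ids)
        self.gene_ids = list(self.gene_ids)
        if self.expr is not None:
            self.expr = _to_csr(self.expr)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        n, g = self.counts.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with {n} spots")
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length inconsistent with counts rows")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length inconsistent with counts columns")
        if self.expr is not None and self.expr.shape != (n, g):
            raise ValueError("expr shape inconsistent with counts")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    def expr_dense(self) -> np.ndarray:
        if self.expr is None:
            raise ValueError("dataset has no normalized expression; "
                             "run normalize_log first")
        return np.asarray(self.expr.todense(), dtype=float)

    def subset(self, spot_mask=None, gene_mask=None) -> "SpatialDataset":
        """Return a row/column subset (boolean mask or index array), preserving order."""

        def as_index(mask, n):
            if mask is None:
                return np.arange(n)
            mask = np.asarray(mask)
            return np.flatnonzero(mask) if mask.dtype == bool else mask

        sm = as_index(spot_mask, self.n_spots)
        gm = as_index(gene_mask, self.n_genes)
        return SpatialDataset(
            counts=self.counts[sm][:, gm],
            coords=self.coords[sm],
            spot_ids=[self.spot_ids[i] for i in sm],
            gene_ids=[self.gene_ids[j] for j in gm],
            expr=None if self.expr is None else self.expr[sm][:, gm],
            in_tissue=None if self.in_tissue is None else np.asarray(self.in_tissue)[sm],
        )

    # ------------------------------------------------------------------
    def to_anndata(self):
        """Convert to an AnnData with counts in ``layers['counts']``."""
        import anndata as ad
        import pandas as pd

        X = self.expr if self.expr is not None else self.counts.astype(float)
        adata = ad.AnnData(
            X=X.copy(),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.layers["counts"] = self.counts.copy()
        adata.obsm["spatial"] = self.coords.copy()
        if self.in_tissue is not None:
            adata.obs["in_tissue"] = np.asarray(self.in_tissue)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "SpatialDataset":
        counts = adata.layers.get("counts", adata.X)
        expr = adata.X if "counts" in adata.layers else None
        in_tissue = (np.asarray(adata.obs["in_tissue"])
                     if "in_tissue" in adata.obs else None)
        return cls(
            counts=_to_csr(counts),
            coords=np.asarray(adata.obsm["spatial"], dtype=float),
            spot_ids=list(map(str, adata.obs_names)),
            gene_ids=list(map(str, adata.var_names)),
            expr=None if expr is None else _to_csr(expr),
            in_tissue=in_tissue,
        )


@dataclass
class QcConfig:
    """Quality-control thresholds applied before normalization.

    The mito-fraction and genes-per-spot filters follow the stricter
    benchmarking protocol and are off by default (``strict=False``).
    """

    min_spots_per_gene: int = 3
    mito_prefixes: Sequence[str] = ("MT-", "mt-")
    drop_mito: bool = True
    max_mito_fraction: float = 0.15
    min_genes_per_spot: int = 100
    strict: bool = False
    deny_prefixes: Sequence[str] = ()
    target_sum: float = 1e4
    n_hvg: int = 3000

    def __post_init__(self):
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
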