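"""Quality control, normalization and highly-variable-gene selection.

The default pipeline drops mitochondrial genes and genes expressed in
fewer than three spots, log-normalizes per-spot totals to a common
target sum, and keeps the top 3000 genes by a dispersion-based
variability score.  The stricter benchmarking profile additionally
removes spots with >15% mitochondrial UMIs or fewer than 100 detected
genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .datasets import QcConfig, SpatialDataset


class DegenerateResultError(ValueError):
    """All spots or all genes were removed by filtering."""


def _gene_support(counts: sp.csr_matrix) -> np.ndarray:
    """Number of spots with count > 0 per gene."""
    return np.asarray((counts > 0).sum(axis=0)).ravel()


def _prefix_mask(gene_ids, prefixes) -> np.ndarray:
    return np.array([any(g.startswith(p) for p in prefixes) for g in gene_ids],
                    dtype=bool)


def qc_filter(ds: SpatialDataset, cfg: QcConfig | None = None) -> SpatialDataset:
    """Apply QC filters; iterated to a fixpoint so the operation is idempotent."""
    cfg = cfg or QcConfig()
    if ds.n_spots == 0 or ds.n_genes == 0:
        raise DegenerateResultError("empty dataset")

    current = ds
    for _ in range(20):
        counts = current.counts
        gene_mask = np.ones(current.n_genes, dtype=bool)
        if cfg.drop_mito and len(cfg.mito_prefixes):
            gene_mask &= ~_prefix_mask(current.gene_ids, cfg.mito_prefixes)
        if len(cfg.deny_prefixes):
            gene_mask &= ~_prefix_mask(current.gene_ids, cfg.deny_prefixes)

        spot_mask = np.ones(current.n_spots, dtype=bool)
        if cfg.strict:
            totals = np.asarray(counts.sum(axis=1)).ravel()
            mito = _prefix_mask(current.gene_ids, cfg.mito_prefixes)
            mito_counts = np.asarray(counts[:, mito].sum(axis=1)).ravel()
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
            spot_mask &= frac <= cfg.max_mito_fraction
            detected = np.asarray((counts > 0).sum(axis=1)).ravel()
            spot_mask &= detected >= cfg.min_genes_per_spot

        trimmed = current.subset(spot_mask=spot_mask, gene_mask=gene_mask)
        support = _gene_support(trimmed.counts)
        keep_genes = support >= cfg.min_spots_per_gene
        trimmed = trimmed.subset(gene_mask=keep_genes)

        if trimmed.n_spots == 0 or trimmed.n_genes == 0:
            raise DegenerateResultError(
                f"QC removed everything ({trimmed.n_spots} spots, "
                f"{trimmed.n_genes} genes remain)")
        if (trimmed.n_spots, trimmed.n_genes) == (current.n_spots, current.n_genes):
            return trimmed
        current = trimmed
    return current


def normalize_log(ds: SpatialDataset, target_sum: float = 1e4) -> SpatialDataset:
    """Per-spot total-count normalization followed by log1p.

    expr[i, j] = log(1 + counts[i, j] * target_sum / total_i).
    """
    totals = np.asarray(ds.counts.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = int((totals <= 0).sum())
        raise ValueError(
            f"{bad} spot(s) have zero total counts; run qc_filter first")
    scaled = ds.counts.multiply((target_sum / totals)[:, None]).tocsr()
    scaled.data = np.log1p(scaled.data)
    return SpatialDataset(counts=ds.counts, coords=ds.coords,
                          spot_ids=ds.spot_ids, gene_ids=ds.gene_ids,
                          expr=scaled, in_tissue=ds.in_tissue)


def hvg_scores(ds: SpatialDataset) -> np.ndarray:
    """Dispersion-based variability score per gene.

    Mean and dispersion (variance/mean) are computed on the linear scale of
    the normalized expression (expm1 of expr).  Genes never expressed score
    zero.  The score is a pure function of the gene's expression column, so
    duplicated genes tie exactly and selection is order-independent.
    """
    if ds.expr is None:
        raise ValueError("normalized expression required; run normalize_log first")
    X = ds.expr.copy()
    X.data = np.expm1(X.data)
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = np.maximum(ex2 - mean ** 2, 0.0) * n / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)


def select_hvg(ds: SpatialDataset, n_hvg: int = 3000) -> SpatialDataset:
    """Keep the top ``n_hvg`` genes by variability score.

    Ties are broken by gene identifier (lexicographically earlier wins), so
    the selected set is independent of input gene order.
    """
    if ds.n_genes <= n_hvg:
        if ds.n_genes < n_hvg:
            warnings.warn(
                f"requested {n_hvg} HVGs but only {ds.n_genes} genes present; "
                "keeping all", stacklevel=2)
        return ds
    score = hvg_scores(ds)
    ranked = sorted(range(ds.n_genes),
                    key=lambda j: (-score[j], ds.gene_ids[j]))
    keep = np.zeros(ds.n_genes, dtype=bool)
    keep[ranked[:n_hvg]] = True
    return ds.subset(gene_mask=keep)


def preprocess(ds: SpatialDataset, cfg: QcConfig | None = None) -> SpatialDataset:
    """qc_filter → normalize_log → select_hvg with the given configuration."""
    cfg = cfg or QcConfig()
    ds = qc_filter(ds, cfg)
    ds = normalize_log(ds, cfg.target_sum)
    return select_hvg(ds, cfg.n_hvg)
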