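"""Spatial neighbor graph (SNG) construction.

Spots are connected if their Euclidean distance is below a radius
cutoff (auto-tuned so the mean degree is as close as possible to six,
the Visium first-shell count) or by symmetrized k-nearest neighbors.
Edge weights follow w_ij = 1 - S_ij / max(S_i.), which vanishes for
each spot's farthest retained neighbor and for all neighbors on a
perfectly regular lattice; downstream attention learns its own
coefficients, so these weights serve diagnostics and the optional
distance-decay autocorrelation scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass
class SpatialGraph:
    n_spots: int
    neighbors: list[np.ndarray]        # per-spot neighbor indices (no self)
    adjacency: sp.csr_matrix           # boolean, symmetric, no self loops
    weights: sp.csr_matrix             # distance-decay weights in [0, 1]
    distances: sp.csr_matrix           # pairwise distances on edges
    rad_cutoff: float | None
    mode: str

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def n_isolated(self) -> int:
        return int((self.degrees == 0).sum())


def tune_rad_cutoff(coords: np.ndarray, target_avg: float = 6.0,
                    k_max: int = 30) -> float:
    """Choose the radius cutoff whose mean neighbor count is closest to target.

    Candidate cutoffs are midpoints between consecutive distinct neighbor
    distances (plus one below the smallest and one above the largest), so the
    neighbor relation "distance < cutoff" is stable under floating-point
    jitter.  Ties prefer the smaller cutoff; the search is deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to tune a cutoff")
    if target_avg <= 0:
        raise ValueError("target_avg must be positive")
    tree = cKDTree(coords)
    k = min(n, k_max + 1)
    dists, _ = tree.query(coords, k=k)
    dists = dists[:, 1:]  # drop self
    finite = dists[np.isfinite(dists)]
    if finite.size == 0 or finite.max() == 0:
        raise ValueError("degenerate coordinates: all spots coincide")
    flat = np.sort(finite[finite > 0])
    uniq = np.unique(np.round(flat, 9))
    cands = np.concatenate([[uniq[0] / 2.0],
                            (uniq[:-1] + uniq[1:]) / 2.0,
                            [uniq[-1] * 1.5]])
    mean_deg = np.searchsorted(flat, cands, side="left") / n
    err = np.abs(mean_deg - target_avg)
    best = int(np.argmin(err))  # argmin takes the first (smallest cutoff) tie
    return float(cands[best])


def build_sng(coords: np.ndarray, rad_cutoff: float | None = None,
              mode: str = "radius", k: int = 6,
              target_avg: float = 6.0) -> SpatialGraph:
    """Build the spatial neighbor graph.

    radius mode: neighbors iff distance < rad_cutoff (tuned when None);
    knn mode: k nearest neighbors, symmetrized by union.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = coords.shape[0]
    tree = cKDTree(coords)

    if mode == "radius":
        if rad_cutoff is None:
            rad_cutoff = tune_rad_cutoff(coords, target_avg=target_avg)
        if rad_cutoff <= 0:
            raise ValueError("rad_cutoff must be positive")
        pairs = tree.query_pairs(r=rad_cutoff, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            strict = d < rad_cutoff
            pairs, d = pairs[strict], d[strict]
        else:
            d = np.empty(0)
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.empty(0, int)
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.empty(0, int)
        dd = np.concatenate([d, d]) if len(pairs) else np.empty(0)
    elif mode == "knn":
        if k < 1:
            raise ValueError("k must be >= 1")
        kk = min(n - 1, k)
        dists, idx = tree.query(coords, k=kk + 1)
        rows = np.repeat(np.arange(n), kk)
        cols = idx[:, 1:].ravel()
        dd = dists[:, 1:].ravel()
        # symmetrize by union
        a = sp.coo_matrix((dd, (rows, cols)), shape=(n, n)).tocsr()
        b = a.maximum(a.T).tocoo()
        rows, cols, dd = b.row, b.col, b.data
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    dist = sp.csr_matrix((dd, (rows, cols)), shape=(n, n))
    adjacency = sp.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                              shape=(n, n))
    adjacency.sum_duplicates()
    adjacency.data[:] = 1

    # Eq-style decay weights: w_ij = 1 - d_ij / max_j d_ij per row
    wdat = np.zeros(len(dd))
    indptr = dist.indptr
    for i in range(n):
        seg = slice(indptr[i], indptr[i + 1])
        row_d = dist.data[seg]
        if row_d.size:
            w = 1.0 - row_d / row_d.max()
            w[w < 1e-12] = 0.0  # equidistant/max-distance neighbors: exactly 0
            wdat[seg] = w
    weights = sp.csr_matrix((wdat, dist.indices.copy(), dist.indptr.copy()),
                            shape=(n, n))

    neighbors = [dist.indices[dist.indptr[i]:dist.indptr[i + 1]].copy()
                 for i in range(n)]
    g = SpatialGraph(n_spots=n, neighbors=neighbors, adjacency=adjacency,
                     weights=weights, distances=dist,
                     rad_cutoff=rad_cutoff if mode == "radius" else None,
                     mode=mode)
    iso = g.n_isolated()
    if iso:
        logger.warning("%d isolated spot(s) in the spatial graph", iso)
    return g


def autocorr_weights(g: SpatialGraph, scheme: str = "binary") -> sp.csr_matrix:
    """Symmetric spatial weights for Moran's I / Geary's C."""
    if scheme == "binary":
        W = g.adjacency.astype(float)
    elif scheme == "eq1":
        W = g.weights.astype(float)
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")
    return ((W + W.T) * 0.5).tocsr()


def export_edges(g: SpatialGraph, path) -> None:
    """Edge-list TSV (i, j, distance, weight) for inspection."""
    coo = g.distances.tocoo()
    w = np.asarray(g.weights[coo.row, coo.col]).ravel()
    pd.DataFrame({"i": coo.row, "j": coo.col,
                  "distance": coo.data, "weight": w}).to_csv(
        path, sep="\t", index=False)


def import_edges(path, n_spots: int) -> SpatialGraph:
    """Rebuild a SpatialGraph from an exported edge-list TSV."""
    df = pd.read_csv(path, sep="\t")
    n = n_spots
    dist = sp.csr_matrix((df["distance"], (df["i"], df["j"])), shape=(n, n))
    weights = sp.csr_matrix((df["weight"], (df["i"], df["j"])), shape=(n, n))
    adjacency = sp.csr_matrix(
        (np.ones(len(df), dtype=np.int8), (df["i"], df["j"])), shape=(n, n))
    neighbors = [dist.indices[dist.indptr[i]:dist.indptr[i + 1]].copy()
                 for i in range(n)]
    return SpatialGraph(n_spots=n, neighbors=neighbors, adjacency=adjacency,
                        weights=weights, distances=dist, rad_cutoff=None,
                        mode="imported")
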