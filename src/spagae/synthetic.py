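"""Synthetic Visium-like data with known ground truth.

Spots sit on an offset-row hexagonal lattice (interior spots have six
equidistant neighbors).  K spatially contiguous domains are planted by
seeded multi-source region growing over the lattice adjacency.  Counts
are negative binomial with a shared shape (size) parameter; background
genes share one mean everywhere, and each planted SVG has its mean
multiplied by ``fold_change`` inside its home domain.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import SpatialDataset
from .graph import build_sng


@dataclass
class SimConfig:
    n_rows: int = 20
    n_cols: int = 20
    spacing: float = 1.0
    n_domains: int = 4
    n_genes: int = 200
    n_svg_per_domain: int = 10
    base_mean: float = 1.0
    fold_change: float = 4.0
    dispersion: float = 4.0       # NB shape: var = mu + mu^2 / dispersion
    noise_seed: int = 0

    def __post_init__(self):
        if self.n_domains > self.n_rows * self.n_cols:
            raise ValueError("more domains than spots")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SimTruth:
    true_labels: np.ndarray
    true_svg: dict[int, list[str]]

    def all_svgs(self) -> set[str]:
        return {g for genes in self.true_svg.values() for g in genes}


def make_lattice(n_rows: int, n_cols: int, spacing: float = 1.0) -> np.ndarray:
    """Offset-row hexagonal lattice; interior degree 6 at distance = spacing."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols),
                             indexing="ij")
    x = (cols + 0.5 * (rows % 2)) * spacing
    y = rows * spacing * np.sqrt(3.0) / 2.0
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def plant_domains(coords: np.ndarray, K: int, seed: int = 0,
                  spacing: float | None = None) -> np.ndarray:
    """K contiguous domains (labels 1..K) by multi-source BFS region growing."""
    n = coords.shape[0]
    if K > n:
        raise ValueError("more domains than spots")
    if K == 1:
        return np.ones(n, dtype=int)
    if spacing is None:
        from scipy.spatial import cKDTree
        d, _ = cKDTree(coords).query(coords, k=2)
        spacing = float(np.median(d[:, 1]))
    g = build_sng(coords, rad_cutoff=spacing * 1.01, mode="radius")

    rng = np.random.default_rng(seed)
    seeds = rng.choice(n, size=K, replace=False)
    labels = np.zeros(n, dtype=int)
    queues = [deque([s]) for s in seeds]
    for k, s in enumerate(seeds):
        labels[s] = k + 1
    remaining = n - K
    while remaining > 0:
        progressed = False
        for k in range(K):
            q = queues[k]
            while q:
                node = q.popleft()
                nxt = [j for j in g.neighbors[node] if labels[j] == 0]
                if nxt:
                    j = nxt[0]
                    labels[j] = k + 1
                    q.append(node)
                    q.append(j)
                    remaining -= 1
                    progressed = True
                    break
        if not progressed:
            # disconnected leftovers: attach to nearest labeled spot
            left = np.flatnonzero(labels == 0)
            done = np.flatnonzero(labels > 0)
            for i in left:
                d = np.linalg.norm(coords[done] - coords[i], axis=1)
                labels[i] = labels[done[np.argmin(d)]]
            remaining = 0
    return labels


def simulate_counts(coords: np.ndarray, labels: np.ndarray,
                    cfg: SimConfig) -> tuple[SpatialDataset, SimTruth]:
    """Negative-binomial counts with domain-enriched planted SVGs."""
    rng = np.random.default_rng(cfg.noise_seed)
    n = coords.shape[0]
    gene_ids = [f"gene{j:04d}" for j in range(cfg.n_genes)]
    spot_ids = [f"spot{i:04d}" for i in range(n)]

    mu = np.full((n, cfg.n_genes), cfg.base_mean, dtype=float)
    true_svg: dict[int, list[str]] = {}
    gene_cursor = 0
    for domain in sorted(np.unique(labels)):
        picked = []
        for _ in range(cfg.n_svg_per_domain):
            if gene_cursor >= cfg.n_genes:
                break
            j = gene_cursor
            gene_cursor += 1
            mu[labels == domain, j] *= cfg.fold_change
            picked.append(gene_ids[j])
        true_svg[int(domain)] = picked

    r = cfg.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    ds = SpatialDataset(counts=sp.csr_matrix(counts), coords=coords,
                        spot_ids=spot_ids, gene_ids=gene_ids)
    return ds, SimTruth(true_labels=np.asarray(labels, dtype=int),
                        true_svg=true_svg)


def simulate_dataset(cfg: SimConfig | None = None
                     ) -> tuple[SpatialDataset, SimTruth]:
    """Lattice → contiguous domains → NB counts, in one call."""
    cfg = cfg or SimConfig()
    coords = make_lattice(cfg.n_rows, cfg.n_cols, cfg.spacing)
    labels = plant_domains(coords, cfg.n_domains, seed=cfg.noise_seed,
                           spacing=cfg.spacing)
    return simulate_counts(coords, labels, cfg)


def write_fixture(ds: SpatialDataset, truth: SimTruth, path) -> None:
    """Write the MTX + positions dialect the loader reads, plus truth CSVs."""
    from .io import write_mtx_dir

    path = Path(path)
    write_mtx_dir(ds, path)
    pd.DataFrame({"barcode": ds.spot_ids,
                  "domain": truth.true_labels}).to_csv(
        path / "truth_labels.csv", index=False)
    rows = [(d, g) for d, genes in truth.true_svg.items() for g in genes]
    pd.DataFrame(rows, columns=["domain", "gene_id"]).to_csv(
        path / "truth_svgs.csv", index=False)
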