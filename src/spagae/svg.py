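"""Domain-restricted detection of spatially variable genes (SVGs).

For each spatial domain the detector compares expression of domain
member spots against the union of the domain's first- and second-order
neighborhoods in the spatial graph (Wilcoxon rank-sum on log-normalized
expression, Benjamini–Hochberg adjusted per domain).  A gene is
reported as an SVG for a domain when all four filters hold:

* adjusted p-value < 0.05,
* Moran's I > 0 (positive spatial autocorrelation),
* expressed in more than 80% of the domain's spots,
* mean expression percentage in the domain exceeds both neighborhood
  means (optionally by a fold-change margin).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .autocorr import AutocorrResult, score_genes
from .datasets import SpatialDataset
from .domains import DomainLabels
from .graph import SpatialGraph

logger = logging.getLogger(__name__)


@dataclass
class SvgConfig:
    alpha: float = 0.05
    min_in_domain_frac: float = 0.8
    min_fold_change: float = 1.0
    frac_mode: str = "domain"     # 'domain': share of member spots expressing;
                                  # 'global': share of expressing spots in domain
    bh_scope: str = "domain"      # 'domain' or 'global' BH adjustment
    weight_scheme: str = "binary"
    exact_max_n: int = 12


@dataclass
class NeighborhoodSets:
    domain: int
    members: np.ndarray
    first_order: np.ndarray
    second_order: np.ndarray


def domain_neighbors(g: SpatialGraph, labels: DomainLabels,
                     domain: int) -> NeighborhoodSets:
    """BFS rings 1 and 2 around a domain in the spatial graph."""
    members = labels.members(domain)
    if members.size == 0:
        raise ValueError(f"domain {domain} has no member spots")
    n = g.n_spots
    in_members = np.zeros(n, dtype=bool)
    in_members[members] = True

    adj = g.adjacency
    reach1 = np.asarray(adj[members].sum(axis=0)).ravel() > 0
    first = np.flatnonzero(reach1 & ~in_members)

    in_first = np.zeros(n, dtype=bool)
    in_first[first] = True
    if first.size:
        reach2 = np.asarray(adj[first].sum(axis=0)).ravel() > 0
        second = np.flatnonzero(reach2 & ~in_members & ~in_first)
    else:
        second = np.empty(0, dtype=int)
    if first.size == 0 and members.size < n:
        logger.warning("domain %d has no spatial neighbors (isolated)", domain)
    return NeighborhoodSets(domain=domain, members=members,
                            first_order=first, second_order=second)


def expression_percentage(counts) -> np.ndarray:
    """Per-spot expression percentages: count_ij / Σ_j count_ij × 100."""
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts,
                       dtype=float)
    totals = dense.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("expression percentage undefined for zero-total spots")
    return dense / totals[:, None] * 100.0


def in_domain_fraction(ds: SpatialDataset, members: np.ndarray, gene: str,
                       mode: str = "domain") -> float:
    """Expression-density filter for the 80% rule.

    'domain' mode: fraction of member spots with count > 0 for the gene.
    'global' mode: fraction of all expressing spots that lie in the domain.
    """
    j = ds.gene_ids.index(gene)
    col = np.asarray((ds.counts[:, j] > 0).todense()).ravel()
    if mode == "domain":
        return float(col[members].mean()) if members.size else 0.0
    if mode == "global":
        total = col.sum()
        return float(col[members].sum() / total) if total else 0.0
    raise ValueError(f"unknown mode {mode!r}")


def wilcoxon_rank_sum(a, b, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the pooled sample is small (≤ ``exact_max_n``)
    and tie-free; otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= exact_max_n and tie_free) \
        else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided",
                              method=method, use_continuity=True).pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detect_svgs(ds: SpatialDataset, g: SpatialGraph, labels: DomainLabels,
                ac: AutocorrResult | None = None,
                cfg: SvgConfig | None = None) -> pd.DataFrame:
    """Per-domain SVG table with all filter columns and flags.

    Returns one row per (domain, gene); use :func:`summarize_svgs` for the
    deduplicated gene-level set.
    """
    cfg = cfg or SvgConfig()
    if ac is None:
        ac = score_genes(ds, g, scheme=cfg.weight_scheme)
    moran = ac.table["morans_i"].to_numpy()

    expr = ds.expr_dense()
    counts_dense = np.asarray(ds.counts.todense(), dtype=float)
    pct = expression_percentage(ds.counts)
    expressed = counts_dense > 0
    gene_ids = np.asarray(ds.gene_ids)

    rows = []
    for domain in labels.domains:
        nb = domain_neighbors(g, labels, domain)
        comparison = np.concatenate([nb.first_order, nb.second_order])
        if comparison.size == 0:
            warnings.warn(f"domain {domain} has empty neighborhoods; skipped",
                          stacklevel=2)
            continue
        m = nb.members
        if cfg.frac_mode == "domain":
            frac = expressed[m].mean(axis=0)
        else:
            tot = expressed.sum(axis=0)
            frac = np.divide(expressed[m].sum(axis=0), tot,
                             out=np.zeros(len(gene_ids)), where=tot > 0)
        pct_target = pct[m].mean(axis=0)
        pct_n1 = pct[nb.first_order].mean(axis=0) if nb.first_order.size \
            else np.zeros(len(gene_ids))
        pct_n2 = pct[nb.second_order].mean(axis=0) if nb.second_order.size \
            else np.zeros(len(gene_ids))

        tested = np.flatnonzero(frac > cfg.min_in_domain_frac)
        pvals = np.full(len(gene_ids), np.nan)
        for j in tested:
            pvals[j] = wilcoxon_rank_sum(expr[m, j], expr[comparison, j],
                                         cfg.exact_max_n)
        padj = np.full(len(gene_ids), np.nan)
        if cfg.bh_scope == "domain" and tested.size:
            padj[tested] = bh_adjust(pvals[tested])

        rows.append(pd.DataFrame({
            "gene_id": gene_ids,
            "domain": domain,
            "expr_pct_target": pct_target,
            "expr_pct_nbr1": pct_n1,
            "expr_pct_nbr2": pct_n2,
            "in_domain_frac": frac,
            "morans_i": moran,
            "p_value": pvals,
            "p_adj": padj,
        }))

    if not rows:
        return pd.DataFrame(columns=[
            "gene_id", "domain", "expr_pct_target", "expr_pct_nbr1",
            "expr_pct_nbr2", "in_domain_frac", "morans_i", "p_value",
            "p_adj", "is_svg"])
    table = pd.concat(rows, ignore_index=True)

    if cfg.bh_scope == "global":
        mask = table["p_value"].notna().to_numpy()
        adj = np.full(len(table), np.nan)
        if mask.any():
            adj[mask] = bh_adjust(table.loc[mask, "p_value"].to_numpy())
        table["p_adj"] = adj

    higher = (table["expr_pct_target"].to_numpy()
              > cfg.min_fold_change * np.maximum(
                  table["expr_pct_nbr1"].to_numpy(),
                  table["expr_pct_nbr2"].to_numpy()))
    with np.errstate(invalid="ignore"):
        table["is_svg"] = (
            (table["p_adj"].to_numpy() < cfg.alpha)
            & (table["morans_i"].to_numpy() > 0)
            & (table["in_domain_frac"].to_numpy() > cfg.min_in_domain_frac)
            & higher
        )
    table["is_svg"] = table["is_svg"].fillna(False).astype(bool)
    return table


def summarize_svgs(table: pd.DataFrame) -> pd.DataFrame:
    """Dataset-level SVG set, deduplicated by gene across domains."""
    hits = table[table["is_svg"]]
    if hits.empty:
        return pd.DataFrame(columns=["gene_id", "n_domains", "domains",
                                     "best_p_adj", "morans_i"])
    grouped = hits.groupby("gene_id", sort=True)
    return pd.DataFrame({
        "gene_id": list(grouped.groups),
        "n_domains": grouped.size().to_numpy(),
        "domains": [",".join(map(str, sorted(sub["domain"])))
                    for _, sub in grouped],
        "best_p_adj": grouped["p_adj"].min().to_numpy(),
        "morans_i": grouped["morans_i"].first().to_numpy(),
    })


class SVGDetector:
    """Estimator-style wrapper: ``fit`` stores ``results_``/``summary_``."""

    def __init__(self, alpha=0.05, min_in_domain_frac=0.8,
                 min_fold_change=1.0, frac_mode="domain",
                 bh_scope="domain", weight_scheme="binary"):
        self.alpha = alpha
        self.min_in_domain_frac = min_in_domain_frac
        self.min_fold_change = min_fold_change
        self.frac_mode = frac_mode
        self.bh_scope = bh_scope
        self.weight_scheme = weight_scheme

    def _config(self) -> SvgConfig:
        return SvgConfig(alpha=self.alpha,
                         min_in_domain_frac=self.min_in_domain_frac,
                         min_fold_change=self.min_fold_change,
                         frac_mode=self.frac_mode, bh_scope=self.bh_scope,
                         weight_scheme=self.weight_scheme)

    def fit(self, ds: SpatialDataset, g: SpatialGraph, labels: DomainLabels,
            ac: AutocorrResult | None = None):
        self.results_ = detect_svgs(ds, g, labels, ac, self._config())
        self.summary_ = summarize_svgs(self.results_)
        return self

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("alpha", "min_in_domain_frac", "min_fold_change",
                 "frac_mode", "bh_scope", "weight_scheme")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
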