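"""Spatial domain assignment by Gaussian-mixture clustering.

Emulates model-based clustering (mclust-style): a full-covariance
Gaussian mixture fit by EM with multiple restarts, with BIC used to
select the number of domains when a range of candidates is given.  By
default clustering runs on the decoder-reconstructed expression reduced
to 20 principal components (a graph-smoothed, denoised view of the
data); the latent embedding is available as an alternative clustering
space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture


@dataclass
class DomainLabels:
    labels: np.ndarray     # per-spot domain in {1..K}
    K: int
    source: str
    bic: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise ValueError("labels must lie in {1..K}")

    def members(self, domain: int) -> np.ndarray:
        return np.flatnonzero(self.labels == domain)

    @property
    def domains(self) -> list[int]:
        return sorted(np.unique(self.labels).tolist())


def _fit_gmm(X: np.ndarray, k: int, seed: int) -> GaussianMixture:
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         n_init=10, reg_covar=1e-6, random_state=seed,
                         max_iter=300)
    try:
        gm.fit(X)
    except ValueError:
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=10, reg_covar=1e-3, random_state=seed,
                             max_iter=300)
        gm.fit(X)
    return gm


def cluster_domains(emb, K: Union[int, Iterable[int]],
                    source: str = "reconstruction", seed: int = 0) -> DomainLabels:
    """Cluster spots into K spatial domains.

    ``emb`` may be an EmbeddingResult or a raw (spots × dims) array.  With an
    integer K that many domains are fit; with an iterable of candidates, the
    K minimizing BIC is chosen.
    """
    if hasattr(emb, "latent"):
        X = emb.latent if source == "latent" else emb.reconstruction
    else:
        X = np.asarray(emb, dtype=float)
    if source == "reconstruction" and X.shape[1] > 20:
        X = PCA(n_components=20, random_state=seed).fit_transform(X)
    X = np.asarray(X, dtype=float)

    if np.isscalar(K):
        K = int(K)
        if K < 2:
            raise ValueError("number of domains must be >= 2")
        gm = _fit_gmm(X, K, seed)
        return DomainLabels(labels=gm.predict(X) + 1, K=K, source=source,
                            bic=float(gm.bic(X)))

    candidates = sorted(int(k) for k in K)
    if not candidates or min(candidates) < 2:
        raise ValueError("candidate domain numbers must be >= 2")
    best = None
    for k in candidates:
        gm = _fit_gmm(X, k, seed)
        bic = float(gm.bic(X))
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    bic, k, gm = best
    return DomainLabels(labels=gm.predict(X) + 1, K=k, source=source, bic=bic)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions."""
    labels_a = np.asarray(labels_a).ravel()
    labels_b = np.asarray(labels_b).ravel()
    if labels_a.size != labels_b.size:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(labels_a, labels_b))


def plot_domains(coords: np.ndarray, labels: np.ndarray, path) -> None:
    """2-D scatter of spots colored by domain (visual QC)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 6))
    for lab in np.unique(labels):
        m = labels == lab
        ax.scatter(coords[m, 0], coords[m, 1], s=12, label=str(lab))
    ax.set_aspect("equal")
    ax.legend(title="domain", fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


class DomainClusterer(ClusterMixin, BaseEstimator):
    """Gaussian-mixture domain assignment as an sklearn clusterer.

    ``n_domains`` is an int, or an iterable of candidates scanned by BIC.
    """

    def __init__(self, n_domains=7, source="reconstruction", random_state=0):
        self.n_domains = n_domains
        self.source = source
        self.random_state = random_state

    def fit(self, X, y=None):
        res = cluster_domains(X, self.n_domains, source=self.source,
                              seed=self.random_state)
        self.labels_ = res.labels
        self.n_domains_ = res.K
        self.bic_ = res.bic
        self.result_ = res
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
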