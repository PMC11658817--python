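"""Stacked graph attention auto-encoder for spatial expression data.

The encoder aggregates each spot's neighborhood (including the spot
itself) with learned attention coefficients

    e_ij = sigmoid(v_s' σ(W h_i) + v_r' σ(W h_j)),
    α_ij = softmax_j(e_ij),
    h_i  = Σ_j α_ij σ(W h_j),

and a mirrored decoder reconstructs the normalized expression.  The
training objective is the sum of per-spot L2 reconstruction errors plus
λ times a negative log-sigmoid graph-structure term over stored edges:

    Loss = Σ_i ||x_i - x̂_i||₂ - λ Σ_i Σ_{j ∈ N_i} log σ(h_i' h_j).

An optional refinement mixes the learned attention with a uniform
neighborhood prior: (1 - a)·α + a·u, sharpening spatial-domain
boundaries on low-resolution arrays at the cost of attention
flexibility (off by default, a = 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import _tape as T
from .datasets import SpatialDataset
from .graph import SpatialGraph

logger = logging.getLogger(__name__)

_NUMPY_ACT = {
    "elu": lambda x: np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))),
    "relu": lambda x: np.maximum(x, 0.0),
    "identity": lambda x: x,
}


@dataclass
class GaaeConfig:
    """Hyperparameters of the graph attention auto-encoder."""

    layer_dims: tuple[int, ...] = (512, 30)
    lambda_struct: float = 0.1
    activation: str = "elu"
    epochs: int = 500
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    seed: int = 0
    alpha_refine: float = 0.0
    gradient_clip: float = 5.0
    tie_weights: bool = False

    def __post_init__(self):
        self.layer_dims = tuple(int(d) for d in self.layer_dims)
        if len(self.layer_dims) < 1 or any(d < 1 for d in self.layer_dims):
            raise ValueError("layer_dims must be >= 1 entries of positive ints")
        if not (0.0 <= self.alpha_refine <= 1.0):
            raise ValueError("alpha_refine must lie in [0, 1]")
        if self.lambda_struct < 0:
            raise ValueError("lambda_struct must be >= 0")
        if self.activation not in _NUMPY_ACT:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class GaaeModel:
    """Trained parameters: per-layer W, v_s, v_r and decoder counterparts."""

    enc_W: list[np.ndarray]
    enc_vs: list[np.ndarray]
    enc_vr: list[np.ndarray]
    dec_W: list[np.ndarray]
    dec_vs: list[np.ndarray]
    dec_vr: list[np.ndarray]
    config: GaaeConfig

    @property
    def n_layers(self) -> int:
        return len(self.enc_W)


@dataclass
class EmbeddingResult:
    latent: np.ndarray
    reconstruction: np.ndarray
    attention: list[sp.csr_matrix]
    loss_history: list[float]
    attention_rowsum_dev: float = 0.0


# ---------------------------------------------------------------------------
# attention edges


def attention_edges(g: SpatialGraph) -> tuple[np.ndarray, np.ndarray]:
    """Directed (receiver i, sender j) pairs over N_i ∪ {i}, sorted by i."""
    coo = g.adjacency.tocoo()
    n = g.n_spots
    i_idx = np.concatenate([coo.row, np.arange(n)])
    j_idx = np.concatenate([coo.col, np.arange(n)])
    order = np.lexsort((j_idx, i_idx))
    return i_idx[order], j_idx[order]


def _edges_to_csr(vals, i_idx, j_idx, n) -> sp.csr_matrix:
    return sp.csr_matrix((np.asarray(vals).ravel(), (i_idx, j_idx)), shape=(n, n))


# ---------------------------------------------------------------------------
# spec-level operations (plain NumPy; the training path goes through the tape
# and is checked against these in the tests)


def attention_scores(h_prev: np.ndarray, W: np.ndarray, vs: np.ndarray,
                     vr: np.ndarray, g: SpatialGraph,
                     activation: str = "elu") -> sp.csr_matrix:
    """Raw attention relevance e_ij on N_i ∪ {i}; values in (0, 1)."""
    if not (np.all(np.isfinite(h_prev)) and np.all(np.isfinite(W))):
        raise ValueError("non-finite inputs to attention_scores")
    act = _NUMPY_ACT[activation]
    z = act(h_prev @ W.T)
    s = z @ np.asarray(vs).ravel()
    r = z @ np.asarray(vr).ravel()
    i_idx, j_idx = attention_edges(g)
    e = expit(s[i_idx] + r[j_idx])
    return _edges_to_csr(e, i_idx, j_idx, g.n_spots)


def normalize_attention(e: sp.csr_matrix, g: SpatialGraph) -> sp.csr_matrix:
    """Row-wise softmax of e over each stored neighborhood."""
    e = e.tocsr()
    out = e.copy().astype(float)
    for i in range(e.shape[0]):
        seg = slice(e.indptr[i], e.indptr[i + 1])
        row = e.data[seg]
        if row.size == 0:
            raise RuntimeError(f"empty attention neighborhood for node {i}")
        w = np.exp(row - row.max())
        out.data[seg] = w / w.sum()
    return out


def refine_attention(alpha: sp.csr_matrix, g: SpatialGraph,
                     alpha_refine: float) -> sp.csr_matrix:
    """Mix learned attention with the uniform neighborhood prior."""
    if not (0.0 <= alpha_refine <= 1.0):
        raise ValueError("alpha_refine must lie in [0, 1]")
    alpha = alpha.tocsr()
    out = alpha.copy().astype(float)
    for i in range(alpha.shape[0]):
        seg = slice(alpha.indptr[i], alpha.indptr[i + 1])
        k = alpha.indptr[i + 1] - alpha.indptr[i]
        if k:
            out.data[seg] = ((1.0 - alpha_refine) * alpha.data[seg]
                             + alpha_refine / k)
    return out


def _propagate(alpha: sp.csr_matrix, z: np.ndarray) -> np.ndarray:
    return alpha @ z


def encoder_layer(h_prev: np.ndarray, params: dict, g: SpatialGraph,
                  activation: str = "elu",
                  alpha_refine: float = 0.0) -> tuple[np.ndarray, sp.csr_matrix]:
    """One encoder layer: h_i = Σ_{j∈N_i∪{i}} α_ij σ(W h_j)."""
    W, vs, vr = params["W"], params["vs"], params["vr"]
    e = attention_scores(h_prev, W, vs, vr, g, activation)
    alpha = normalize_attention(e, g)
    if alpha_refine > 0:
        alpha = refine_attention(alpha, g, alpha_refine)
    z = _NUMPY_ACT[activation](h_prev @ W.T)
    return _propagate(alpha, z), alpha


def decoder_layer(h_next: np.ndarray, params: dict, g: SpatialGraph,
                  activation: str = "elu",
                  alpha_refine: float = 0.0) -> tuple[np.ndarray, sp.csr_matrix]:
    """One decoder layer; identical structure with decoder parameters."""
    return encoder_layer(h_next, params, g, activation, alpha_refine)


def loss(x: np.ndarray, x_hat: np.ndarray, latent: np.ndarray,
         g: SpatialGraph, lambda_struct: float) -> float:
    """Feature reconstruction plus λ-weighted graph structure loss."""
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat shapes differ")
    feat = np.linalg.norm(x - x_hat, axis=1).sum()
    total = feat
    if lambda_struct > 0:
        coo = g.adjacency.tocoo()
        dots = np.einsum("ij,ij->i", latent[coo.row], latent[coo.col])
        struct = (-np.logaddexp(0.0, -dots)).sum()  # Σ log sigmoid(h_i·h_j)
        total = feat - lambda_struct * struct
    if not np.isfinite(total):
        raise FloatingPointError("non-finite loss")
    return float(total)


# ---------------------------------------------------------------------------
# differentiable forward pass


def _init_params(input_dim: int, cfg: GaaeConfig, rng: np.random.Generator):
    """Glorot-uniform matrices, zero attention vectors."""
    dims = (input_dim,) + cfg.layer_dims
    enc, dec = [], []
    for k in range(len(cfg.layer_dims)):
        d_in, d_out = dims[k], dims[k + 1]
        lim = np.sqrt(6.0 / (d_in + d_out))
        enc.append({
            "W": T.Tensor(rng.uniform(-lim, lim, size=(d_out, d_in))),
            "vs": T.Tensor(np.zeros((d_out, 1))),
            "vr": T.Tensor(np.zeros((d_out, 1))),
        })
    for k in reversed(range(len(cfg.layer_dims))):
        d_in, d_out = dims[k + 1], dims[k]   # decoder maps layer k -> k-1
        lim = np.sqrt(6.0 / (d_in + d_out))
        dec.append({
            "W": T.Tensor(rng.uniform(-lim, lim, size=(d_out, d_in))),
            "vs": T.Tensor(np.zeros((d_out, 1))),
            "vr": T.Tensor(np.zeros((d_out, 1))),
        })
    return enc, dec


def _tape_layer(H, layer, i_idx, j_idx, n, act_name, alpha_refine, inv_deg):
    act = T.ACTIVATIONS[act_name]
    W = (T.transpose(layer["tied_to"]) if "tied_to" in layer else layer["W"])
    Z = act(T.matmul(H, T.transpose(W)))
    s = T.matmul(Z, layer["vs"])               # (N, 1)
    r = T.matmul(Z, layer["vr"])
    e = T.sigmoid(T.add(T.take(s, i_idx), T.take(r, j_idx)))  # (E, 1)
    ex = T.exp(e)
    den = T.segment_sum(ex, i_idx, n)
    alpha = T.div(ex, T.take(den, i_idx))
    if alpha_refine > 0:
        alpha = T.add(T.mul(alpha, 1.0 - alpha_refine),
                      T.Tensor(alpha_refine * inv_deg))
    Hn = T.segment_sum(T.mul(alpha, T.take(Z, j_idx)), i_idx, n)
    return Hn, alpha


def _forward(X, enc, dec, i_idx, j_idx, n, cfg, inv_deg):
    H = T.Tensor(X)
    alphas = []
    for layer in enc:
        H, a = _tape_layer(H, layer, i_idx, j_idx, n, cfg.activation,
                           cfg.alpha_refine, inv_deg)
        alphas.append(a)
    latent = H
    for layer in dec:
        H, a = _tape_layer(H, layer, i_idx, j_idx, n, cfg.activation,
                           cfg.alpha_refine, inv_deg)
        alphas.append(a)
    return latent, H, alphas


def _tape_loss(Xt, latent, recon, adj_i, adj_j, lam):
    diff = T.sub(Xt, recon)
    feat = T.sum_all(T.sqrt0(T.sum_axis(T.mul(diff, diff), axis=1)))
    if lam > 0 and len(adj_i):
        hi = T.take(latent, adj_i)
        hj = T.take(latent, adj_j)
        dots = T.sum_axis(T.mul(hi, hj), axis=1)
        struct = T.sum_all(T.logsigmoid(dots))
        return T.sub(feat, T.mul(struct, lam))
    return feat


class _Adam:
    def __init__(self, params, lr, weight_decay):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, clip: float):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.value)
                 for p in self.params]
        if self.wd:
            grads = [g + self.wd * p.value
                     for g, p in zip(grads, self.params)]
        if clip and clip > 0:
            norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if norm > clip:
                grads = [g * (clip / norm) for g in grads]
        self.t += 1
        for k, (p, g) in enumerate(zip(self.params, grads)):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mh / (np.sqrt(vh) + self.eps)


def train(ds: SpatialDataset, g: SpatialGraph,
          cfg: GaaeConfig | None = None) -> tuple[GaaeModel, EmbeddingResult]:
    """Full-batch training; reproducible bit-for-bit for a fixed seed."""
    cfg = cfg or GaaeConfig()
    X = ds.expr_dense() if ds.expr is not None else np.asarray(
        ds.counts.todense(), dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")
    n = X.shape[0]
    if g.n_spots != n:
        raise ValueError("graph and dataset cover different numbers of spots")

    rng = np.random.default_rng(cfg.seed)
    enc, dec = _init_params(X.shape[1], cfg, rng)
    i_idx, j_idx = attention_edges(g)
    deg = np.bincount(i_idx, minlength=n).astype(float)
    inv_deg = (1.0 / deg[i_idx])[:, None]
    coo = g.adjacency.tocoo()
    adj_i, adj_j = coo.row, coo.col

    if cfg.tie_weights:
        # decoder layer reconstructing level k-1 shares W with encoder layer k
        for le, ld in zip(enc, reversed(dec)):
            ld["tied_to"] = le["W"]

    params = [layer["W"] for layer in enc]
    params += [layer["W"] for layer in dec if "tied_to" not in layer]
    params += [layer[key] for layer in enc + dec for key in ("vs", "vr")]
    opt = _Adam(params, cfg.learning_rate, cfg.weight_decay)

    history: list[float] = []
    rowsum_dev = 0.0

    def evaluate(epoch):
        nonlocal rowsum_dev
        latent, recon, alphas = _forward(X, enc, dec, i_idx, j_idx, n, cfg,
                                         inv_deg)
        total = _tape_loss(T.Tensor(X), latent, recon, adj_i, adj_j,
                           cfg.lambda_struct)
        val = float(total.value)
        if not np.isfinite(val):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {val}")
        history.append(val)
        for a in alphas:
            sums = np.bincount(i_idx, weights=a.value.ravel(), minlength=n)
            rowsum_dev = max(rowsum_dev, float(np.abs(sums - 1.0).max()))
        return latent, recon, alphas, total

    for epoch in range(cfg.epochs):
        *_, total = evaluate(epoch)
        T.backward(total)
        opt.step(cfg.gradient_clip)

    # final evaluation so the returned embedding matches the final weights
    latent, recon, alphas, _ = evaluate(cfg.epochs)
    latent_v, recon_v = latent.value.copy(), recon.value.copy()
    alphas_v = [a.value.copy() for a in alphas]

    model = GaaeModel(
        enc_W=[l["W"].value.copy() for l in enc],
        enc_vs=[l["vs"].value.ravel().copy() for l in enc],
        enc_vr=[l["vr"].value.ravel().copy() for l in enc],
        dec_W=[(l["tied_to"].value.T.copy() if "tied_to" in l
                else l["W"].value.copy()) for l in dec],
        dec_vs=[l["vs"].value.ravel().copy() for l in dec],
        dec_vr=[l["vr"].value.ravel().copy() for l in dec],
        config=cfg,
    )
    attn = [_edges_to_csr(a, i_idx, j_idx, n) for a in alphas_v]
    result = EmbeddingResult(latent=latent_v, reconstruction=recon_v,
                             attention=attn, loss_history=history,
                             attention_rowsum_dev=rowsum_dev)
    return model, result


def apply_model(model: GaaeModel, X: np.ndarray,
                g: SpatialGraph) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass of a trained model on (possibly new) data over a graph."""
    cfg = model.config
    H = np.asarray(X, dtype=float)
    for k in range(model.n_layers):
        params = {"W": model.enc_W[k], "vs": model.enc_vs[k],
                  "vr": model.enc_vr[k]}
        H, _ = encoder_layer(H, params, g, cfg.activation, cfg.alpha_refine)
    latent = H
    for k in range(model.n_layers):
        params = {"W": model.dec_W[k], "vs": model.dec_vs[k],
                  "vr": model.dec_vr[k]}
        H, _ = decoder_layer(H, params, g, cfg.activation, cfg.alpha_refine)
    return latent, H


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: GaaeModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in model.config.__dict__.items()})
        for side, Ws, vss, vrs in [("enc", model.enc_W, model.enc_vs, model.enc_vr),
                                   ("dec", model.dec_W, model.dec_vs, model.dec_vr)]:
            for k in range(len(Ws)):
                f.create_dataset(f"{side}/W{k}", data=Ws[k])
                f.create_dataset(f"{side}/vs{k}", data=vss[k])
                f.create_dataset(f"{side}/vr{k}", data=vrs[k])


def load_model(path) -> GaaeModel:
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config"])
        cfg = GaaeConfig(**cfg_dict)
        L = len(cfg.layer_dims)
        def grab(side):
            return ([f[f"{side}/W{k}"][:] for k in range(L)],
                    [f[f"{side}/vs{k}"][:] for k in range(L)],
                    [f[f"{side}/vr{k}"][:] for k in range(L)])
        eW, evs, evr = grab("enc")
        dW, dvs, dvr = grab("dec")
    return GaaeModel(enc_W=eW, enc_vs=evs, enc_vr=evr,
                     dec_W=dW, dec_vs=dvs, dec_vr=dvr, config=cfg)


# ---------------------------------------------------------------------------
# sklearn-style estimator


class GraphAttentionAutoencoder(TransformerMixin, BaseEstimator):
    """Graph attention auto-encoder as a transformer.

    fit(X, graph=...) trains on the full dataset (transductive, full batch);
    ``embedding_`` holds the latent representation, ``reconstruction_`` the
    decoded expression.  ``transform`` re-runs the trained forward pass.

    Parameters mirror :class:`GaaeConfig`.
    """

    def __init__(self, layer_dims=(512, 30), lambda_struct=0.1,
                 activation="elu", epochs=500, learning_rate=1e-4,
                 weight_decay=1e-4, alpha_refine=0.0, gradient_clip=5.0,
                 tie_weights=False, random_state=0):
        self.layer_dims = layer_dims
        self.lambda_struct = lambda_struct
        self.activation = activation
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.alpha_refine = alpha_refine
        self.gradient_clip = gradient_clip
        self.tie_weights = tie_weights
        self.random_state = random_state

    def _config(self) -> GaaeConfig:
        return GaaeConfig(
            layer_dims=tuple(self.layer_dims),
            lambda_struct=self.lambda_struct, activation=self.activation,
            epochs=self.epochs, learning_rate=self.learning_rate,
            weight_decay=self.weight_decay, seed=self.random_state,
            alpha_refine=self.alpha_refine, gradient_clip=self.gradient_clip,
            tie_weights=self.tie_weights)

    def fit(self, X, y=None, *, graph: SpatialGraph):
        X = np.asarray(X, dtype=float)
        ds = SpatialDataset(
            counts=sp.csr_matrix(np.zeros_like(X)), coords=np.zeros((X.shape[0], 2)),
            spot_ids=[str(i) for i in range(X.shape[0])],
            gene_ids=[str(j) for j in range(X.shape[1])],
            expr=sp.csr_matrix(X))
        self.model_, result = train(ds, graph, self._config())
        self.graph_ = graph
        self.embedding_ = result.latent
        self.reconstruction_ = result.reconstruction
        self.attention_ = result.attention
        self.loss_history_ = result.loss_history
        self.attention_rowsum_dev_ = result.attention_rowsum_dev
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).embedding_

    def transform(self, X, graph: SpatialGraph | None = None):
        check_is_fitted(self, "model_")
        latent, _ = apply_model(self.model_, X, graph or self.graph_)
        return latent
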