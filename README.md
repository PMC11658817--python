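# spagae

Spatial-domain clustering and spatially variable gene (SVG) detection for
spatial transcriptomics, built around a **graph attention auto-encoder**
over the spatial neighbor graph of a Visium-style slide.

## Who this is for

Analysts working with spot-based spatial transcriptomics (10x Visium and
similar platforms) who want to (1) partition a tissue section into
spatially coherent expression domains and (2) find genes whose expression
is specifically enriched in a domain relative to its immediate spatial
surroundings — rather than genes that are merely "spatially non-random"
somewhere on the slide.

## Method

**Spatial neighbor graph (SNG).** Spots *i*, *j* are connected when their
Euclidean distance S<sub>ij</sub> falls below a radius cutoff, auto-tuned so
the mean neighbor count is as close as possible to six (the Visium first
shell). Distance-decay edge weights
w<sub>ij</sub> = 1 − S<sub>ij</sub>/max(S<sub>i·</sub>) are computed for
diagnostics and an optional autocorrelation weighting scheme.

**Graph attention auto-encoder.** With h<sub>i</sub><sup>(0)</sup> = x<sub>i</sub>
(log-normalized expression), each encoder layer *k* computes

    e_ij = sigmoid(v_s' σ(W h_i) + v_r' σ(W h_j)),   j ∈ N_i ∪ {i}
    α_ij = softmax_j(e_ij)
    h_i  = Σ_j α_ij σ(W h_j)

and a mirrored decoder with its own parameters (Ŵ, v̂_s, v̂_r) reconstructs
x̂<sub>i</sub>. Training minimizes

    Loss = Σ_i ‖x_i − x̂_i‖₂ − λ Σ_i Σ_{j∈N_i} log σ(h_i' h_j)

by full-batch Adam (the second term ties embeddings of spatial neighbors
together; λ = 0.1 by default). An optional refinement mixes the learned
attention with a uniform neighborhood prior,
(1 − a)·α + a·u, which sharpens domain boundaries on low-resolution arrays.

**Domains.** The decoder-reconstructed expression (reduced to 20 principal
components) is clustered by a full-covariance Gaussian mixture (mclust-style
EM, 10 restarts); the number of domains is fixed when known or chosen by BIC.

**SVGs.** For each domain, genes are compared between domain spots and the
union of the domain's first- and second-order BFS neighborhoods in the SNG
(Wilcoxon rank-sum on log-normalized expression, Benjamini–Hochberg per
domain). A gene is an SVG for a domain when all of: adjusted p < 0.05,
Moran's I > 0, expressed in > 80% of domain spots, and its mean expression
percentage (count share per spot × 100) in the domain exceeds both
neighborhood means. Per-gene Moran's I and Geary's C quantify the spatial
coherence of the calls.

## Worked example

```python
from spagae.pipeline import run_synthetic_study

run = run_synthetic_study(seed=1)
print(f"ARI vs planted domains : {run['ari']:.3f}")
print(f"planted-SVG recall     : {run['svg_recall']:.2f}")
print(f"false-discovery rate   : {run['svg_fdr']:.2f}")
print(f"SVGs reported          : {run['n_svgs']}")
```

This simulates a 20×20 hexagonal slide (400 spots, 4 contiguous domains,
200 genes of which 40 are domain-enriched at 4-fold), runs the full method
and prints:

```
ARI vs planted domains : 0.912
planted-SVG recall     : 1.00
false-discovery rate   : 0.00
SVGs reported          : 40
```

i.e. the recovered domains agree with the planted partition almost
perfectly, and the detector returns exactly the 40 planted genes with no
false positives.

On real data, use the CLI:

```bash
spagae run --input /path/to/visium_dir --format mtx_dir \
    --out results/ --seed 0 --n-domains 7
```

which writes `domains.csv`, `svgs.csv` (deduplicated gene-level calls),
`svgs_by_domain.csv` (all per-domain statistics), `autocorrelation.csv`,
the model checkpoint, and a `manifest.json` recording seed/config for exact
reproduction. `spagae simulate` writes a synthetic fixture with ground
truth; `spagae evaluate` scores a run against it.

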