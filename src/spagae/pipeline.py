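"""End-to-end orchestration: preprocess → graph → train → cluster →
autocorrelation → SVG detection, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .autocorr import score_genes
from .datasets import QcConfig, SpatialDataset
from .domains import ari, cluster_domains, plot_domains
from .graph import build_sng, export_edges
from .model import GaaeConfig, save_model, train
from .preprocess import preprocess
from .svg import SvgConfig, detect_svgs, summarize_svgs

DEFAULT_CONFIG = {
    "qc": {"min_spots_per_gene": 3, "drop_mito": True, "strict": False,
           "target_sum": 1e4, "n_hvg": 3000},
    "graph": {"mode": "radius", "rad_cutoff": None, "k": 6, "target_avg": 6.0},
    "model": {"layer_dims": [512, 30], "lambda_struct": 0.1,
              "activation": "elu", "epochs": 500, "learning_rate": 1e-4,
              "weight_decay": 1e-4, "alpha_refine": 0.0, "gradient_clip": 5.0,
              "tie_weights": False},
    "cluster": {"n_domains": "auto", "auto_range": [2, 8],
                "source": "reconstruction"},
    "svg": {"alpha": 0.05, "min_in_domain_frac": 0.8, "min_fold_change": 1.0,
            "frac_mode": "domain", "bh_scope": "domain",
            "weight_scheme": "binary"},
}


def merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, values in (overrides or {}).items():
        if section not in cfg:
            cfg[section] = values
        elif isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def _manifest(outdir: Path, config: dict, seed: int) -> None:
    blob = json.dumps(config, sort_keys=True).encode()
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "spagae_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(ds: SpatialDataset, outdir, seed: int = 0,
                 config: dict | None = None, write_plots: bool = False) -> dict:
    """Run the full pipeline on a loaded dataset, writing all artifacts.

    Returns a dict of in-memory results for programmatic use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = merge_config(config)

    qc = QcConfig(**{k: v for k, v in cfg["qc"].items()
                     if k in QcConfig.__dataclass_fields__})
    processed = preprocess(ds, qc)

    gcfg = cfg["graph"]
    g = build_sng(processed.coords, rad_cutoff=gcfg.get("rad_cutoff"),
                  mode=gcfg.get("mode", "radius"), k=gcfg.get("k", 6),
                  target_avg=gcfg.get("target_avg", 6.0))
    export_edges(g, outdir / "graph_edges.tsv")

    mcfg = GaaeConfig(seed=seed, **{k: v for k, v in cfg["model"].items()
                                    if k in GaaeConfig.__dataclass_fields__
                                    and k != "seed"})
    model, emb = train(processed, g, mcfg)
    save_model(model, outdir / "model.h5")
    pd.DataFrame(emb.latent, index=processed.spot_ids).to_csv(
        outdir / "latent.csv", float_format="%.8g")
    pd.DataFrame({"epoch": range(len(emb.loss_history)),
                  "loss": emb.loss_history}).to_csv(
        outdir / "loss_history.csv", index=False, float_format="%.8g")

    ccfg = cfg["cluster"]
    n_domains = ccfg.get("n_domains", "auto")
    if n_domains in (None, "auto"):
        lo, hi = ccfg.get("auto_range", [2, 8])
        n_domains = range(int(lo), int(hi) + 1)
    labels = cluster_domains(emb, n_domains,
                             source=ccfg.get("source", "reconstruction"),
                             seed=seed)
    pd.DataFrame({"spot_id": processed.spot_ids,
                  "domain": labels.labels}).to_csv(
        outdir / "domains.csv", index=False)
    if write_plots:
        plot_domains(processed.coords, labels.labels, outdir / "domains.png")

    scfg = SvgConfig(**{k: v for k, v in cfg["svg"].items()
                        if k in SvgConfig.__dataclass_fields__})
    ac = score_genes(processed, g, scheme=scfg.weight_scheme)
    ac.table.to_csv(outdir / "autocorrelation.csv", index=False,
                    float_format="%.8g")
    table = detect_svgs(processed, g, labels, ac, scfg)
    table.to_csv(outdir / "svgs_by_domain.csv", index=False,
                 float_format="%.8g")
    summary = summarize_svgs(table)
    summary.to_csv(outdir / "svgs.csv", index=False, float_format="%.8g")

    _manifest(outdir, cfg, seed)
    return {"dataset": processed, "graph": g, "model": model, "embedding": emb,
            "labels": labels, "autocorr": ac, "svg_table": table,
            "svg_summary": summary}


# desk-scale model configuration for the bundled synthetic study
STUDY_MODEL = GaaeConfig(layer_dims=(64, 16), epochs=450, learning_rate=1e-3)


def run_synthetic_study(seed: int = 0, fold_change: float = 4.0,
                        sim_overrides: dict | None = None,
                        model_cfg: GaaeConfig | None = None) -> dict:
    """Simulate one slide, run the full method in memory, score vs truth.

    Returns the evaluation metrics plus the per-run objects.  The study
    conditions are the generator defaults (20×20 hex lattice, K=4 contiguous
    domains, 200 genes with 10 planted SVGs per domain).
    """
    from .synthetic import SimConfig, simulate_dataset

    params = dict(fold_change=fold_change, noise_seed=seed)
    params.update(sim_overrides or {})
    sim_cfg = SimConfig(**params)
    ds, truth = simulate_dataset(sim_cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        processed = preprocess(ds, QcConfig())
    g = build_sng(processed.coords)
    base = model_cfg or STUDY_MODEL
    cfg = GaaeConfig(**{**base.__dict__, "seed": seed})
    model, emb = train(processed, g, cfg)
    labels = cluster_domains(emb, sim_cfg.n_domains, seed=seed)
    table = detect_svgs(processed, g, labels)
    summary = summarize_svgs(table)
    result = {"dataset": processed, "graph": g, "model": model,
              "embedding": emb, "labels": labels, "svg_table": table,
              "svg_summary": summary, "truth": truth}
    result.update(evaluate_run(result, truth.true_labels, truth.all_svgs()))
    return result


def evaluate_run(result: dict, true_labels: np.ndarray,
                 true_svgs: set[str]) -> dict:
    """ARI against planted domains plus SVG recovery statistics."""
    processed: SpatialDataset = result["dataset"]
    labels = result["labels"]
    detected = set(result["svg_summary"]["gene_id"]) if len(
        result["svg_summary"]) else set()
    present = {g for g in true_svgs if g in processed.gene_ids}
    recall = len(detected & present) / len(present) if present else float("nan")
    fdr = (len(detected - true_svgs) / len(detected)) if detected else 0.0
    return {
        "ari": ari(labels.labels, np.asarray(true_labels)),
        "n_domains": labels.K,
        "n_svgs": len(detected),
        "svg_recall": recall,
        "svg_fdr": fdr,
    }
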