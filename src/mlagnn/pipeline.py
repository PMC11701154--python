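"""One-command orchestration of the full workflow with a run manifest.

Stages run in order — simulate, preprocess, select, integrate, graph,
train, explain, evaluate — each writing its artifacts under the run
directory.  A stage whose artifacts already exist is reloaded rather than
recomputed, so deleting only downstream artifacts and rerunning reproduces
them identically; the manifest records every artifact with its producing
stage, configuration hash and content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffsel, evaluate, graph as graphmod, integrate, model as modelmod
from . import preprocess, simulate
from .io import (
    file_sha256,
    read_gene_list,
    read_matrix,
    read_omics,
    write_gene_list,
    write_manifest,
    write_matrix,
)
from .omics import FeaturePanel

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "preprocess", "select", "integrate",
    "graph", "train", "explain", "evaluate",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "run",
    "stages": {s: True for s in STAGES},
    "inputs": {},  # external matrices when simulate is disabled
    "simulate": {},  # SimConfig overrides
    "select": {"expr_fc": 2.0, "meth_fc": 1.2, "p": 0.05, "use_all_genes": False},
    "split": {"train_fraction": 0.7, "grouping": "pair"},
    "graph": {"alpha": "auto", "adj_thresh": 0.5},
    "model": {},  # MLAGNNConfig overrides
    "explain": {"top_k": 10},
}


def load_config(path: Path | str | None = None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _check_dependencies(stages: dict) -> None:
    needs = {
        "preprocess": [], "select": ["preprocess"], "integrate": ["preprocess"],
        "graph": ["integrate"], "train": ["integrate", "graph"],
        "explain": ["train"], "evaluate": ["train"],
    }
    for stage, deps in needs.items():
        if stages.get(stage):
            for d in deps:
                if not stages.get(d):
                    raise ValueError(
                        f"stage {stage!r} is enabled but its dependency {d!r} "
                        "is disabled"
                    )


def run_pipeline(cfg: dict) -> Path:
    """Execute the configured stages; returns the run directory."""
    _check_dependencies(cfg["stages"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    chash = _config_hash(cfg)
    manifest: dict[str, dict] = {}

    def record(name: str, path: Path, stage: str) -> None:
        manifest[name] = {
            "path": str(path.relative_to(out)),
            "stage": stage,
            "config_hash": chash,
            "sha256": file_sha256(path),
        }

    stages = cfg["stages"]

    # -- simulate / load inputs ----------------------------------------------
    sim_dir = out / "cohort"
    if stages.get("simulate"):
        sim_cfg = simulate.SimConfig(**{"seed": seed, **cfg["simulate"]})
        if not (sim_dir / "manifest.json").exists():
            expr, meth, truth = simulate.generate_paired_cohort(sim_cfg)
            simulate.write_cohort(expr, meth, truth, sim_dir)
        for f in sorted(sim_dir.iterdir()):
            record(f"cohort/{f.name}", f, "simulate")
        inputs = {
            "expr_matrix": sim_dir / "expression_matrix.tsv",
            "expr_labels": sim_dir / "expression_labels.tsv",
            "meth_matrix": sim_dir / "methylation_matrix.tsv",
            "meth_labels": sim_dir / "methylation_labels.tsv",
            "expr_probe_map": sim_dir / "expression_probe_map.tsv",
            "meth_probe_map": sim_dir / "methylation_probe_map.tsv",
        }
    else:
        inputs = {k: Path(v) for k, v in cfg["inputs"].items()}
        for k in ("expr_matrix", "expr_labels", "meth_matrix", "meth_labels"):
            if k not in inputs or not inputs[k].exists():
                raise FileNotFoundError(f"input {k!r} missing (and simulate disabled)")

    # -- preprocess ------------------------------------------------------------
    layers = {}
    for key, kind in (("expr", "expression"), ("meth", "methylation")):
        pm = inputs.get(f"{key}_probe_map")
        m = read_omics(
            inputs[f"{key}_matrix"], inputs[f"{key}_labels"], omics_kind=kind,
            probe_map_path=pm if pm and Path(pm).exists() else None,
        )
        raw_path = out / f"{key}_raw_genes.tsv"
        norm_path = out / f"{key}_normalized.tsv"
        if raw_path.exists() and norm_path.exists():
            raw = m.with_values(read_matrix(raw_path), probe_map=None)
            norm = m.with_values(read_matrix(norm_path), scale="normalized", probe_map=None)
        else:
            raw, norm = preprocess.preprocess_layer(m)
            write_matrix(raw.values, raw_path)
            write_matrix(norm.values, norm_path)
        record(f"{key}_raw_genes", raw_path, "preprocess")
        record(f"{key}_normalized", norm_path, "preprocess")
        layers[key] = (raw, norm)

    # -- select ----------------------------------------------------------------
    panel_path = out / "panel.tsv"
    sel = cfg["select"]
    if sel.get("use_all_genes"):
        genes = sorted(
            set(layers["expr"][0].gene_ids) & set(layers["meth"][0].gene_ids)
        )
        panel = FeaturePanel(gene_ids=genes)
        write_gene_list(genes, panel_path)
    elif panel_path.exists():
        panel = FeaturePanel(gene_ids=read_gene_list(panel_path))
    else:
        panel, es, ms = diffsel.select_panel(
            layers["expr"][0], layers["meth"][0],
            diffsel.SelectionCriteria(sel["expr_fc"], sel["p"]),
            diffsel.SelectionCriteria(sel["meth_fc"], sel["p"]),
        )
        write_gene_list(panel.gene_ids, panel_path)
        for key, stats in (("expr", es), ("meth", ms)):
            p = out / f"{key}_diff_stats.tsv"
            stats.to_csv(p, sep="\t")
            record(f"{key}_diff_stats", p, "select")
    record("panel", panel_path, "select")

    # -- integrate + split -------------------------------------------------------
    ds = integrate.cartesian_integrate(layers["expr"][1], layers["meth"][1], panel)
    spec = integrate.SplitSpec(
        train_fraction=cfg["split"]["train_fraction"],
        seed=seed + 11,
        grouping=cfg["split"]["grouping"],
    )
    train_ds, test_ds = integrate.split_train_test(ds, spec)
    split_path = out / "split.json"
    split_path.write_text(json.dumps({
        "n_pairs": len(ds), "n_train": len(train_ds), "n_test": len(test_ds),
        "grouping": spec.grouping,
    }, indent=2) + "\n")
    record("split", split_path, "integrate")

    if not (stages.get("graph") or stages.get("train")):
        write_manifest(manifest, out / "manifest.json")
        return out

    # -- graph -------------------------------------------------------------------
    gcfg = cfg["graph"]
    alpha = None if gcfg["alpha"] == "auto" else float(gcfg["alpha"])
    if gcfg["adj_thresh"] == "auto":
        sub_spec = integrate.SplitSpec(train_fraction=0.75, seed=seed + 13)
        tr, val = integrate.split_train_test(train_ds, sub_spec)
        obs = graphmod.training_observations(tr.features)
        if alpha is None:
            alpha, _ = graphmod.pick_soft_power(obs)
        adj_thresh, _ = graphmod.tune_adj_thresh(
            tr, val, (0.3, 0.5, 0.7), alpha=alpha
        )
    else:
        adj_thresh = float(gcfg["adj_thresh"])
    g = graphmod.build_graph(
        train_ds.features, ds.gene_ids, alpha=alpha, adj_thresh=adj_thresh
    )
    cpath, apath = out / "soft_adjacency.tsv", out / "edges.tsv"
    write_matrix(pd.DataFrame(g.C, index=g.gene_ids, columns=g.gene_ids), cpath)
    edge_i, edge_j = np.nonzero(np.triu(g.A, 1))
    apath.write_text(
        "gene_i\tgene_j\n"
        + "".join(f"{g.gene_ids[i]}\t{g.gene_ids[j]}\n" for i, j in zip(edge_i, edge_j))
    )
    gmeta = out / "graph.json"
    gmeta.write_text(json.dumps({
        "alpha": g.alpha, "adj_thresh": g.adj_thresh,
        "n_edges": int(len(edge_i)), "fingerprint": g.training_fingerprint,
        "r2_trace": g.r2_trace,
    }, indent=2) + "\n")
    for name, p in (("soft_adjacency", cpath), ("edges", apath), ("graph_meta", gmeta)):
        record(name, p, "graph")

    if not stages.get("train"):
        write_manifest(manifest, out / "manifest.json")
        return out

    # -- train ---------------------------------------------------------------------
    mcfg = modelmod.MLAGNNConfig(**{"seed": seed + 17, **cfg["model"]})
    params, trace = modelmod.train(train_ds, g, mcfg)
    model_path = out / "model.json"
    model_path.write_text(json.dumps(
        {k: v.tolist() for k, v in params.items()}, sort_keys=True
    ) + "\n")
    meta = out / "model_meta.json"
    meta.write_text(json.dumps({
        "config": mcfg.__dict__, "loss_trace": trace, "seed": seed,
    }, indent=2) + "\n")
    record("model", model_path, "train")
    record("model_meta", meta, "train")

    # -- explain ---------------------------------------------------------------------
    if stages.get("explain"):
        report = modelmod.fgs_saliency(
            params, g, test_ds.features, mcfg, top_k=int(cfg["explain"]["top_k"])
        )
        spath = out / "saliency.tsv"
        report.scores.to_csv(spath, sep="\t")
        record("saliency", spath, "explain")

    # -- evaluate --------------------------------------------------------------------
    if stages.get("evaluate"):
        prob = modelmod.predict_proba(test_ds.features, g, params, mcfg)
        metrics = {"MLA-GNN": evaluate.compute_metrics(prob, test_ds.y).as_dict()}
        baselines = evaluate.run_baselines(
            train_ds.features, train_ds.y, test_ds.features, test_ds.y, seed=seed,
        )
        for name, rep in baselines.items():
            metrics[name] = rep.as_dict() if rep is not None else None
        mpath = out / "metrics.json"
        mpath.write_text(json.dumps(metrics, indent=2) + "\n")
        record("metrics", mpath, "evaluate")

    write_manifest(manifest, out / "manifest.json")
    return out
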