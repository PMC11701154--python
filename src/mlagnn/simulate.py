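"""Synthetic paired expression/methylation cohorts with planted biomarkers.

The generator emulates the statistical structure the downstream pipeline
assumes: two omics layers over a shared gene universe, a planted set of
genes upregulated in tumors in *both* layers, block-correlated gene modules
(so co-expression structure exists for graph construction), Gaussian noise
on a linear positive scale, and optional missing values and duplicated
probe rows.  Every run is fully reproducible from the seed, and the planted
ground truth is returned so downstream recovery can be scored.

Model
-----
For a sample of group ``g`` (tumor or normal) the value of gene ``i`` is

    x_i = mu + delta_i(g) + noise_sd * (sqrt(rho) * z_m + sqrt(1-rho) * eps)

where ``mu`` is a positive baseline, ``delta_i(tumor) = effect_size *
noise_sd`` for planted genes and 0 otherwise, ``z_m`` is a per-sample latent
factor shared by all genes of module ``m`` (absent for module-free genes),
and ``eps`` is i.i.d. standard normal.  The latent-factor construction makes
the pairwise within-module correlation exactly ``rho`` in expectation.
Values are clipped to a small positive floor so the ratio fold change is
always defined.

The baseline ``mu`` is 2 noise-SD units, so a planted shift of 3 SD gives a
linear fold change of about 2.5 — comfortably above the expression screen's
FC > 2 — while the clipped-normal distortion stays small (about 2% of
values touch the floor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    write_gene_list,
    write_labels,
    write_manifest,
    write_matrix,
    write_probe_map,
)
from .omics import NORMAL, TUMOR, OmicsMatrix

BASELINE_SD_UNITS = 2.0  # baseline mean, in units of noise_sd
POSITIVE_FLOOR = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic paired cohort."""

    n_genes: int = 200
    n_tumor_expr: int = 30
    n_normal_expr: int = 30
    n_tumor_meth: int = 30
    n_normal_meth: int = 30
    n_planted: int = 10
    effect_size: float = 3.0  # tumor mean shift, in units of noise_sd
    n_modules: int = 4
    module_size: int = 20
    within_module_rho: float = 0.8
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    dup_probe_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tumor_expr": self.n_tumor_expr,
            "n_normal_expr": self.n_normal_expr,
            "n_tumor_meth": self.n_tumor_meth,
            "n_normal_meth": self.n_normal_meth,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_planted < 0 or self.n_planted > self.n_genes:
            raise ValueError(
                f"n_planted must be in [0, n_genes], got {self.n_planted}"
            )
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                "module blocks must be disjoint and fit the gene universe: "
                f"n_modules*module_size = {self.n_modules * self.module_size} "
                f"> n_genes = {self.n_genes}"
            )
        if not 0 <= self.within_module_rho < 1:
            raise ValueError(
                f"within_module_rho must be in [0,1), got {self.within_module_rho}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        for name in ("missing_rate", "dup_probe_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0,1), got {v}")


@dataclass(frozen=True)
class GroundTruth:
    """Which genes were planted as dual-layer biomarkers, and module membership."""

    planted_genes: tuple[str, ...]
    module_assignment: dict[str, int | None] = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _simulate_layer(
    cfg: SimConfig,
    rng: np.random.Generator,
    gene_ids: list[str],
    planted_idx: np.ndarray,
    module_of: np.ndarray,
    n_tumor: int,
    n_normal: int,
    prefix: str,
    omics_kind: str,
) -> OmicsMatrix:
    n_genes = cfg.n_genes
    n_samples = n_tumor + n_normal
    rho = cfg.within_module_rho

    eps = rng.standard_normal((n_genes, n_samples))
    latent = rng.standard_normal((cfg.n_modules, n_samples))
    noise = np.sqrt(1.0 - rho) * eps
    in_module = module_of >= 0
    noise[in_module] += np.sqrt(rho) * latent[module_of[in_module]]
    noise[~in_module] = eps[~in_module]

    values = cfg.noise_sd * (BASELINE_SD_UNITS + noise)
    values[np.ix_(planted_idx, np.arange(n_tumor))] += cfg.effect_size * cfg.noise_sd
    np.clip(values, POSITIVE_FLOOR, None, out=values)

    if cfg.missing_rate > 0:
        mask = rng.random((n_genes, n_samples)) < cfg.missing_rate
        values[mask] = np.nan

    sample_ids = [f"{prefix}T{i + 1:03d}" for i in range(n_tumor)] + [
        f"{prefix}N{i + 1:03d}" for i in range(n_normal)
    ]
    labels = pd.Series(
        [TUMOR] * n_tumor + [NORMAL] * n_normal, index=sample_ids, dtype=str
    )
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    df.index.name = "gene_id"

    probe_map = None
    if cfg.dup_probe_rate > 0:
        # duplicated probes: a second row per chosen gene with fresh noise,
        # identified by a probe suffix plus an explicit probe -> gene map
        n_dup = int(np.floor(cfg.dup_probe_rate * n_genes))
        dup_idx = rng.choice(n_genes, size=n_dup, replace=False)
        rows, index, mapping = [], [], {}
        for i, g in enumerate(gene_ids):
            rows.append(df.iloc[i].to_numpy())
            index.append(f"{g}_p1")
            mapping[f"{g}_p1"] = g
        for i in sorted(dup_idx):
            extra = df.iloc[i].to_numpy() + cfg.noise_sd * rng.standard_normal(
                n_samples
            )
            extra = np.clip(extra, POSITIVE_FLOOR, None)
            rows.append(extra)
            index.append(f"{gene_ids[i]}_p2")
            mapping[f"{gene_ids[i]}_p2"] = gene_ids[i]
        df = pd.DataFrame(np.vstack(rows), index=index, columns=sample_ids)
        df.index.name = "gene_id"
        probe_map = pd.Series(mapping, dtype=str)

    return OmicsMatrix(
        values=df, labels=labels, omics_kind=omics_kind, scale="raw",
        probe_map=probe_map,
    )


def generate_paired_cohort(
    config: SimConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, GroundTruth]:
    """Generate an expression layer, a methylation layer, and the ground truth.

    Both layers share the gene universe, the planted biomarker set, and the
    module assignment; noise is drawn independently per layer.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = _gene_ids(config.n_genes)

    planted_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_planted, replace=False)
    )
    module_of = np.full(config.n_genes, -1)
    for m in range(config.n_modules):
        lo = m * config.module_size
        module_of[lo : lo + config.module_size] = m

    expr = _simulate_layer(
        config, rng, gene_ids, planted_idx, module_of,
        config.n_tumor_expr, config.n_normal_expr, "E", "expression",
    )
    meth = _simulate_layer(
        config, rng, gene_ids, planted_idx, module_of,
        config.n_tumor_meth, config.n_normal_meth, "M", "methylation",
    )
    truth = GroundTruth(
        planted_genes=tuple(gene_ids[i] for i in planted_idx),
        module_assignment={
            g: (int(module_of[i]) if module_of[i] >= 0 else None)
            for i, g in enumerate(gene_ids)
        },
    )
    return expr, meth, truth


def write_cohort(
    expression: OmicsMatrix,
    methylation: OmicsMatrix,
    truth: GroundTruth,
    out_dir: Path | str,
) -> dict[str, Path]:
    """Write the cohort in the delimited formats the preprocess stage reads.

    Ground truth is saved separately (test use only) and a manifest names
    every file.  Returns the artifact name -> path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    for name, layer in (("expression", expression), ("methylation", methylation)):
        files[f"{name}_matrix"] = out / f"{name}_matrix.tsv"
        write_matrix(layer.values, files[f"{name}_matrix"])
        files[f"{name}_labels"] = out / f"{name}_labels.tsv"
        write_labels(layer.labels, files[f"{name}_labels"])
        if layer.probe_map is not None:
            files[f"{name}_probe_map"] = out / f"{name}_probe_map.tsv"
            write_probe_map(layer.probe_map, files[f"{name}_probe_map"])
    files["ground_truth"] = out / "ground_truth.tsv"
    write_gene_list(list(truth.planted_genes), files["ground_truth"])
    files["module_assignment"] = out / "module_assignment.json"
    files["module_assignment"].write_text(
        json.dumps(truth.module_assignment, indent=0, sort_keys=True) + "\n"
    )
    write_manifest(
        {k: {"path": p.name, "stage": "simulate"} for k, p in files.items()},
        out / "manifest.json",
    )
    files["manifest"] = out / "manifest.json"
    return files
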