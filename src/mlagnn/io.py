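"""Delimited-text readers and writers for the pipeline's on-disk formats.

All artifacts are plain TSV / JSON: matrix files (first column ``gene_id``,
remaining columns sample ids), a label file (``sample_id<TAB>label``), a
probe map (``probe_id<TAB>gene_id``), gene-list files, and run manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .omics import LABELS, OmicsMatrix


def write_matrix(values: pd.DataFrame, path: Path | str) -> None:
    df = values.copy()
    df.index.name = "gene_id"
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_matrix(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    return df


def write_labels(labels: pd.Series, path: Path | str) -> None:
    labels.rename("label").rename_axis("sample_id").to_csv(path, sep="\t")


def read_labels(path: Path | str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    labels = df["label"]
    bad = set(labels) - set(LABELS)
    if bad:
        raise ValueError(f"{path}: labels must be in {LABELS}, found {sorted(bad)}")
    return labels


def write_probe_map(probe_map: pd.Series, path: Path | str) -> None:
    probe_map.rename("gene_id").rename_axis("probe_id").to_csv(path, sep="\t")


def read_probe_map(path: Path | str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df["gene_id"]


def write_gene_list(gene_ids: list[str], path: Path | str) -> None:
    Path(path).write_text("gene_id\n" + "".join(g + "\n" for g in gene_ids))


def read_gene_list(path: Path | str) -> list[str]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "gene_id":
        raise ValueError(f"{path}: expected a 'gene_id' header")
    return lines[1:]


def read_omics(
    matrix_path: Path | str,
    labels_path: Path | str,
    omics_kind: str = "expression",
    scale: str = "raw",
    probe_map_path: Path | str | None = None,
) -> OmicsMatrix:
    probe_map = read_probe_map(probe_map_path) if probe_map_path else None
    return OmicsMatrix(
        values=read_matrix(matrix_path),
        labels=read_labels(labels_path),
        omics_kind=omics_kind,
        scale=scale,
        probe_map=probe_map,
    )


def file_sha256(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(entries: dict[str, dict], path: Path | str) -> None:
    """Write a run manifest: artifact name -> {path, stage, sha256, ...}."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")


def read_manifest(path: Path | str) -> dict[str, dict]:
    return json.loads(Path(path).read_text())
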