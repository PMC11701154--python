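"""Core in-memory container for a single omics layer.

An :class:`OmicsMatrix` holds a genes-by-samples value matrix for one omics
layer (gene expression or DNA methylation) together with sample labels
(tumor / normal) and scale metadata.  All pipeline stages consume and
produce this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
LABELS = (TUMOR, NORMAL)


@dataclass
class OmicsMatrix:
    """One omics layer: genes in rows, samples in columns.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe) identifier with sample
        identifiers as columns.  May contain NaN before imputation.
    labels
        Series mapping every sample identifier to ``"tumor"`` or ``"normal"``.
    omics_kind
        ``"expression"`` or ``"methylation"``.
    scale
        ``"raw"`` (linear positive values) or ``"normalized"`` (per-gene
        min-max scaled into [0, 1]).
    probe_map
        Optional probe -> gene mapping when rows are probe-level; ``None``
        once rows are collapsed to genes.
    """

    values: pd.DataFrame
    labels: pd.Series
    omics_kind: str = "expression"
    scale: str = "raw"
    probe_map: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.omics_kind not in ("expression", "methylation"):
            raise ValueError(f"unknown omics_kind {self.omics_kind!r}")
        if self.scale not in ("raw", "normalized"):
            raise ValueError(f"unknown scale {self.scale!r}")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        bad = set(self.labels.loc[list(self.values.columns)]) - set(LABELS)
        if bad:
            raise ValueError(f"labels must be in {LABELS}, found {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, label: str) -> list[str]:
        lab = self.labels.loc[list(self.values.columns)]
        return [s for s in self.values.columns if lab[s] == label]

    def group_values(self, label: str) -> pd.DataFrame:
        return self.values[self.samples_of(label)]

    def with_values(self, values: pd.DataFrame, **kwargs) -> "OmicsMatrix":
        return replace(self, values=values, **kwargs)


@dataclass
class FeaturePanel:
    """Ordered gene panel shared by both omics layers.

    ``provenance`` carries, per panel gene, the (fold change, p-value) pair
    from each layer that justified its selection; empty for panels built
    without differential screening.
    """

    gene_ids: list[str]
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["fc_expr", "p_expr", "fc_meth", "p_meth"]
        )
    )

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("panel gene_ids must be unique")

    def __len__(self) -> int:
        return len(self.gene_ids)


def check_positive(values: pd.DataFrame, what: str) -> None:
    arr = values.to_numpy(float)
    if np.nanmin(arr) <= 0:
        raise ValueError(f"{what} requires strictly positive values")
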