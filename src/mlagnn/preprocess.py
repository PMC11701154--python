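"""Per-layer preprocessing: probe collapsing, group-mean imputation, min-max.

The order mirrors the workflow the rest of the pipeline expects: probes are
collapsed to genes by averaging, residual missing values are imputed with
the mean of the sample's own label group, and each gene is min-max scaled
across all samples of the layer.  Normalization is deliberately computed on
the pooled (train+test) samples; see the package docs for the leakage
caveat this implies.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .omics import LABELS, OmicsMatrix

logger = logging.getLogger(__name__)


def collapse_probes(m: OmicsMatrix, probe_map: pd.Series | None = None) -> OmicsMatrix:
    """Average probe rows mapping to the same gene.

    Unmapped probes are reported and dropped; means ignore missing entries.
    Output gene order is lexicographic.
    """
    if probe_map is None:
        probe_map = m.probe_map
    if probe_map is None:
        raise ValueError("no probe map supplied and none attached to the matrix")
    mapped = [p for p in m.values.index if p in probe_map.index]
    unmapped = [p for p in m.values.index if p not in probe_map.index]
    if not mapped:
        raise ValueError("no probe in the matrix appears in the probe map")
    if unmapped:
        logger.warning("dropping %d unmapped probes (e.g. %s)", len(unmapped), unmapped[:3])
    sub = m.values.loc[mapped]
    genes = probe_map.loc[mapped]
    collapsed = sub.groupby(genes.to_numpy()).mean()  # skipna mean per gene
    collapsed = collapsed.sort_index()
    collapsed.index = collapsed.index.astype(str)
    return m.with_values(collapsed, probe_map=None)


def impute_group_mean(m: OmicsMatrix) -> OmicsMatrix:
    """Replace each missing cell by that gene's mean over its label group.

    A gene missing across an entire label group cannot be recovered and is
    dropped (count logged).
    """
    values = m.values.copy()
    group_means = {}
    for label in LABELS:
        samples = m.samples_of(label)
        if not samples:
            raise ValueError(f"group {label!r} has zero samples")
        group_means[label] = values[samples].mean(axis=1)

    unrecoverable = pd.Series(False, index=values.index)
    for label in LABELS:
        unrecoverable |= group_means[label].isna()
    if unrecoverable.any():
        logger.warning(
            "dropping %d genes missing across an entire group", int(unrecoverable.sum())
        )
        values = values.loc[~unrecoverable]

    for label in LABELS:
        samples = m.samples_of(label)
        block = values[samples]
        fill = group_means[label].loc[values.index]
        values[samples] = block.apply(lambda col: col.fillna(fill))
    assert not values.isna().any().any()
    return m.with_values(values)


def minmax_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Per-gene (x - min) / (max - min) across all samples of the layer.

    Constant genes map to 0.  Requires a fully imputed matrix.
    """
    if m.values.isna().any().any():
        raise ValueError("minmax_normalize requires no missing values; impute first")
    arr = m.values.to_numpy(float)
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(arr)
    nonconst = (span > 0).ravel()
    out[nonconst] = (arr[nonconst] - lo[nonconst]) / span[nonconst]
    return m.with_values(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        scale="normalized",
    )


def preprocess_layer(
    m: OmicsMatrix, probe_map: pd.Series | None = None
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Full per-layer chain; returns (raw gene-level, normalized) matrices.

    The raw gene-level matrix (collapsed and imputed, still on the linear
    positive scale) is what fold changes are computed on; the normalized
    matrix feeds integration and the model.
    """
    if probe_map is not None or m.probe_map is not None:
        m = collapse_probes(m, probe_map)
    m = impute_group_mean(m)
    return m, minmax_normalize(m)
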