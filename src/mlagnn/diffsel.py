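"""Differential screening: fold change, Welch t-test, thresholds, intersection.

Screening is applied independently to the expression and methylation layers
(default thresholds FC > 2 and FC > 1.2 respectively, both with p < 0.05,
upregulated only), then the two selected gene sets are intersected into the
feature panel the classifier operates on.  Fold changes are ratios of group
means on the raw linear scale; p-values are raw (no multiple-testing
correction), a deliberately liberal screening rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .omics import NORMAL, TUMOR, FeaturePanel, OmicsMatrix

logger = logging.getLogger(__name__)

DEFAULT_EXPR_FC = 2.0
DEFAULT_METH_FC = 1.2
DEFAULT_P = 0.05


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for one layer: FC > fc_threshold, p < p_threshold, up only."""

    fc_threshold: float
    p_threshold: float = DEFAULT_P

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")


EXPRESSION_CRITERIA = SelectionCriteria(DEFAULT_EXPR_FC, DEFAULT_P)
METHYLATION_CRITERIA = SelectionCriteria(DEFAULT_METH_FC, DEFAULT_P)


def fold_change(m: OmicsMatrix, log2_input: bool = False) -> pd.Series:
    """Per-gene ratio of tumor group mean to normal group mean.

    With ``log2_input`` the matrix is taken as log2-scale and FC is
    ``2**(mean_tumor - mean_normal)``.  A zero normal mean yields +inf with
    a warning.
    """
    tumor = m.group_values(TUMOR).mean(axis=1)
    normal = m.group_values(NORMAL).mean(axis=1)
    if tumor.empty or len(m.samples_of(TUMOR)) == 0 or len(m.samples_of(NORMAL)) == 0:
        raise ValueError("both groups must be non-empty")
    if log2_input:
        return np.power(2.0, tumor - normal).rename("fold_change")
    if (normal == 0).any():
        warnings.warn("zero normal group mean: fold change reported as +inf")
    with np.errstate(divide="ignore"):
        fc = tumor / normal
    return fc.rename("fold_change")


def t_test(m: OmicsMatrix) -> pd.DataFrame:
    """Two-sided Welch two-sample t-test per gene (tumor vs normal).

    Degenerate genes (zero variance in both groups, equal means) report
    t = 0, p = 1.
    """
    tumor = m.group_values(TUMOR).to_numpy(float)
    normal = m.group_values(NORMAL).to_numpy(float)
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("t-test requires >= 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame({"t_stat": t, "p_value": p}, index=m.values.index)


def diff_stats(m: OmicsMatrix, log2_input: bool = False) -> pd.DataFrame:
    """Full per-gene table: fold_change, t_stat, p_value, direction."""
    fc = fold_change(m, log2_input=log2_input)
    tt = t_test(m)
    direction = pd.Series(
        np.select([fc > 1, fc < 1], ["up", "down"], default="flat"), index=fc.index
    )
    return pd.DataFrame(
        {
            "fold_change": fc,
            "t_stat": tt["t_stat"],
            "p_value": tt["p_value"],
            "direction": direction,
        }
    )


def select_differential(
    stats_table: pd.DataFrame, criteria: SelectionCriteria
) -> set[str]:
    """Genes with FC strictly > threshold, p strictly < threshold, direction up."""
    keep = (
        (stats_table["fold_change"] > criteria.fc_threshold)
        & (stats_table["p_value"] < criteria.p_threshold)
        & (stats_table["direction"] == "up")
    )
    return set(stats_table.index[keep])


def intersect_panels(
    deg: set[str],
    dmp: set[str],
    expr_stats: pd.DataFrame | None = None,
    meth_stats: pd.DataFrame | None = None,
) -> FeaturePanel:
    """Sorted intersection of the two layers' selected genes, with provenance."""
    common = sorted(deg & dmp)
    if not common:
        raise ValueError(
            "no gene passes both layers' criteria; relax the FC or p thresholds"
        )
    prov = pd.DataFrame(index=common)
    if expr_stats is not None:
        prov["fc_expr"] = expr_stats.loc[common, "fold_change"]
        prov["p_expr"] = expr_stats.loc[common, "p_value"]
    if meth_stats is not None:
        prov["fc_meth"] = meth_stats.loc[common, "fold_change"]
        prov["p_meth"] = meth_stats.loc[common, "p_value"]
    return FeaturePanel(gene_ids=common, provenance=prov)


def select_panel(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    expr_criteria: SelectionCriteria = EXPRESSION_CRITERIA,
    meth_criteria: SelectionCriteria = METHYLATION_CRITERIA,
    log2_input: bool = False,
) -> tuple[FeaturePanel, pd.DataFrame, pd.DataFrame]:
    """Screen both layers and intersect; returns (panel, expr stats, meth stats)."""
    es = diff_stats(expr, log2_input=log2_input)
    ms = diff_stats(meth, log2_input=log2_input)
    deg = select_differential(es, expr_criteria)
    dmp = select_differential(ms, meth_criteria)
    logger.info("selected %d DEGs, %d DMPs", len(deg), len(dmp))
    return intersect_panels(deg, dmp, es, ms), es, ms
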