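"""Pre-filters applied to the lncRNA matrix before clustering.

Two rules: a detectability filter (mean RPKM across all retained samples at
or above a threshold, default 0.3) and selection of the top-k genes by
expression variability (default 500), measured on the log2(RPKM + 1) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix
from .errors import ConfigError

VARIABILITY_MEASURES = ("variance_log2", "sd_log2", "mad_log2")


@dataclass
class FeatureSelectionParams:
    detectable_mean_rpkm: float = 0.3
    top_k: int = 500
    variability_measure: str = "variance_log2"

    def validate(self) -> None:
        if self.detectable_mean_rpkm < 0:
            raise ConfigError("detectable_mean_rpkm must be >= 0")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.variability_measure not in VARIABILITY_MEASURES:
            raise ConfigError(
                f"variability_measure must be one of {VARIABILITY_MEASURES}")


def filter_detectable(expr: ExpressionMatrix,
                      threshold: float = 0.3) -> ExpressionMatrix:
    """Keep genes whose arithmetic mean RPKM across all samples >= threshold."""
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    means = expr.values.mean(axis=1)
    keep = expr.gene_ids[means >= threshold]
    return expr.subset_genes(keep)


def _variability(log2_values: pd.DataFrame, measure: str) -> pd.Series:
    if measure == "variance_log2":
        return log2_values.var(axis=1, ddof=1)
    if measure == "sd_log2":
        return log2_values.std(axis=1, ddof=1)
    if measure == "mad_log2":
        return pd.Series(
            stats.median_abs_deviation(log2_values.to_numpy(), axis=1),
            index=log2_values.index,
        )
    raise ConfigError(f"unknown variability measure {measure!r}")


def top_variable(expr: ExpressionMatrix, k: int = 500,
                 measure: str = "variance_log2") -> ExpressionMatrix:
    """The k genes with the largest variability on log2(RPKM + 1).

    Ties are broken by gene-id lexicographic order so repeated runs select
    an identical set.  Input gene order is preserved in the output.
    """
    if measure not in VARIABILITY_MEASURES:
        raise ConfigError(f"variability_measure must be one of {VARIABILITY_MEASURES}")
    if k > expr.shape[0]:
        raise ConfigError(f"k={k} exceeds gene count {expr.shape[0]}")
    score = _variability(np.log2(expr.values + 1.0), measure)
    order = sorted(score.index, key=lambda g: (-score[g], g))
    selected = set(order[:k])
    keep = [g for g in expr.gene_ids if g in selected]
    return expr.subset_genes(keep)


def select_features(expr: ExpressionMatrix,
                    params: FeatureSelectionParams) -> ExpressionMatrix:
    params.validate()
    detected = filter_detectable(expr, params.detectable_mean_rpkm)
    return top_variable(detected, params.top_k, params.variability_measure)
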