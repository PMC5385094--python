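"""Association of cluster membership with clinical/molecular features.

Categorical features are tested globally with an uncorrected Pearson
chi-square on the k x L contingency table (Fisher's exact test when the
table is 2 x 2) and per cluster with Fisher 2 x 2 tests of in-cluster vs
out-of-cluster against feature-level vs rest, yielding an odds ratio and
an enrichment/depletion call.  Continuous features use Welch's unequal-
variance t test.  Multiple testing is handled by Benjamini-Hochberg
(Bonferroni available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    table: np.ndarray
    statistic: float
    df: int | None
    p_value: float
    odds_ratio: float | None     # 2x2 only; may be inf; None when 0/0
    direction: str               # enriched | depleted | none


def _check_counts(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise InputError("contingency table must be 2-dimensional")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise InputError("contingency cells must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise InputError("contingency cells must be non-negative")
    return arr


def fisher_exact_2x2(table, alpha: float = 0.05) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's.  The odds ratio is the cross-product ad/bc (+inf when bc = 0
    and ad > 0; undefined when both products vanish).
    """
    arr = _check_counts(table)
    if arr.shape != (2, 2):
        raise InputError("fisher_exact_2x2 needs a 2x2 table")
    if arr.sum() == 0:
        raise InputError("contingency table is empty")
    (a, b), (c, d) = arr
    res = stats.fisher_exact(arr, alternative="two-sided")
    p = float(res.pvalue)
    ad, bc = a * d, b * c
    if bc == 0 and ad == 0:
        odds: float | None = None
    elif bc == 0:
        odds = np.inf
    else:
        odds = ad / bc
    direction = "none"
    if odds is not None and p < alpha:
        if odds > 1:
            direction = "enriched"
        elif odds < 1:
            direction = "depleted"
    return ContingencyResult(arr, float(odds) if odds is not None else np.nan,
                             None, p, odds, direction)


def chi_square(table) -> ContingencyResult:
    """Uncorrected Pearson chi-square on an r x c table of counts."""
    arr = _check_counts(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise InputError("zero row/column margin gives an expected count of 0")
    res = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(arr, float(res.statistic), int(res.dof),
                             float(res.pvalue), None, "none")


@dataclass
class FeatureAssociation:
    """Global + per-(cluster, level) association of one categorical feature."""

    feature: str
    global_result: ContingencyResult
    per_cluster: list[tuple[int, str, ContingencyResult]]
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        g = self.global_result
        rows.append({
            "feature": self.feature, "cluster": "all", "level": "all",
            "a": None, "b": None, "c": None, "d": None,
            "statistic": g.statistic, "odds_ratio": g.odds_ratio,
            "p_value": g.p_value, "direction": g.direction,
        })
        for cluster, level, r in self.per_cluster:
            (a, b), (c, d) = r.table
            rows.append({
                "feature": self.feature, "cluster": cluster, "level": level,
                "a": a, "b": b, "c": c, "d": d,
                "statistic": r.statistic, "odds_ratio": r.odds_ratio,
                "p_value": r.p_value, "direction": r.direction,
            })
        return pd.DataFrame(rows)


def cluster_feature_association(labels: pd.Series, feature: pd.Series,
                                alpha: float = 0.05) -> FeatureAssociation:
    """Test a categorical feature against the clustering.

    Samples missing the feature are dropped (count logged).  The global
    test is chi-square on the k x L table (Fisher when 2 x 2); per-cluster
    tests are Fisher 2 x 2 of cluster membership against each feature
    level, with enrichment/depletion called from the odds ratio at alpha.
    """
    common = labels.index.intersection(feature.index)
    labels = labels.loc[common]
    feature = feature.loc[common]
    keep = feature.notna()
    n_dropped = int((~keep).sum())
    labels, feature = labels[keep], feature[keep]
    if n_dropped:
        logger.info("association: dropped %d samples with missing data", n_dropped)
    clusters = sorted(labels.unique())
    levels = sorted(feature.unique())
    if len(clusters) < 2 or len(levels) < 2:
        raise InputError("need >= 2 clusters and >= 2 feature levels")
    table = pd.crosstab(labels, feature).loc[clusters, levels].to_numpy()
    if table.shape == (2, 2):
        global_result = fisher_exact_2x2(table, alpha)
    else:
        global_result = chi_square(table)
    per_cluster = []
    for cluster in clusters:
        in_c = labels == cluster
        for level in levels:
            has = feature == level
            t = np.array([
                [int((in_c & has).sum()), int((in_c & ~has).sum())],
                [int((~in_c & has).sum()), int((~in_c & ~has).sum())],
            ])
            per_cluster.append((cluster, level, fisher_exact_2x2(t, alpha)))
    name = feature.name if feature.name is not None else "feature"
    return FeatureAssociation(str(name), global_result, per_cluster, n_dropped)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(pd.Series(group_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(group_b).dropna(), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs >= 2 non-missing values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Bonferroni by flag)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ConfigError("method must be 'fdr_bh' or 'bonferroni'")
    return multipletests(p, method=method)[1]
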