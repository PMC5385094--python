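"""Template-based guilt-by-association (GBA) annotation of tumor clusters.

For each cluster a binary template vector marks its member samples.  A
lncRNA is a *surrogate* of the cluster when (i) its log2(RPKM + 1) profile
correlates with the template at r > 0.3 with p < 1e-6, (ii) its mean raw
RPKM within the cluster is >= 0.1, and (iii) it is overexpressed in the
cluster relative to normal tissue (Welch t on the log2 scale,
BH-corrected p < 0.05).  Each cluster's surrogates are averaged into a
mean profile, and protein-coding genes correlating with that profile at
|r| > 0.3 with p < 1e-9 are reported as directly (up) or inversely (down)
co-expressed partners — the raw material for enrichment-based functional
inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import bh_adjust
from .data_io import ExpressionMatrix
from .errors import (
    ConfigError,
    DegenerateTemplateError,
    InputError,
    UndefinedCorrelationError,
)

logger = logging.getLogger(__name__)


@dataclass
class GbaThresholds:
    surrogate_r: float = 0.3
    surrogate_p: float = 1e-6
    min_cluster_rpkm: float = 0.1
    overexpr_alpha: float = 0.05        # applied to BH-corrected p
    pcg_r: float = 0.3
    pcg_p: float = 1e-9
    correction: str = "fdr_bh"          # or "bonferroni"

    def validate(self) -> None:
        for name in ("surrogate_r", "pcg_r"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        for name in ("surrogate_p", "overexpr_alpha", "pcg_p"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.min_cluster_rpkm < 0:
            raise ConfigError("min_cluster_rpkm must be >= 0")


@dataclass
class ClusterSurrogates:
    cluster: int
    surrogates: pd.DataFrame          # index gene id: r, p, cluster_mean_rpkm, overexpr_adj_p
    mean_profile: pd.Series | None    # over tumor samples, log2 scale
    up_pcgs: pd.DataFrame             # index gene id: r, p
    down_pcgs: pd.DataFrame


@dataclass
class SurrogateSet:
    clusters: dict[int, ClusterSurrogates]

    def __getitem__(self, cluster: int) -> ClusterSurrogates:
        return self.clusters[cluster]

    def __iter__(self):
        return iter(self.clusters.values())


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def make_template(labels: pd.Series, cluster_id) -> pd.Series:
    """Binary indicator over samples: 1 inside the target cluster, else 0."""
    if cluster_id not in set(labels.unique()):
        raise DegenerateTemplateError(f"cluster {cluster_id!r} absent from labels")
    template = (labels == cluster_id).astype(int)
    if template.all():
        raise DegenerateTemplateError(
            f"cluster {cluster_id!r} covers all samples; template has no contrast")
    return template.rename("template")


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p of the t transform
    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise InputError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation with a constant vector")
    res = stats.pearsonr(x, y)
    return float(np.clip(res.statistic, -1, 1)), float(res.pvalue)


def pearson_rows_with_p(X: np.ndarray, y: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson of every row of X against y.

    Constant rows get r = NaN, p = 1 (treated as non-correlated by callers;
    their count is logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[1]
    if n != len(y) or n < 3:
        raise InputError("need aligned vectors of length >= 3")
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("template vector is constant")
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    constant = sx == 0
    if constant.any():
        logger.info("pearson_rows_with_p: %d constant genes treated as "
                    "non-correlated", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r[constant] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[constant] = 1.0
    return r, p


# ---------------------------------------------------------------------------
# surrogate selection
# ---------------------------------------------------------------------------

def select_surrogates(lnc_expr: ExpressionMatrix, labels: pd.Series,
                      normal_expr: ExpressionMatrix,
                      thresholds: GbaThresholds | None = None) -> SurrogateSet:
    """Per-cluster surrogate lncRNAs by template correlation and filters.

    ``lnc_expr`` must cover the tumor samples of ``labels``;
    ``normal_expr`` holds the same genes over normal samples.  The BH
    family for the overexpression test is, per cluster, the set of genes
    passing the correlation and expression filters.
    """
    thresholds = thresholds or GbaThresholds()
    thresholds.validate()
    if normal_expr is None or normal_expr.shape[1] == 0:
        raise InputError("no normal samples available for the overexpression test")
    missing = labels.index.difference(lnc_expr.sample_ids)
    if len(missing):
        raise InputError(f"expression lacks tumor samples: {list(missing[:5])}")
    if not lnc_expr.gene_ids.equals(normal_expr.gene_ids):
        raise InputError("tumor and normal matrices must share the same genes")

    tumor_raw = lnc_expr.values[labels.index]
    tumor_log = np.log2(tumor_raw + 1.0)
    normal_log = np.log2(normal_expr.values + 1.0).to_numpy()
    normal_mean = normal_log.mean(axis=1)

    clusters: dict[int, ClusterSurrogates] = {}
    for cluster in sorted(labels.unique()):
        template = make_template(labels, cluster)
        r, p = pearson_rows_with_p(tumor_log.to_numpy(), template.to_numpy())
        in_cols = labels.index[labels == cluster]
        cluster_mean_rpkm = tumor_raw[in_cols].mean(axis=1).to_numpy()
        candidates = (
            (r > thresholds.surrogate_r)
            & (p < thresholds.surrogate_p)
            & (cluster_mean_rpkm >= thresholds.min_cluster_rpkm)
        )
        idx = np.flatnonzero(candidates)
        if idx.size:
            in_mask = labels == cluster
            tum = tumor_log.to_numpy()[idx][:, in_mask.to_numpy()]
            tt = stats.ttest_ind(tum, normal_log[idx], axis=1, equal_var=False)
            adj = bh_adjust(tt.pvalue, method=thresholds.correction)
            over = (
                (adj < thresholds.overexpr_alpha)
                & (tum.mean(axis=1) > normal_mean[idx])
            )
            sel = idx[over]
            frame = pd.DataFrame({
                "r": r[sel],
                "p": p[sel],
                "cluster_mean_rpkm": cluster_mean_rpkm[sel],
                "overexpr_adj_p": adj[over],
            }, index=tumor_log.index[sel])
            frame = frame.sort_values("r", ascending=False)
        else:
            frame = pd.DataFrame(
                columns=["r", "p", "cluster_mean_rpkm", "overexpr_adj_p"])
        if frame.empty:
            logger.info("cluster %s: no surrogate lncRNAs selected", cluster)
            profile = None
        else:
            profile = cluster_mean_profile(lnc_expr, frame.index,
                                           sample_ids=labels.index)
        clusters[cluster] = ClusterSurrogates(
            cluster=int(cluster), surrogates=frame, mean_profile=profile,
            up_pcgs=pd.DataFrame(columns=["r", "p"]),
            down_pcgs=pd.DataFrame(columns=["r", "p"]),
        )
    return SurrogateSet(clusters)


def cluster_mean_profile(lnc_expr: ExpressionMatrix, surrogate_ids,
                         sample_ids=None) -> pd.Series:
    """Per-sample mean of log2(RPKM + 1) over the surrogate genes."""
    surrogate_ids = pd.Index(surrogate_ids)
    if len(surrogate_ids) == 0:
        raise InputError("empty surrogate list")
    sub = lnc_expr.subset_genes(surrogate_ids)
    values = np.log2(sub.values + 1.0)
    if sample_ids is not None:
        values = values[pd.Index(sample_ids)]
    return values.mean(axis=0).rename("mean_profile")


def correlated_pcgs(pcg_expr: ExpressionMatrix, profile: pd.Series,
                    thresholds: GbaThresholds | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCGs directly/inversely correlated with a cluster's mean profile.

    Returns (up, down) DataFrames with columns r, p, each sorted by |r|
    descending; up has r > pcg_r, down r < -pcg_r, both with p < pcg_p.
    """
    thresholds = thresholds or GbaThresholds()
    thresholds.validate()
    X = np.log2(pcg_expr.values[profile.index] + 1.0)
    r, p = pearson_rows_with_p(X.to_numpy(), profile.to_numpy())
    frame = pd.DataFrame({"r": r, "p": p}, index=X.index)
    sig = frame["p"] < thresholds.pcg_p
    up = frame[sig & (frame["r"] > thresholds.pcg_r)]
    down = frame[sig & (frame["r"] < -thresholds.pcg_r)]
    up = up.reindex(up["r"].abs().sort_values(ascending=False).index)
    down = down.reindex(down["r"].abs().sort_values(ascending=False).index)
    return up, down


def run_gba(expr: ExpressionMatrix, labels: pd.Series,
            thresholds: GbaThresholds | None = None) -> SurrogateSet:
    """Full GBA stage on a combined matrix (lncRNA + PCG, tumor + normal)."""
    thresholds = thresholds or GbaThresholds()
    lnc = expr.select_class("lncRNA")
    pcg = expr.select_class("PCG")
    lnc_tumor = lnc.select_role("tumor").subset_samples(labels.index)
    lnc_normal = lnc.select_role("normal")
    pcg_tumor = pcg.select_role("tumor").subset_samples(labels.index)
    result = select_surrogates(lnc_tumor, labels, lnc_normal, thresholds)
    for cs in result:
        if cs.mean_profile is None:
            continue
        cs.up_pcgs, cs.down_pcgs = correlated_pcgs(
            pcg_tumor, cs.mean_profile, thresholds)
    return result
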