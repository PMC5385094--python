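"""Consensus clustering with PAC-based selection of the cluster number.

The algorithm repeatedly subsamples items (samples) and features (genes),
partitions each subsample into k groups with PAM k-medoids on Euclidean
distance, and records for every item pair the proportion of runs in which
the two items were clustered together among the runs that sampled both.
The resulting per-k consensus matrix is summarized by its empirical CDF and
by the proportion of ambiguous clustering (PAC): the fraction of pairwise
consensus values falling in an intermediate window (default (0.1, 0.9)).
The selected k is the smallest k whose PAC is within a tolerance of the
minimum over the tested range, encoding a preference for fewer clusters
when PAC differences are minor.  Final cluster labels come from
complete-linkage agglomeration of 1 - consensus.

Default settings: k in 2..6, 1000 resamples, 80% item subsampling, 100%
feature subsampling, PAM with a deterministic greedy (BUILD) initialization
followed by steepest-descent SWAP, complete final linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)


@dataclass
class ConsensusParams:
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 1000
    p_item: float = 0.8
    p_feature: float = 1.0
    base_clusterer: str = "k_medoids"
    distance: str = "euclidean"          # or "pearson" for 1 - r
    inner_linkage: str = "complete"      # accepted for config parity; unused
    final_linkage: str = "complete"
    pac_lower: float = 0.1
    pac_upper: float = 0.9
    k_tolerance: float = 0.01
    median_center: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ConfigError("need 2 <= k_min <= k_max")
        if not 0 < self.p_item <= 1 or not 0 < self.p_feature <= 1:
            raise ConfigError("subsampling proportions must be in (0, 1]")
        if not 0 <= self.pac_lower < self.pac_upper <= 1:
            raise ConfigError("need 0 <= pac_lower < pac_upper <= 1")
        if self.n_resamples < 1:
            raise ConfigError("n_resamples must be >= 1")
        if self.base_clusterer != "k_medoids":
            raise ConfigError("only the k_medoids base clusterer is supported")
        if self.distance not in ("euclidean", "pearson"):
            raise ConfigError("distance must be 'euclidean' or 'pearson'")
        if self.inner_linkage != "complete":
            logger.info("inner_linkage=%s is accepted but unused with k-medoids",
                        self.inner_linkage)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and summaries plus the selected k."""

    ks: list[int]
    matrices: dict[int, np.ndarray]
    co_sampled: dict[int, np.ndarray]      # N(i, j): runs sampling both
    co_clustered: dict[int, np.ndarray]    # C(i, j): runs co-clustering both
    cdf: dict[int, pd.DataFrame]
    pac: dict[int, float]
    labels: dict[int, pd.Series]
    selected_k: int

    @property
    def final_labels(self) -> pd.Series:
        return self.labels[self.selected_k]


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------

def pam_kmedoids(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partition items into k groups by PAM on a precomputed distance matrix.

    Deterministic: greedy BUILD initialization followed by steepest-descent
    SWAP until no swap lowers the total within-cluster medoid distance (or
    max_iter sweeps).  Returns integer labels in 0..k-1; ties in nearest
    medoid go to the lowest medoid index.
    """
    n = D.shape[0]
    if not 1 <= k <= n:
        raise InputError(f"k={k} outside 1..{n}")
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dmin = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
        dmin = np.minimum(dmin, D[medoids[-1]])

    med = np.array(medoids)
    for _ in range(max_iter):
        Dm = D[med]                                   # k x n
        nearest = np.argmin(Dm, axis=0)
        best = Dm[nearest, np.arange(n)]
        if k > 1:
            part = np.partition(Dm, 1, axis=0)
            second = part[1]
        else:
            second = np.full(n, np.inf)
        cost = best.sum()
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[med] = True
        cand = np.flatnonzero(~is_medoid)
        best_delta, best_swap = -1e-9, None
        for mi in range(k):
            without = np.where(nearest == mi, second, best)
            new_costs = np.minimum(without[None, :], D[cand]).sum(axis=1)
            j = int(np.argmin(new_costs))
            delta = cost - new_costs[j]
            if delta > best_delta:
                best_delta, best_swap = delta, (mi, cand[j])
        if best_swap is None:
            break
        med[best_swap[0]] = best_swap[1]
    Dm = D[med]
    return np.argmin(Dm, axis=0)


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise item distances; X is features x items."""
    if metric == "euclidean":
        return squareform(pdist(X.T, metric="euclidean"))
    if metric == "pearson":
        return squareform(pdist(X.T, metric="correlation"))
    raise ConfigError(f"unknown distance {metric!r}")


# ---------------------------------------------------------------------------
# resampling and consensus
# ---------------------------------------------------------------------------

def run_resamples(X: np.ndarray, k: int, params: ConsensusParams,
                  rng: np.random.Generator | None = None
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subsampled k-medoids partitions of the item columns of X.

    X is a features x items array, already transformed and feature-selected.
    Each of n_resamples runs draws ceil(p_item * n) items and
    ceil(p_feature * m) features without replacement and partitions the
    sampled items into k groups.  Returns (item_indices, labels) per run.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng([int(params.seed), int(k)])
    m, n = X.shape
    n_items = int(np.ceil(params.p_item * n))
    n_feats = int(np.ceil(params.p_feature * m))
    runs = []
    for _ in range(params.n_resamples):
        for attempt in range(10):
            items = np.sort(rng.choice(n, size=n_items, replace=False))
            if k <= n_items:
                break
            logger.warning("resample drew fewer items than k; retrying")
        else:
            raise InputError(f"k={k} exceeds sampled item count {n_items}")
        if n_feats < m:
            feats = np.sort(rng.choice(m, size=n_feats, replace=False))
            sub = X[np.ix_(feats, items)]
        else:
            sub = X[:, items]
        D = _distance_matrix(sub, params.distance)
        labels = pam_kmedoids(D, k)
        runs.append((items, labels))
    return runs


def co_counts(runs, n_items: int) -> tuple[np.ndarray, np.ndarray]:
    """N(i,j) = runs sampling both i and j; C(i,j) = runs co-clustering them."""
    N = np.zeros((n_items, n_items))
    C = np.zeros((n_items, n_items))
    for items, labels in runs:
        N[np.ix_(items, items)] += 1
        for lab in np.unique(labels):
            members = items[labels == lab]
            C[np.ix_(members, members)] += 1
    return N, C


def consensus_matrix(runs, n_items: int) -> np.ndarray:
    """M(i,j) = C(i,j) / N(i,j), with unit diagonal.

    Errors if some pair was never co-sampled (its consensus is undefined);
    raising with advice beats silently writing a 0 or NaN.
    """
    N, C = co_counts(runs, n_items)
    off = ~np.eye(n_items, dtype=bool)
    if np.any(N[off] == 0):
        raise InputError(
            "some item pair was never co-sampled; "
            "increase n_resamples or p_item"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(N > 0, C / np.maximum(N, 1), 0.0)
    np.fill_diagonal(M, 1.0)
    return M


def _lower_triangle(M: np.ndarray) -> np.ndarray:
    return M[np.tril_indices(M.shape[0], k=-1)]


def pac(M: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of strict-lower-triangle
    consensus entries strictly inside (lower, upper)."""
    if lower >= upper:
        raise ConfigError("need lower < upper")
    tri = _lower_triangle(M)
    if tri.size == 0:
        raise InputError("matrix has no off-diagonal entries")
    return float(np.mean((tri > lower) & (tri < upper)))


def consensus_cdf(M: np.ndarray) -> pd.DataFrame:
    """Empirical CDF of the strict-lower-triangle entries on a 0..1 grid
    with step 0.01, as a DataFrame with columns threshold, cdf."""
    tri = np.sort(_lower_triangle(M))
    grid = np.round(np.arange(0, 101) / 100.0, 2)
    counts = np.searchsorted(tri, grid, side="right")
    return pd.DataFrame({"threshold": grid, "cdf": counts / tri.size})


def final_clusters(M: np.ndarray, k: int, sample_ids=None,
                   method: str = "complete") -> pd.Series:
    """Cut a complete-linkage tree on dissimilarity 1 - M at k groups.

    Labels are renumbered 1..k by decreasing cluster size, ties broken by
    the smallest contained sample id.
    """
    n = M.shape[0]
    if not 2 <= k <= n:
        raise ConfigError(f"k={k} outside 2..{n}")
    if sample_ids is None:
        sample_ids = pd.RangeIndex(n)
    sample_ids = pd.Index(sample_ids)
    dissim = 1.0 - M
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    Z = linkage(condensed, method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    return _renumber(pd.Series(raw, index=sample_ids, name="cluster"))


def _renumber(labels: pd.Series) -> pd.Series:
    """Relabel clusters 1..k by decreasing size; ties by smallest sample id."""
    order = sorted(
        labels.unique(),
        key=lambda c: (-(labels == c).sum(), min(labels.index[labels == c])),
    )
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return labels.map(mapping).rename("cluster")


def select_k(pac_by_k: dict[int, float], tolerance: float = 0.01) -> int:
    """Smallest k whose PAC is within tolerance of the minimum PAC."""
    if not pac_by_k:
        raise ConfigError("pac_by_k is empty")
    best = min(pac_by_k.values())
    return min(k for k, v in sorted(pac_by_k.items()) if v <= best + tolerance)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def consensus_cluster(data: pd.DataFrame,
                      params: ConsensusParams | None = None) -> ConsensusResult:
    """Run the full consensus procedure on a features x items DataFrame.

    ``data`` must already be on the clustering scale (log2(RPKM + 1)) and
    feature-selected; columns are the items to cluster.
    """
    params = params or ConsensusParams()
    params.validate()
    X = data.to_numpy(dtype=float)
    if params.median_center:
        X = X - np.median(X, axis=1, keepdims=True)
    n = X.shape[1]
    if params.k_max > n:
        raise ConfigError(f"k_max={params.k_max} exceeds item count {n}")
    ks = list(range(params.k_min, params.k_max + 1))
    matrices, Ns, Cs, cdfs, pacs, labels = {}, {}, {}, {}, {}, {}
    for k in ks:
        runs = run_resamples(X, k, params)
        N, C = co_counts(runs, n)
        off = ~np.eye(n, dtype=bool)
        if np.any(N[off] == 0):
            raise InputError(
                "some item pair was never co-sampled; "
                "increase n_resamples or p_item"
            )
        M = np.where(N > 0, C / np.maximum(N, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        matrices[k], Ns[k], Cs[k] = M, N, C
        cdfs[k] = consensus_cdf(M)
        pacs[k] = pac(M, params.pac_lower, params.pac_upper)
        labels[k] = final_clusters(M, k, data.columns,
                                   method=params.final_linkage)
        logger.info("consensus k=%d: PAC=%.4f", k, pacs[k])
    selected = select_k(pacs, params.k_tolerance)
    return ConsensusResult(ks, matrices, Ns, Cs, cdfs, pacs, labels, selected)
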