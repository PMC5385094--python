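import numpy as np
import pandas as pd
import pytest

from lncluster.consensus_clustering import (
    ConsensusParams,
    co_counts,
    consensus_cdf,
    consensus_cluster,
    consensus_matrix,
    final_clusters,
    pac,
    pam_kmedoids,
    run_resamples,
    select_k,
)
from lncluster.errors import ConfigError, InputError
from lncluster.pipeline import compare_partitions


def random_consensus_like(n, rng):
    """Random symmetric matrix with unit diagonal and entries in [0, 1]."""
    A = rng.random((n, n))
    M = (A + A.T) / 2
    np.fill_diagonal(M, 1.0)
    return M


# ---------------------------------------------------------------------------
# consensus matrix from explicit runs (enumeration oracle)
# ---------------------------------------------------------------------------

FIXTURE_RUNS = [
    (np.array([0, 1, 2]), np.array([0, 0, 1])),       # {1,2} | {3}
    (np.array([0, 1, 3]), np.array([0, 1, 1])),       # {1} | {2,4}
    (np.array([0, 1, 2, 3]), np.array([0, 0, 1, 1])), # {1,2} | {3,4}
]


def test_consensus_matrix_enumeration_fixture():
    M = consensus_matrix(FIXTURE_RUNS, 4)
    assert M[0, 1] == pytest.approx(2 / 3)   # co-sampled 3x, co-clustered 2x
    assert M[1, 3] == pytest.approx(1 / 2)   # co-sampled 2x, co-clustered 1x
    assert np.allclose(M, M.T)
    assert np.allclose(np.diag(M), 1.0)


def test_consensus_matrix_matches_loop_oracle():
    rng = np.random.default_rng(0)
    n = 8
    runs = []
    for _ in range(30):
        items = np.sort(rng.choice(n, size=6, replace=False))
        labels = rng.integers(0, 3, size=6)
        runs.append((items, labels))
    M = consensus_matrix(runs, n)
    # independent O(runs * n^2) loop
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            N = C = 0
            for items, labels in runs:
                pos = {it: lab for it, lab in zip(items, labels)}
                if i in pos and j in pos:
                    N += 1
                    if pos[i] == pos[j]:
                        C += 1
            assert M[i, j] == pytest.approx(C / N)


def test_always_coclustered_pair_gives_ones():
    runs = [(np.array([0, 1]), np.array([0, 0]))] * 5
    assert np.allclose(consensus_matrix(runs, 2), 1.0)


def test_never_cosampled_pair_is_an_error():
    runs = [(np.array([0, 1]), np.array([0, 0]))]
    with pytest.raises(InputError, match="co-sampled"):
        consensus_matrix(runs, 3)


# ---------------------------------------------------------------------------
# PAC and CDF
# ---------------------------------------------------------------------------

def test_pac_zero_for_perfect_consensus():
    M = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
    assert pac(M) == 0.0


def test_pac_hand_counted():
    M = np.eye(4)
    tril = [(1, 0, 0.0), (2, 0, 0.5), (2, 1, 1.0), (3, 0, 0.95),
            (3, 1, 0.2), (3, 2, 0.3)]
    for i, j, v in tril:
        M[i, j] = M[j, i] = v
    # strictly inside (0.1, 0.9): 0.5, 0.2, 0.3 -> 3 of 6
    assert pac(M, 0.1, 0.9) == pytest.approx(0.5)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_pac_matches_explicit_loop(seed):
    rng = np.random.default_rng(seed)
    M = random_consensus_like(9, rng)
    count = total = 0
    for i in range(9):
        for j in range(i):
            total += 1
            if 0.1 < M[i, j] < 0.9:
                count += 1
    assert pac(M, 0.1, 0.9) == pytest.approx(count / total)


def test_pac_bad_window_rejected():
    with pytest.raises(ConfigError):
        pac(np.eye(3), 0.9, 0.1)


def test_cdf_degenerate_all_ones():
    M = np.ones((3, 3))
    cdf = consensus_cdf(M).set_index("threshold")["cdf"]
    assert (cdf[cdf.index < 1.0] == 0.0).all()
    assert cdf[1.0] == 1.0


def test_cdf_two_point_mass():
    M = np.eye(4)
    vals = [0.2, 0.2, 0.2, 0.8, 0.8, 0.8]
    k = 0
    for i in range(4):
        for j in range(i):
            M[i, j] = M[j, i] = vals[k]
            k += 1
    cdf = consensus_cdf(M).set_index("threshold")["cdf"]
    assert cdf[0.1] == 0.0
    assert cdf[0.2] == pytest.approx(0.5)
    assert cdf[0.79] == pytest.approx(0.5)
    assert cdf[0.8] == 1.0


def test_cdf_matches_sorted_rank_oracle():
    rng = np.random.default_rng(3)
    M = random_consensus_like(10, rng)
    tri = sorted(M[np.tril_indices(10, k=-1)])
    cdf = consensus_cdf(M)
    for thr, value in zip(cdf["threshold"], cdf["cdf"]):
        assert value == pytest.approx(
            sum(v <= thr for v in tri) / len(tri))


# ---------------------------------------------------------------------------
# final clusters
# ---------------------------------------------------------------------------

def naive_complete_linkage(D, k):
    """O(n^3) textbook agglomeration: repeatedly merge the pair of clusters
    with the smallest maximum inter-point distance."""
    clusters = [[i] for i in range(len(D))]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i][j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(D), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


def test_block_diagonal_blocks_recovered():
    M = np.zeros((6, 6))
    M[:3, :3] = 1.0
    M[3:, 3:] = 1.0
    labels = final_clusters(M, 2)
    assert labels.nunique() == 2
    assert labels.iloc[:3].nunique() == 1 and labels.iloc[3:].nunique() == 1
    # renumbering: equal sizes, tie broken by smallest sample id -> first block is 1
    assert labels.iloc[0] == 1


def test_k_equals_n_gives_singletons():
    rng = np.random.default_rng(1)
    M = random_consensus_like(5, rng)
    assert final_clusters(M, 5).nunique() == 5


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("k", [2, 3, 4])
def test_final_clusters_matches_naive_oracle(seed, k):
    rng = np.random.default_rng(seed)
    n = 8 + (seed % 3)
    M = random_consensus_like(n, rng)
    ours = final_clusters(M, k)
    oracle = naive_complete_linkage(1.0 - M, k)
    assert compare_partitions(
        ours, pd.Series(oracle, index=ours.index)) == pytest.approx(1.0)


def test_label_renumbering_by_size():
    M = np.zeros((5, 5))
    M[:2, :2] = 1.0
    M[2:, 2:] = 1.0
    labels = final_clusters(M, 2, sample_ids=list("abcde"))
    assert list(labels[["c", "d", "e"]]) == [1, 1, 1]   # larger cluster is 1
    assert list(labels[["a", "b"]]) == [2, 2]


def test_k_out_of_range_rejected():
    with pytest.raises(ConfigError):
        final_clusters(np.eye(4), 5)


# ---------------------------------------------------------------------------
# select_k
# ---------------------------------------------------------------------------

def test_select_k_prefers_smaller_within_tolerance():
    assert select_k({2: 0.30, 3: 0.25, 4: 0.12, 5: 0.050, 6: 0.049},
                    tolerance=0.01) == 5


def test_select_k_single_entry():
    assert select_k({2: 0.4}) == 2


def test_select_k_unique_minimum_zero_tolerance():
    assert select_k({2: 0.5, 3: 0.1, 4: 0.3}, tolerance=0) == 3


def test_select_k_empty_rejected():
    with pytest.raises(ConfigError):
        select_k({})


# ---------------------------------------------------------------------------
# resampling + PAM
# ---------------------------------------------------------------------------

def two_cloud_data(rng, n_per=10, sep=8.0):
    a = rng.normal(0.0, 0.5, size=(5, n_per))
    b = rng.normal(sep, 0.5, size=(5, n_per))
    return np.hstack([a, b])


def test_full_subsampling_covers_all_items():
    rng = np.random.default_rng(0)
    X = two_cloud_data(rng)
    params = ConsensusParams(n_resamples=5, p_item=1.0, seed=0)
    runs = run_resamples(X, 2, params)
    for items, labels in runs:
        assert len(items) == X.shape[1]
        assert len(labels) == len(items)


def test_separated_clouds_always_split_identically():
    rng = np.random.default_rng(1)
    X = two_cloud_data(rng)
    params = ConsensusParams(n_resamples=50, p_item=0.8, seed=1)
    for items, labels in run_resamples(X, 2, params):
        truth = (items >= 10).astype(int)
        assert len(np.unique(labels)) == 2
        assert (labels == labels[0]).sum() == (truth == truth[0]).sum()
        assert np.all((labels == labels[0]) == (truth == truth[0]))


def test_resamples_deterministic_given_seed():
    rng = np.random.default_rng(2)
    X = two_cloud_data(rng)
    params = ConsensusParams(n_resamples=10, seed=42)
    runs_a = run_resamples(X, 3, params)
    runs_b = run_resamples(X, 3, params)
    for (ia, la), (ib, lb) in zip(runs_a, runs_b):
        assert np.array_equal(ia, ib) and np.array_equal(la, lb)


def test_pam_exact_on_well_separated_blobs():
    rng = np.random.default_rng(3)
    pts = np.concatenate([rng.normal(c, 0.3, size=(12, 2))
                          for c in (0.0, 10.0, 20.0)])
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = pam_kmedoids(D, 3)
    truth = np.repeat([0, 1, 2], 12)
    assert compare_partitions(pd.Series(labels), pd.Series(truth)) == 1.0


def test_resampling_stability_under_more_resamples():
    """Doubling n_resamples moves consensus entries by a small amount."""
    rng = np.random.default_rng(4)
    X = rng.normal(0, 1, size=(20, 24)) + np.repeat(
        [0.0, 2.5], 12)[None, :] * rng.choice([0, 1], size=(20, 1))
    M = {}
    for reps in (150, 300):
        params = ConsensusParams(k_min=2, k_max=2, n_resamples=reps,
                                 seed=5)
        runs = run_resamples(X, 2, params)
        M[reps] = consensus_matrix(runs, X.shape[1])
    assert np.abs(M[150] - M[300]).mean() < 0.05


# ---------------------------------------------------------------------------
# end-to-end on planted structure
# ---------------------------------------------------------------------------

def test_within_cluster_consensus_exceeds_between(tiny_cohort):
    from lncluster.feature_selection import FeatureSelectionParams, select_features

    lnc = tiny_cohort.expression.select_class("lncRNA").select_role("tumor")
    sel = select_features(lnc, FeatureSelectionParams(top_k=120))
    params = ConsensusParams(k_min=3, k_max=3, n_resamples=100, seed=0)
    res = consensus_cluster(sel.log2(), params)
    M = res.matrices[3]
    truth = tiny_cohort.truth_labels.to_numpy()
    same = truth[:, None] == truth[None, :]
    off = ~np.eye(len(truth), dtype=bool)
    assert M[same & off].mean() > M[~same].mean()
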