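import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncluster.errors import DegenerateTemplateError, InputError, UndefinedCorrelationError
from lncluster.gba import (
    GbaThresholds,
    cluster_mean_profile,
    correlated_pcgs,
    make_template,
    pearson_rows_with_p,
    pearson_with_p,
    run_gba,
    select_surrogates,
)

from conftest import make_expression


class TestTemplate:
    def test_indicator_construction(self):
        labels = pd.Series([1, 1, 2, 3], index=list("abcd"))
        assert list(make_template(labels, 1)) == [1, 1, 0, 0]
        labels2 = pd.Series([1, 2], index=list("ab"))
        assert list(make_template(labels2, 2)) == [0, 1]

    def test_absent_cluster_rejected(self):
        labels = pd.Series([1, 2])
        with pytest.raises(DegenerateTemplateError):
            make_template(labels, 3)

    def test_cluster_covering_all_samples_rejected(self):
        labels = pd.Series([1, 1, 1])
        with pytest.raises(DegenerateTemplateError):
            make_template(labels, 1)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(5.0)
        assert pearson_with_p(x, x)[0] == pytest.approx(1.0)
        assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_evaluated_r(self):
        r, p = pearson_with_p([1, 2, 3, 4, 5], [1, 2, 3, 4, 6])
        assert r == pytest.approx(12 / np.sqrt(148))

    def test_p_is_t_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r, p = pearson_with_p(x, y)
        t = r * np.sqrt(18) / np.sqrt(1 - r ** 2)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 15))
        y = rng.normal(size=15)
        r, p = pearson_rows_with_p(X, y)
        for i in range(12):
            ri, pi = pearson_with_p(X[i], y)
            assert r[i] == pytest.approx(ri, rel=1e-12)
            assert p[i] == pytest.approx(pi, rel=1e-9)

    def test_vectorized_constant_row_non_correlated(self):
        X = np.vstack([np.ones(10), np.arange(10.0)])
        r, p = pearson_rows_with_p(X, np.arange(10.0))
        assert np.isnan(r[0]) and p[0] == 1.0
        assert r[1] == pytest.approx(1.0) and p[1] == 0.0


class TestMeanProfile:
    def test_single_surrogate_equals_transformed_gene(self):
        expr = make_expression([[1.0, 3.0, 7.0]])
        profile = cluster_mean_profile(expr, ["G0"])
        np.testing.assert_allclose(profile, np.log2([2.0, 4.0, 8.0]))

    def test_symmetric_pair_gives_constant(self):
        v = np.array([0.5, 1.0, 1.5, 2.5])
        c = 3.0
        expr = make_expression(np.vstack([2 ** v - 1, 2 ** (c - v) - 1]))
        profile = cluster_mean_profile(expr, ["G0", "G1"])
        np.testing.assert_allclose(profile, c / 2)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        expr = make_expression(rng.gamma(2.0, 2.0, size=(5, 6)))
        profile = cluster_mean_profile(expr, list(expr.gene_ids))
        log2 = np.log2(expr.values + 1.0)
        for j, s in enumerate(expr.sample_ids):
            assert profile[s] == pytest.approx(
                sum(log2.iloc[i, j] for i in range(5)) / 5)

    def test_empty_list_rejected(self):
        expr = make_expression([[1.0, 2.0]])
        with pytest.raises(InputError):
            cluster_mean_profile(expr, [])


def planted_surrogate_fixture(seed=0, n_per=30, n_clusters=2):
    """lncRNA matrix with one planted template-follower per cluster, one
    flat gene, one noise gene, plus a normal block."""
    rng = np.random.default_rng(seed)
    n = n_per * n_clusters
    labels = pd.Series(np.repeat(np.arange(1, n_clusters + 1), n_per),
                       index=[f"T{i}" for i in range(n)])
    rows = {}
    for c in range(1, n_clusters + 1):
        template = (labels == c).to_numpy()
        x = 1.0 + 2.0 * template + rng.normal(0, 0.1, size=n)
        rows[f"follow_c{c}"] = np.maximum(0, 2.0 ** x - 1)
    rows["flat"] = np.full(n, 1.0)
    rows["noise"] = np.maximum(0, 2.0 ** rng.normal(1, 0.5, size=n) - 1)
    tumor = pd.DataFrame(rows).T
    tumor.columns = labels.index
    normals = pd.DataFrame(
        np.maximum(0, 2.0 ** rng.normal(1.0, 0.1, size=(len(rows), 10)) - 1),
        index=tumor.index, columns=[f"N{i}" for i in range(10)])
    # planted followers are near zero RPKM in normals (overexpressed in tumors)
    for c in range(1, n_clusters + 1):
        normals.loc[f"follow_c{c}"] = np.maximum(
            0, 2.0 ** rng.normal(0.2, 0.1, size=10) - 1)
    expr_t = make_expression(tumor.to_numpy(), gene_ids=list(tumor.index),
                             sample_ids=list(tumor.columns))
    expr_n = make_expression(normals.to_numpy(), gene_ids=list(normals.index),
                             sample_ids=list(normals.columns),
                             sample_role="normal")
    return expr_t, expr_n, labels


class TestSelectSurrogates:
    def test_planted_follower_selected_and_filters_recorded(self):
        expr_t, expr_n, labels = planted_surrogate_fixture()
        result = select_surrogates(expr_t, labels, expr_n, GbaThresholds())
        for c in (1, 2):
            sel = result[c].surrogates
            assert f"follow_c{c}" in sel.index
            row = sel.loc[f"follow_c{c}"]
            assert row["r"] > 0.3 and row["p"] < 1e-6
            assert row["cluster_mean_rpkm"] >= 0.1
            assert row["overexpr_adj_p"] < 0.05
            assert f"follow_c{3 - c}" not in sel.index

    def test_flat_gene_never_selected(self):
        expr_t, expr_n, labels = planted_surrogate_fixture(seed=1)
        result = select_surrogates(expr_t, labels, expr_n, GbaThresholds())
        for c in (1, 2):
            assert "flat" not in result[c].surrogates.index

    def test_no_normals_is_error(self):
        expr_t, _, labels = planted_surrogate_fixture()
        empty = make_expression(np.empty((4, 0)),
                                gene_ids=list(expr_t.gene_ids),
                                sample_ids=[], sample_role=[])
        with pytest.raises(InputError, match="normal"):
            select_surrogates(expr_t, labels, empty, GbaThresholds())

    def test_default_thresholds(self):
        thr = GbaThresholds()
        assert (thr.surrogate_r, thr.surrogate_p) == (0.3, 1e-6)
        assert thr.min_cluster_rpkm == 0.1
        assert thr.overexpr_alpha == 0.05
        assert (thr.pcg_r, thr.pcg_p) == (0.3, 1e-9)


class TestCorrelatedPcgs:
    def test_direct_and_inverse_recovery(self):
        rng = np.random.default_rng(3)
        # keep the profile in [1, 4] so the RPKM floor at 0 never bites
        profile = pd.Series(rng.uniform(1.0, 4.0, size=50),
                            index=[f"T{i}" for i in range(50)])
        up_vals = 2.0 ** profile.to_numpy() - 1
        down_vals = 2.0 ** (5.0 - profile.to_numpy()) - 1
        expr = make_expression(np.vstack([up_vals, down_vals]),
                               gene_ids=["up", "down"],
                               sample_ids=list(profile.index),
                               gene_class="PCG")
        up, down = correlated_pcgs(expr, profile, GbaThresholds())
        assert list(up.index) == ["up"]
        assert up.loc["up", "r"] == pytest.approx(1.0)
        assert list(down.index) == ["down"]
        assert down.loc["down", "r"] == pytest.approx(-1.0)

    def test_independent_noise_excluded(self):
        rng = np.random.default_rng(4)
        n = 300
        profile = pd.Series(rng.normal(2, 1, size=n),
                            index=[f"T{i}" for i in range(n)])
        noise = np.maximum(0, 2.0 ** rng.normal(2, 1, size=(40, n)) - 1)
        expr = make_expression(noise, sample_ids=list(profile.index),
                               gene_class="PCG")
        up, down = correlated_pcgs(expr, profile, GbaThresholds())
        assert up.empty and down.empty


def test_run_gba_recovers_planted_markers_with_truth_labels(tiny_cohort):
    result = run_gba(tiny_cohort.expression, tiny_cohort.truth_labels)
    for cluster, planted in tiny_cohort.truth_markers.items():
        cs = result[cluster]
        selected = set(cs.surrogates.index)
        hits = len(selected & set(planted["lnc"]))
        assert hits / len(planted["lnc"]) >= 0.9
        up_hits = len(set(cs.up_pcgs.index) & set(planted["pcg_up"]))
        down_hits = len(set(cs.down_pcgs.index) & set(planted["pcg_down"]))
        assert up_hits / len(planted["pcg_up"]) >= 0.9
        assert down_hits / len(planted["pcg_down"]) >= 0.9
        # no cross-contamination from other clusters' markers
        for other, other_planted in tiny_cohort.truth_markers.items():
            if other != cluster:
                assert not selected & set(other_planted["lnc"])
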