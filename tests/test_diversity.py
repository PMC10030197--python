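"""Composition clustering: matrix construction, PAM, k selection, tests, summaries."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ssf_assess as sa
from ssf_assess.diversity import (CompositionMatrix, anova_cluster_year,
                                  build_composition_matrix, cluster_k,
                                  manhattan_distance_matrix,
                                  manova_cluster_species, select_k,
                                  summarize_clusters)


def _species_df(rows):
    return pd.DataFrame(rows, columns=["fisher_id", "period_tag", "year_assigned",
                                       "species_id", "catch_kg"])


class TestCompositionMatrix:
    def test_keeps_top_n_by_total_catch(self):
        df = _species_df([("F1", "first", 1990, "a", 5.0),
                          ("F1", "first", 1990, "b", 1.0),
                          ("F2", "last", 2019, "b", 1.0),
                          ("F2", "last", 2019, "c", 4.0)])
        comp = build_composition_matrix(df, top_n=2)
        assert comp.species == ["a", "c"]  # totals 5 and 4 beat b's 2
        assert comp.values.shape == (2, 2)

    def test_proportion_mode_normalizes_rows(self):
        df = _species_df([("F1", "first", 1990, "a", 3.0),
                          ("F1", "first", 1990, "b", 1.0)])
        comp = build_composition_matrix(df, top_n=2, mode="proportion")
        np.testing.assert_allclose(comp.values.iloc[0], [0.75, 0.25])

    def test_boundary_tie_prefers_lexically_smaller_and_warns(self):
        df = _species_df([("F1", "first", 1990, "zeta", 2.0),
                          ("F1", "first", 1990, "alpha", 2.0),
                          ("F1", "first", 1990, "mid", 5.0)])
        with pytest.warns(UserWarning, match="tie"):
            comp = build_composition_matrix(df, top_n=2)
        assert comp.species == ["mid", "alpha"]

    def test_all_zero_dataset_rejected(self):
        df = _species_df([("F1", "first", 1990, "a", 0.0)])
        with pytest.raises(ValueError):
            build_composition_matrix(df)


class TestManhattan:
    def test_hand_value(self):
        D = manhattan_distance_matrix(np.array([[1.0, 2.0], [4.0, 6.0]]))
        assert D[0, 1] == pytest.approx(7.0)

    def test_symmetric_zero_diagonal(self):
        X = np.random.default_rng(1).uniform(size=(12, 5))
        D = manhattan_distance_matrix(X)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0)


class TestClusterK:
    def test_k_equals_n_costs_nothing(self):
        X = np.random.default_rng(0).uniform(size=(6, 2))
        res = cluster_k(manhattan_distance_matrix(X), 6)
        assert res.total_within_dissimilarity == 0.0
        assert sorted(res.medoid_rows) == list(range(6))

    def test_two_well_separated_pairs(self):
        D = manhattan_distance_matrix(np.array([[0.0], [1.0], [10.0], [11.0]]))
        res = cluster_k(D, 2)
        assert res.assignment[0] == res.assignment[1]
        assert res.assignment[2] == res.assignment[3]
        assert res.assignment[0] != res.assignment[2]
        assert res.total_within_dissimilarity == pytest.approx(2.0)

    def test_matches_exhaustive_search_on_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n, k = int(rng.integers(4, 9)), int(rng.integers(1, 4))
            D = manhattan_distance_matrix(rng.uniform(0, 10, size=(n, 3)))
            res = cluster_k(D, k)
            best = min(D[:, list(m)].min(axis=1).sum()
                       for m in itertools.combinations(range(n), k))
            assert res.total_within_dissimilarity == pytest.approx(best, abs=1e-9)

    def test_medoids_belong_to_their_clusters(self):
        X = np.random.default_rng(3).uniform(size=(20, 4))
        res = cluster_k(manhattan_distance_matrix(X), 4)
        for pos, m in enumerate(res.medoid_rows):
            assert res.assignment[m] == pos

    def test_k_out_of_range_rejected(self):
        D = manhattan_distance_matrix(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            cluster_k(D, 4)


class TestSelectK:
    def test_wss_curve_nonincreasing(self):
        X = np.random.default_rng(5).uniform(size=(25, 4))
        rep = select_k(X, k_max=8, B=10, seed=0)
        assert np.all(np.diff(rep.wss_curve) <= 1e-9)

    def test_silhouette_bounded_and_nan_at_k1(self):
        X = np.random.default_rng(6).uniform(size=(20, 3))
        rep = select_k(X, k_max=6, B=10, seed=0)
        assert np.isnan(rep.mean_silhouette[0])
        valid = rep.mean_silhouette[~np.isnan(rep.mean_silhouette)]
        assert np.all((-1 <= valid) & (valid <= 1))

    def test_degenerate_all_identical_rows_choose_k1(self):
        X = np.ones((10, 3))
        rep = select_k(X, k_max=5, B=10, seed=0)
        assert rep.consensus_k == 1

    def test_same_seed_same_report(self):
        X = np.random.default_rng(7).uniform(size=(18, 4))
        a = select_k(X, k_max=6, B=15, seed=9)
        b = select_k(X, k_max=6, B=15, seed=9)
        np.testing.assert_array_equal(a.wss_curve, b.wss_curve)
        np.testing.assert_array_equal(a.gap, b.gap)
        assert a.chosen_k == b.chosen_k and a.consensus_k == b.consensus_k


class TestAnovaClusterYear:
    def test_hand_computed_f(self):
        res = anova_cluster_year([0, 0, 0, 1, 1, 1], [1, 2, 3, 7, 8, 9])
        assert res.anova_f == pytest.approx(54.0)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_identical_year_distributions_give_f_near_zero(self):
        years = np.tile([1990.0, 2000.0, 2010.0], 4)
        labels = np.repeat([0, 1], 6)
        res = anova_cluster_year(labels, years)
        assert res.anova_f == pytest.approx(0.0, abs=1e-10)
        assert res.p_value > 0.99

    def test_f_equals_squared_t_for_two_clusters(self):
        rng = np.random.default_rng(2)
        years = np.concatenate([rng.normal(1990, 5, 15), rng.normal(2005, 5, 12)])
        labels = np.repeat([0, 1], [15, 12])
        res = anova_cluster_year(labels, years)
        t, _ = stats.ttest_ind(years[:15], years[15:], equal_var=True)
        assert res.anova_f == pytest.approx(t ** 2, rel=1e-10)

    def test_tukey_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(8)
        years = np.concatenate([rng.normal(1990, 6, 10), rng.normal(1994, 6, 10),
                                rng.normal(1998, 6, 10)])
        labels = np.repeat([0, 1, 2], 10)
        res = anova_cluster_year(labels, years)
        msw = sum(np.var(years[labels == u], ddof=1) * 9 for u in (0, 1, 2)) / 27
        for _, row in res.tukey_pairs.iterrows():
            g1, g2 = int(row["group1"]), int(row["group2"])
            diff = years[labels == g2].mean() - years[labels == g1].mean()
            se = np.sqrt(msw * (1 / 10 + 1 / 10))
            p_unadj = 2 * stats.t.sf(abs(diff) / se, 27)
            assert float(row["p-adj"]) >= p_unadj - 1e-9

    def test_singleton_cluster_flagged(self):
        res = anova_cluster_year([0, 0, 0, 1], [1990, 1991, 1992, 2010])
        assert res.singleton_clusters == [1]


class TestManova:
    def test_identical_group_distributions_give_small_pillai(self):
        block = np.random.default_rng(3).uniform(size=(20, 4))
        X = np.vstack([block, block])  # two clusters with identical rows
        labels = np.repeat([0, 1], 20)
        res = manova_cluster_species(X, labels)
        assert res.pillai_trace == pytest.approx(0.0, abs=1e-10)

    def test_single_column_reduces_to_anova_f(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 12), rng.normal(1.5, 1, 12)])
        labels = np.repeat([0, 1], 12)
        res = manova_cluster_species(x[:, None], labels)
        f, _ = stats.f_oneway(x[:12], x[12:])
        assert res.approx_f == pytest.approx(f, rel=1e-9)

    def test_matches_statsmodels_manova_pillai(self):
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3)) + np.repeat([[0, 0, 0], [1, 0.5, 0], [0, 1, 1]],
                                                 10, axis=0)
        labels = np.repeat([0, 1, 2], 10)
        ours = manova_cluster_species(X, labels)
        df = pd.DataFrame(X, columns=["a", "b", "c"]).assign(g=labels.astype(str))
        mv = MANOVA.from_formula("a + b + c ~ g", data=df)
        tab = mv.mv_test().results["g"]["stat"]
        assert ours.pillai_trace == pytest.approx(float(tab.loc["Pillai's trace", "Value"]),
                                                  rel=1e-8)
        assert ours.approx_f == pytest.approx(float(tab.loc["Pillai's trace", "F Value"]),
                                              rel=1e-6)

    def test_separated_single_species_hits_pillai_upper_bound(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])[:, None]
        res = manova_cluster_species(x, np.repeat([0, 1], 10))
        assert res.pillai_trace == pytest.approx(1.0)  # upper bound min(p, k-1) = 1


class TestSummaries:
    def test_single_cluster_median_year(self):
        X = np.random.default_rng(6).uniform(size=(5, 3))
        summ = summarize_clusters(X, np.zeros(5, dtype=int), [1980.0] * 5)
        assert summ.table.median_year.iloc[0] == 1980.0

    def test_uniform_composition_has_unit_evenness(self):
        X = np.ones((6, 12))
        summ = summarize_clusters(X, np.zeros(6, dtype=int), np.arange(6, dtype=float))
        assert summ.table.evenness.iloc[0] == pytest.approx(1.0)
        assert summ.table.dominance.iloc[0] == pytest.approx(1 / 12)

    def test_funnel_requires_strictly_decreasing_dominance(self):
        X = np.array([[9.0, 1.0], [9.0, 1.0],     # early, dominated
                      [6.0, 4.0], [6.0, 4.0],     # mid
                      [5.0, 5.0], [5.0, 5.0]])    # late, even
        labels = np.array([0, 0, 1, 1, 2, 2])
        years = np.array([1970, 1971, 1995, 1996, 2018, 2019], dtype=float)
        assert summarize_clusters(X, labels, years).funnel
        # reverse time ordering breaks the funnel
        assert not summarize_clusters(X, labels, years[::-1].copy()).funnel


def test_clusterer_estimator_interface():
    from sklearn.base import clone
    rng = np.random.default_rng(9)
    X = np.vstack([rng.dirichlet([20, 2, 2, 2], 15), rng.dirichlet([2, 2, 20, 2], 15)])
    clus = sa.CompositionClusterer(n_clusters=2)
    assert clone(clus).get_params()["n_clusters"] == 2
    labels = clus.fit_predict(X)
    assert len(np.unique(labels)) == 2
    assert clus.k_ == 2 and clus.inertia_ > 0
    auto = sa.CompositionClusterer(n_clusters="auto", k_max=5, gap_b=10, random_state=0).fit(X)
    assert auto.selection_report_.consensus_k == auto.k_
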