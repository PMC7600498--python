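"""Descriptor ranking, correspondence analysis, consensus clustering, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency
from sklearn.metrics import adjusted_rand_score

from catapanel import (
    CatapanelWarning,
    FrequencyTable,
    ca_cell_contributions,
    cluster_products,
    cluster_profile,
    consensus_cluster_count,
    correspondence_analysis,
    select_ca_attributes,
    spider_data,
    top_descriptors,
)


def _freq(counts, denominator):
    frame = pd.DataFrame(counts)
    frame.index = [f"P{i+1}" for i in range(len(frame))]
    frame.columns = [f"A{i+1}" for i in range(frame.shape[1])]
    return FrequencyTable(frame, pd.Series(float(denominator), index=frame.index))


class TestTopDescriptors:
    def test_orders_by_proportion(self):
        freq = _freq([[6, 4, 2, 0]], 10)
        tops = top_descriptors(freq, k=3)
        assert tops["P1"] == [("A1", 0.6), ("A2", 0.4), ("A3", 0.2)]

    def test_zero_proportions_suppressed(self):
        freq = _freq([[3, 2, 1, 0, 0]], 10)
        tops = top_descriptors(freq, k=5)
        assert len(tops["P1"]) == 3

    def test_tie_broken_alphabetically(self):
        freq = _freq([[2, 2, 2, 1]], 10)
        tops = top_descriptors(freq, k=2)
        assert [a for a, _ in tops["P1"]] == ["A1", "A2"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_descriptors(_freq([[1, 2]], 10), k=3)


class TestSelectCaAttributes:
    def test_union_of_top_n(self):
        freq = _freq([[5, 3, 1, 0], [0, 1, 3, 5]], 10)
        assert set(select_ca_attributes(freq, top_n=2)) == {"A1", "A2", "A3", "A4"}

    def test_include_forces_membership(self):
        freq = _freq([[5, 3, 1, 0], [5, 3, 1, 0]], 10)
        selected = select_ca_attributes(freq, top_n=2, include=["A4"])
        assert "A4" in selected

    def test_exclude_removes(self):
        freq = _freq([[5, 3, 1, 0]], 10)
        assert "A1" not in select_ca_attributes(freq, top_n=2, exclude=["A1"])

    def test_order_by_overall_citation(self):
        freq = _freq([[1, 5, 3, 0], [1, 5, 3, 0]], 10)
        assert select_ca_attributes(freq, top_n=3) == ["A2", "A3", "A1"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            select_ca_attributes(_freq([[1, 2]], 10), include=["Zest"])


class TestCorrespondenceAnalysis:
    def test_diagonal_table_fixture(self):
        ca = correspondence_analysis(pd.DataFrame([[10, 0], [0, 10]]))
        assert ca.total_inertia == pytest.approx(1.0, abs=1e-12)
        assert ca.chi2 == pytest.approx(20.0, abs=1e-12)  # equals the table total
        assert ca.explained_inertia[0] == pytest.approx(100.0)

    def test_rank_one_table_zero_inertia(self):
        table = pd.DataFrame(np.outer([1, 2, 3], [4, 5, 6]), dtype=float)
        with pytest.warns(CatapanelWarning, match="independent"):
            ca = correspondence_analysis(table)
        assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_inertia_accounting_random_tables(self, rng):
        for _ in range(50):
            shape = (rng.integers(3, 8), rng.integers(3, 7))
            table = pd.DataFrame(rng.integers(1, 40, shape).astype(float))
            ca = correspondence_analysis(table)
            chi2 = chi2_contingency(table.to_numpy(), correction=False)[0]
            assert abs(ca.eigenvalues.sum() - chi2 / table.to_numpy().sum()) < 1e-10
            assert ca.explained_inertia.sum() == pytest.approx(100.0, abs=1e-9)
            np.testing.assert_allclose(ca.row_masses @ ca.row_coordinates, 0, atol=1e-9)
            np.testing.assert_allclose(ca.col_masses @ ca.col_coordinates, 0, atol=1e-9)
            assert np.all(np.diff(ca.eigenvalues) <= 1e-12)

    def test_transition_formulas(self, rng):
        table = pd.DataFrame(rng.integers(1, 30, (6, 5)).astype(float))
        ca = correspondence_analysis(table)
        # row coords = row profiles x column standard coords:
        # F = D_r^-1 P G D_sv^-1 (transition between row and column coordinates)
        P = ca.correspondence
        sv = np.sqrt(ca.eigenvalues)
        approx = (P / ca.row_masses[:, None]) @ ca.col_coordinates / sv
        np.testing.assert_allclose(approx, ca.row_coordinates, atol=1e-9)

    def test_identical_rows_identical_coordinates(self):
        table = pd.DataFrame([[5, 1, 2], [5, 1, 2], [1, 6, 3]], dtype=float)
        ca = correspondence_analysis(table)
        np.testing.assert_allclose(
            ca.row_coordinates[0], ca.row_coordinates[1], atol=1e-10
        )

    def test_sign_convention_stable(self):
        table = pd.DataFrame([[8, 1, 1], [1, 8, 1], [1, 1, 8]], dtype=float)
        ca = correspondence_analysis(table)
        for d in range(ca.n_dimensions):
            extreme = np.argmax(np.abs(ca.row_coordinates[:, d]))
            assert ca.row_coordinates[extreme, d] > 0

    def test_zero_row_dropped_with_warning(self):
        table = pd.DataFrame([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
        with pytest.warns(CatapanelWarning, match="dropped"):
            ca = correspondence_analysis(table)
        assert len(ca.row_labels) == 2


class TestCellContributions:
    def test_diagonal_table_symmetric_contributions(self):
        ca = correspondence_analysis(pd.DataFrame([[10, 0], [0, 10]]))
        np.testing.assert_allclose(ca_cell_contributions(ca).to_numpy(), 25.0)

    def test_contributions_sum_to_100(self, rng):
        table = pd.DataFrame(rng.integers(1, 25, (5, 4)).astype(float))
        ca = correspondence_analysis(table)
        assert ca_cell_contributions(ca).to_numpy().sum() == pytest.approx(100.0, abs=1e-9)

    def test_independence_table_zero_with_warning(self):
        table = pd.DataFrame(np.outer([1, 2], [3, 4]), dtype=float)
        with pytest.warns(CatapanelWarning):
            ca = correspondence_analysis(table)
        with pytest.warns(CatapanelWarning, match="zero total inertia"):
            contrib = ca_cell_contributions(ca)
        assert (contrib.to_numpy() == 0).all()


class TestConsensusClusterCount:
    def test_two_point_masses_unanimous(self, rng):
        X = np.vstack([np.zeros((6, 2)), np.full((6, 2), 50.0)])
        vote = consensus_cluster_count(X, kmax=5, seed=0)
        assert vote.chosen_k == 2
        assert vote.tally[2] == len(vote.votes)

    def test_four_separated_clouds(self, rng):
        centers = np.array([[0, 0], [40, 0], [0, 40], [40, 40]], dtype=float)
        X = np.vstack([c + rng.normal(scale=1.0, size=(4, 2)) for c in centers])
        vote = consensus_cluster_count(X, kmax=8, seed=1)
        assert vote.chosen_k == 4

    def test_vote_tie_prefers_smallest_k(self):
        from catapanel.products import choose_modal_k

        assert choose_modal_k({5: 2, 2: 2, 3: 1}) == 2
        assert choose_modal_k({7: 3, 4: 1}) == 7

    def test_kmax_bound(self, rng):
        with pytest.raises(ValueError, match="kmax"):
            consensus_cluster_count(rng.normal(size=(5, 2)), kmax=5)


class TestClusterProducts:
    def test_each_point_own_cluster(self, rng):
        X = rng.normal(size=(5, 2)) * 10
        labels = cluster_products(X, k=5)
        assert sorted(labels) == [1, 2, 3, 4, 5]

    def test_recovers_separated_clouds(self, rng):
        truth = np.repeat([0, 1, 2, 3], 5)
        centers = np.array([[0, 0], [30, 0], [0, 30], [30, 30]], dtype=float)
        X = centers[truth] + rng.normal(scale=1.0, size=(20, 2))
        labels = cluster_products(X, k=4)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_kmeans_deterministic_under_seed(self, rng):
        X = rng.normal(size=(12, 3))
        a = cluster_products(X, k=3, method="kmeans", seed=5)
        b = cluster_products(X, k=3, method="kmeans", seed=5)
        np.testing.assert_array_equal(a, b)

    def test_unknown_method(self, rng):
        with pytest.raises(ValueError, match="unknown method"):
            cluster_products(rng.normal(size=(6, 2)), k=2, method="fuzzy")


class TestClusterProfile:
    def test_two_by_two_residual_fixture(self):
        freq = _freq([[8, 2], [2, 8]], 10)
        profile = cluster_profile(freq, labels=[1, 2])
        # counts: [[8,2],[2,8]] -> expected all 5 -> residual (8-5)/sqrt(5)
        assert profile.residuals.iloc[0, 0] == pytest.approx(3 / np.sqrt(5), abs=1e-12)

    def test_margin_proportional_table_zero_residuals(self):
        freq = _freq([[4, 2], [8, 4]], 20)
        profile = cluster_profile(freq, labels=[1, 2])
        np.testing.assert_allclose(profile.residuals.to_numpy(), 0.0, atol=1e-12)

    def test_residuals_match_scipy_expected(self, rng):
        counts = rng.integers(1, 20, (5, 3)).astype(float)
        freq = _freq(counts, 30)
        profile = cluster_profile(freq, labels=[1, 2, 3, 1, 2])
        observed = profile.counts.to_numpy()
        expected = chi2_contingency(observed, correction=False)[3]
        np.testing.assert_allclose(
            profile.residuals.to_numpy(), (observed - expected) / np.sqrt(expected)
        )

    def test_attribute_subset_restricts_rows(self):
        freq = _freq([[5, 1, 3], [2, 2, 2]], 10)
        profile = cluster_profile(freq, labels=[1, 2], attributes=["A1", "A3"])
        assert list(profile.counts.index) == ["A1", "A3"]


class TestSpiderData:
    def test_single_product_cluster_is_its_own_profile(self):
        freq = _freq([[4, 2], [6, 0]], 10)
        spider = spider_data(freq, labels=[1, 2])
        np.testing.assert_allclose(spider.loc["Cluster 2"].to_numpy(), [0.6, 0.0])

    def test_two_member_cluster_averages(self):
        freq = _freq([[4, 0], [6, 0]], 10)
        spider = spider_data(freq, labels=[1, 1])
        assert spider.loc["Cluster 1", "A1"] == pytest.approx(0.5)

    def test_matches_explicit_loop(self, rng):
        counts = rng.integers(0, 10, (6, 4)).astype(float)
        freq = _freq(counts, 10)
        labels = [1, 2, 1, 2, 3, 3]
        spider = spider_data(freq, labels)
        for cluster in (1, 2, 3):
            members = [i for i, l in enumerate(labels) if l == cluster]
            expected = np.mean([counts[i] / 10 for i in members], axis=0)
            np.testing.assert_allclose(
                spider.loc[f"Cluster {cluster}"].to_numpy(), expected
            )
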