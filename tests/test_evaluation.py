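import itertools

import numpy as np
import pytest
from conftest import all_partitions, ami_oracle, ari_oracle, fmi_oracle

from nisc.data_model import ExpressionMatrix
from nisc.evaluation import (
    adjusted_mutual_information,
    adjusted_rand_index,
    cluster_and_score,
    fowlkes_mallows,
    rmse,
    silhouette_score,
)
from nisc.simulator import SimConfig, simulate


class TestRmse:
    def test_zero_iff_equal(self, rng):
        a = ExpressionMatrix(rng.gamma(1.0, 5.0, size=(10, 8)))
        assert rmse(a, a) == 0.0
        b = ExpressionMatrix(a.values + 0.5)
        assert rmse(a, b) > 0

    def test_hand_value(self):
        truth = ExpressionMatrix(np.array([[0.0, np.e - 1]]))
        other = ExpressionMatrix(np.array([[0.0, 0.0]]))
        assert rmse(truth, other) == pytest.approx(np.sqrt(0.5))

    def test_symmetry(self, rng):
        a = ExpressionMatrix(rng.gamma(1.0, 5.0, size=(6, 6)))
        b = ExpressionMatrix(rng.gamma(1.0, 5.0, size=(6, 6)))
        assert rmse(a, b) == rmse(b, a)

    def test_raw_scale_option(self):
        a = ExpressionMatrix(np.array([[3.0]]))
        b = ExpressionMatrix(np.array([[0.0]]))
        assert rmse(a, b, scale="raw") == pytest.approx(3.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rmse(ExpressionMatrix(np.ones((2, 2))), ExpressionMatrix(np.ones((2, 3))))


class TestPartitionMetricsAgainstOracles:
    """The sklearn-backed metric surface must agree with independent
    brute-force pair-counting / contingency / permutation-model oracles."""

    METRICS = [
        (adjusted_rand_index, ari_oracle),
        (fowlkes_mallows, fmi_oracle),
        (adjusted_mutual_information, ami_oracle),
    ]

    @pytest.mark.parametrize("impl, oracle", METRICS)
    def test_exhaustive_small_partitions(self, impl, oracle):
        for n in (3, 4, 5):
            parts = list(all_partitions(n))
            for a, b in itertools.product(parts, parts):
                assert impl(list(a), list(b)) == pytest.approx(
                    oracle(list(a), list(b)), abs=1e-9
                ), (a, b)

    @pytest.mark.parametrize("impl, oracle", METRICS)
    def test_random_partitions_of_eight(self, impl, oracle, rng):
        for _ in range(60):
            a = list(rng.integers(0, 3, size=8))
            b = list(rng.integers(0, 4, size=8))
            assert impl(a, b) == pytest.approx(oracle(a, b), abs=1e-9)

    @pytest.mark.parametrize("impl", [m for m, _ in METRICS])
    def test_identical_partitions_score_one(self, impl):
        assert impl([1, 1, 2, 2, 3], [1, 1, 2, 2, 3]) == pytest.approx(1.0)

    @pytest.mark.parametrize("impl", [m for m, _ in METRICS])
    def test_label_name_invariance(self, impl):
        a = [0, 0, 1, 1, 2, 2]
        renamed = [7, 7, 5, 5, 9, 9]
        b = [0, 1, 1, 0, 2, 2]
        assert impl(a, b) == pytest.approx(impl(renamed, b))

    def test_constant_labeling_ami_zero(self):
        assert adjusted_mutual_information([1, 1, 1, 1], [1, 2, 1, 2]) == 0.0

    def test_singletons_vs_one_cluster_fmi_zero(self):
        assert fowlkes_mallows([1, 2, 3, 4], [1, 1, 1, 1]) == 0.0

    def test_random_labelings_concentrate_near_zero(self, rng):
        aris, amis = [], []
        for _ in range(200):
            a = rng.integers(0, 3, size=30)
            b = rng.integers(0, 3, size=30)
            aris.append(adjusted_rand_index(a, b))
            amis.append(adjusted_mutual_information(a, b))
        assert abs(np.mean(aris)) < 0.05
        assert abs(np.mean(amis)) < 0.05

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestSilhouette:
    def test_two_tight_far_clusters(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, (20, 2)), rng.normal(100, 0.01, (20, 2))])
        labels = [0] * 20 + [1] * 20
        assert silhouette_score(pts, labels) > 0.9

    def test_random_labels_near_zero(self, rng):
        pts = rng.normal(0, 1, (100, 2))
        labels = rng.integers(0, 2, 100)
        assert abs(silhouette_score(pts, labels)) < 0.1

    def test_four_point_hand_value(self):
        # pairs (0,0),(0,1) and (5,0),(5,1); a=1, b=(5+sqrt26)/2 for each point
        pts = np.array([[0, 0], [0, 1], [5, 0], [5, 1]], dtype=float)
        labels = [0, 0, 1, 1]
        b = (5 + np.sqrt(26.0)) / 2
        expected = (b - 1) / b
        assert silhouette_score(pts, labels) == pytest.approx(expected)

    def test_single_cluster_raises(self):
        with pytest.raises(ValueError):
            silhouette_score(np.ones((4, 2)), [1, 1, 1, 1])


@pytest.fixture(scope="module")
def strong_sim():
    return simulate(
        SimConfig(n_genes=200, n_cells=300, n_groups=4, de_prob=0.3,
                  de_factor_logmean=0.8, de_factor_logsd=0.4, seed=21)
    )


class TestClusterAndScore:
    def test_truth_with_separated_groups_high_ari(self, strong_sim):
        report = cluster_and_score(strong_sim.truth, strong_sim.labels, k=4, seed=0)
        assert report.ari > 0.95
        assert report.ami > 0.9
        assert report.fmi > 0.9

    def test_report_determinism(self, strong_sim):
        r1 = cluster_and_score(strong_sim.truth, strong_sim.labels, k=4, seed=3)
        r2 = cluster_and_score(strong_sim.truth, strong_sim.labels, k=4, seed=3)
        assert r1 == r2

    def test_includes_rmse_when_truth_given(self, strong_sim):
        report = cluster_and_score(
            strong_sim.raw, strong_sim.labels, k=4, seed=0, truth=strong_sim.truth
        )
        assert report.rmse == pytest.approx(rmse(strong_sim.truth, strong_sim.raw))

    def test_hierarchical_also_recovers_strong_signal(self, strong_sim):
        report = cluster_and_score(
            strong_sim.truth, strong_sim.labels, k=4, clustering="hierarchical", seed=0
        )
        assert report.ari > 0.9

    def test_k_exceeding_cells_raises(self, strong_sim):
        with pytest.raises(ValueError):
            cluster_and_score(strong_sim.truth, strong_sim.labels, k=301)

    def test_unknown_methods_raise(self, strong_sim):
        with pytest.raises(ValueError, match="embedding"):
            cluster_and_score(strong_sim.truth, strong_sim.labels, k=4, embedding="nope")
        with pytest.raises(ValueError, match="clustering"):
            cluster_and_score(strong_sim.truth, strong_sim.labels, k=4, clustering="nope")
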