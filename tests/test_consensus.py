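import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from methsubtypes.consensus import (cdf_area, cluster_consensus,
                                    consensus_cdf, consensus_cdf_area,
                                    consensus_matrices, final_assignments,
                                    kmeans, run_consensus, select_k)


def _blobs(rng, centers, n_per, scale=0.05):
    data = np.vstack([rng.normal(c, scale, size=(n_per, len(c)))
                      for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return data, labels


class TestKmeans:
    def test_two_points_two_singletons(self):
        labels = kmeans(np.array([[0.0], [1.0]]), k=2, seed=0)
        assert labels[0] != labels[1]

    def test_square_corners_matches_exhaustive_oracle(self):
        """k = 2 on the 4 corners of a square: the k-means objective
        equals the best of all 7 bipartitions, enumerated directly."""
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        labels = kmeans(pts, k=2, seed=0)

        def objective(assign):
            total = 0.0
            for c in set(assign):
                grp = pts[[i for i, a in enumerate(assign) if a == c]]
                total += ((grp - grp.mean(axis=0)) ** 2).sum()
            return total

        best = min(objective(a) for a in itertools.product([0, 1], repeat=4)
                   if len(set(a)) == 2)
        assert objective(labels) == pytest.approx(best, abs=1e-12)

    def test_k_larger_than_distinct_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans(np.array([[0.0], [0.0], [1.0]]), k=3, seed=0)


class TestConsensusMatrices:
    def test_single_full_sample_iteration_is_comembership(self, rng):
        data, _ = _blobs(rng, [[0, 0], [5, 5]], 6)
        M = consensus_matrices(data, [2], n_iter=1, subsample_frac=1.0,
                               seed=0)[2]
        assert set(np.unique(M)) <= {0.0, 1.0}
        # co-membership is an equivalence relation: blocks of ones
        labels = M[0]  # row of sample 0 marks its block
        block = labels == 1.0
        assert np.allclose(M[np.ix_(block, block)], 1.0)

    def test_separated_blobs_polarized_consensus(self, rng):
        data, truth = _blobs(rng, [[0, 0], [5, 5]], 10)
        M = consensus_matrices(data, [2], n_iter=100, subsample_frac=0.8,
                               seed=1)[2]
        within = truth[:, None] == truth[None, :]
        off_diag = ~np.eye(len(data), dtype=bool)
        assert M[within & off_diag].min() >= 0.95
        assert M[~within].max() <= 0.05

    def test_matrix_invariants_on_noise(self, rng):
        data = rng.uniform(size=(15, 4))
        for k, M in consensus_matrices(data, [2, 3, 4], n_iter=20,
                                       seed=3).items():
            assert np.allclose(M, M.T)
            assert np.allclose(np.diag(M), 1.0)
            assert M.min() >= 0.0 and M.max() <= 1.0

    def test_deterministic_and_krange_extension_stable(self, rng):
        data = rng.uniform(size=(12, 3))
        a = consensus_matrices(data, [2, 3], n_iter=10, seed=5)
        b = consensus_matrices(data, [2, 3, 4], n_iter=10, seed=5)
        for k in (2, 3):
            assert np.array_equal(a[k], b[k])


class TestCdfArea:
    def test_all_ones_matrix_area_is_one_bin(self):
        M = np.ones((3, 3))
        cdf = consensus_cdf(M)
        assert cdf[-1] == 1.0 and cdf[:-1].max() == 0.0
        assert cdf_area(cdf) == pytest.approx(0.01, abs=1e-15)

    def test_hand_evaluated_three_value_cdf(self):
        """Upper-triangle values {0, 0.5, 1}: CDF steps 1/3, 2/3, 1 and
        the Riemann sum over the 101-point grid is
        0.01 * (49/3 + 100/3 + 1)."""
        M = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 1.0], [0.5, 1.0, 1.0]])
        cdf = consensus_cdf(M)
        assert cdf[0] == pytest.approx(1 / 3)
        assert cdf[50] == pytest.approx(2 / 3)
        assert cdf[100] == 1.0
        expected = 0.01 * (49 / 3 + 100 / 3 + 1)
        assert cdf_area(cdf) == pytest.approx(expected, abs=1e-12)

    def test_delta_area_definition(self):
        M2 = np.ones((3, 3))
        M3 = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 1.0], [0.5, 1.0, 1.0]])
        cdfs, areas, deltas = consensus_cdf_area({2: M2, 3: M3})
        assert deltas[2] == pytest.approx(areas[2])
        assert deltas[3] == pytest.approx((areas[3] - areas[2]) / areas[2])

    def test_noncontiguous_k_range_rejected(self):
        with pytest.raises(ValueError):
            consensus_cdf_area({2: np.ones((3, 3)), 4: np.ones((3, 3))})


class TestClusterConsensusAndSelectK:
    def test_perfect_block_matrix_scores_one(self):
        M = np.kron(np.eye(2), np.ones((3, 3)))
        np.fill_diagonal(M, 1.0)
        labels = [1, 1, 1, 2, 2, 2]
        assert cluster_consensus(M, labels) == {1: 1.0, 2: 1.0}

    def test_three_pair_mean(self):
        M = np.eye(3)
        M[0, 1] = M[1, 0] = 0.9
        M[0, 2] = M[2, 0] = 0.8
        M[1, 2] = M[2, 1] = 1.0
        assert cluster_consensus(M, [1, 1, 1])[1] == pytest.approx(0.9)

    def test_singleton_cluster_scores_one(self):
        assert cluster_consensus(np.eye(2), [1, 2]) == {1: 1.0, 2: 1.0}

    def test_single_eligible_k_chosen_regardless_of_delta(self):
        deltas = {2: 0.9, 3: 0.9, 4: 0.9}
        scores = {2: {1: 0.5}, 3: {1: 0.95, 2: 0.99}, 4: {1: 0.2}}
        chosen, trace = select_k(deltas, scores)
        assert chosen == 3
        assert trace["eligible"] == [3]

    def test_no_eligible_k_falls_back_with_warning(self):
        deltas = {2: 0.1, 3: 0.1}
        scores = {2: {1: 0.6, 2: 0.7}, 3: {1: 0.8, 2: 0.5, 3: 0.6}}
        chosen, trace = select_k(deltas, scores)
        assert chosen == 2  # higher mean cluster consensus
        assert trace["warning"]

    def test_delta_stability_prefers_plateau_k(self):
        deltas = {2: 0.5, 3: 0.4, 4: 0.3, 5: 0.01, 6: 0.01}
        scores = {k: {1: 0.95, 2: 0.95} for k in range(2, 7)}
        chosen, _ = select_k(deltas, scores)
        # 4 is the largest k with all later deltas below tolerance
        # (5 and 6 qualify vacuously upward, so the largest stable is 6)
        assert chosen == 6


class TestFinalAssignments:
    def test_perfect_block_diagonal_recovered(self):
        M = np.kron(np.eye(3), np.ones((4, 4)))
        np.fill_diagonal(M, 1.0)
        labels = final_assignments(M, K=3)
        truth = np.repeat([1, 2, 3], 4)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_manual_average_linkage_merge_order(self):
        """4-sample dendrogram worked by hand: pairs (a,b) then (c,d)
        merge first; the K=2 cut is {a,b} vs {c,d}; equal sizes break
        the label tie toward the cluster holding the first sample."""
        M = np.array([[1.0, 0.9, 0.2, 0.1],
                      [0.9, 1.0, 0.3, 0.2],
                      [0.2, 0.3, 1.0, 0.8],
                      [0.1, 0.2, 0.8, 1.0]])
        labels = final_assignments(M, K=2)
        assert list(labels) == [1, 1, 2, 2]

    def test_labels_ordered_by_decreasing_size(self):
        M = np.kron(np.eye(2), np.ones((3, 3)))
        M = np.pad(M, ((0, 1), (0, 1)))  # add an outlier sample
        np.fill_diagonal(M, 1.0)
        labels = final_assignments(M, K=3)
        sizes = [np.sum(labels == c) for c in (1, 2, 3)]
        assert sizes == sorted(sizes, reverse=True)


class TestRecovery:
    def test_planted_four_subtype_cohort_recovered(self):
        from methsubtypes.synthetic import CohortSpec, generate_cohort
        spec = CohortSpec(n_samples=100, n_cpgs=200, n_subtypes=4,
                          n_specific_per_subtype=50, delta=0.3,
                          missing_frac=0.0, n_flagged_crossreactive=0,
                          n_sexchrom=0, n_snp=0, seed=2)
        cohort = generate_cohort(spec)
        res = run_consensus(cohort.methylation.T.to_numpy(), range(2, 7),
                            n_iter=50, seed=2)
        assert res.chosen_k == 4
        assert adjusted_rand_score(cohort.true_labels, res.labels) >= 0.9

    def test_no_signal_gives_near_zero_ari(self):
        """delta = 0 cohort: clustering cannot recover the latent
        subtype labels."""
        from methsubtypes.synthetic import CohortSpec, generate_cohort
        spec = CohortSpec(n_samples=60, n_cpgs=80, n_subtypes=3,
                          n_specific_per_subtype=10, delta=0.0,
                          missing_frac=0.0, n_flagged_crossreactive=0,
                          n_sexchrom=0, n_snp=0, seed=9)
        cohort = generate_cohort(spec)
        res = run_consensus(cohort.methylation.T.to_numpy(), range(2, 5),
                            n_iter=20, seed=9)
        ari = adjusted_rand_score(cohort.true_labels,
                                  res.labels_per_k[3])
        assert abs(ari) < 0.15
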