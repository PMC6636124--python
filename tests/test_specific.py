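import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from methsubtypes.specific import (annotate_genes, call_specific,
                                   cluster_mean_matrix, find_specific_cpgs,
                                   methylation_entropy,
                                   null_entropy_threshold)


def entropy_oracle(means):
    """Direct evaluation of -sum p log2 p with p = m / sum(m)."""
    m = np.asarray(means, float)
    total = m.sum()
    if total == 0:
        return np.log2(len(m))
    p = m / total
    return float(-sum(pi * np.log2(pi) for pi in p if pi > 0))


class TestClusterMeanMatrix:
    def test_one_sample_per_cluster_returns_values(self):
        m = pd.DataFrame({"s1": [0.2, 0.9], "s2": [0.6, 0.1]},
                         index=["p1", "p2"])
        means = cluster_mean_matrix(m, [1, 2])
        assert means.loc[1, "p1"] == 0.2
        assert means.loc[2, "p2"] == 0.1

    def test_two_by_two_arithmetic(self):
        m = pd.DataFrame({"a": [0.2], "b": [0.4], "c": [0.6], "d": [0.8]},
                         index=["p"])
        means = cluster_mean_matrix(m, [1, 1, 2, 2])
        assert means.loc[1, "p"] == pytest.approx(0.3)
        assert means.loc[2, "p"] == pytest.approx(0.7)

    def test_dimensions_clusters_by_probes(self, default_cohort):
        m = default_cohort.methylation.iloc[:50]
        means = cluster_mean_matrix(m, default_cohort.true_labels)
        assert means.shape == (7, 50)


class TestEntropy:
    def test_uniform_means_give_log2_k(self):
        h_raw, _ = methylation_entropy([1 / 7] * 7)
        assert h_raw == pytest.approx(np.log2(7), abs=1e-12)

    def test_one_hot_gives_zero(self):
        h_raw, _ = methylation_entropy([1.0, 0.0, 0.0])
        assert h_raw == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        h_raw, _ = methylation_entropy([0.8, 0.1, 0.1])
        assert h_raw == pytest.approx(0.9219280948873623, abs=1e-12)

    def test_reflected_is_entropy_of_complement(self):
        means = [0.2, 0.7, 0.7]
        _, h_ref = methylation_entropy(means)
        assert h_ref == pytest.approx(entropy_oracle(1 - np.asarray(means)),
                                      abs=1e-12)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            means = rng.uniform(0, 1, size=rng.integers(2, 9))
            h_raw, h_ref = methylation_entropy(means)
            assert abs(h_raw - entropy_oracle(means)) < 1e-12
            assert abs(h_ref - entropy_oracle(1 - means)) < 1e-12

    @given(hnp.arrays(float, st.integers(2, 8),
                      elements=st.floats(0, 1)))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bounds_and_permutation_invariance(self, means):
        K = len(means)
        h_raw, h_ref = methylation_entropy(means)
        assert -1e-12 <= h_raw <= np.log2(K) + 1e-12
        assert -1e-12 <= h_ref <= np.log2(K) + 1e-12
        perm = np.random.default_rng(0).permutation(means)
        h_perm, _ = methylation_entropy(perm)
        assert h_perm == pytest.approx(h_raw, abs=1e-12)


class TestNullThreshold:
    def test_vanishing_noise_concentrates_at_log2_k(self):
        means = pd.DataFrame(np.full((5, 30), 0.5),
                             index=range(1, 6))
        thr = null_entropy_threshold(means, sd=1e-4, n_null=2000, seed=0)
        assert np.log2(5) - 0.01 < thr < np.log2(5)

    def test_matches_independent_reimplementation(self, default_cohort):
        means = cluster_mean_matrix(default_cohort.methylation.iloc[:200],
                                    default_cohort.true_labels)
        thr = null_entropy_threshold(means, sd=0.04, n_null=10000, q=0.001,
                                     seed=3)
        # independent re-implementation of the same null sampler
        rng = np.random.default_rng(3)
        grand = means.mean(axis=0).to_numpy()
        base = rng.choice(grand, size=10000, replace=True)
        nulls = np.clip(base[:, None]
                        + rng.normal(0, 0.04, size=(10000, means.shape[0])),
                        0.01, 0.99)
        scores = [min(entropy_oracle(v), entropy_oracle(1 - v))
                  for v in nulls]
        assert thr == pytest.approx(np.quantile(scores, 0.001), abs=1e-10)

    def test_small_n_null_rejected(self):
        means = pd.DataFrame(np.full((3, 10), 0.5))
        with pytest.raises(ValueError):
            null_entropy_threshold(means, n_null=100)


class TestCallSpecific:
    @pytest.fixture()
    def means(self):
        return pd.DataFrame(
            {
                "flat": [0.5, 0.5, 0.5],
                "hyper_in_2": [0.2, 0.8, 0.2],
                "hypo_in_3": [0.7, 0.7, 0.1],
            },
            index=pd.Index([1, 2, 3], name="cluster"),
        )

    def test_planted_directions_and_clusters(self, means):
        calls = call_specific(means, threshold=1.4)
        assert "flat" not in calls.index
        assert calls.loc["hyper_in_2", "direction"] == "hyper"
        assert calls.loc["hyper_in_2", "cluster"] == 2
        assert calls.loc["hypo_in_3", "direction"] == "hypo"
        assert calls.loc["hypo_in_3", "cluster"] == 3

    def test_direction_invariant_to_cluster_permutation(self, means):
        perm = means.reindex([3, 1, 2])
        calls = call_specific(perm, threshold=1.4)
        assert calls.loc["hyper_in_2", "cluster"] == 2
        assert calls.loc["hypo_in_3", "cluster"] == 3

    def test_nonpositive_threshold_rejected(self, means):
        with pytest.raises(ValueError):
            call_specific(means, threshold=0.0)


class TestAnnotateGenes:
    @pytest.fixture()
    def manifest(self):
        return pd.DataFrame(
            {
                "chromosome": ["1", "2", "3"],
                "position": [100, 200, 300],
                "genes": ["A;B", "B;C", ""],
                "feature": ["TSS200", "Body", "Body"],
                "cross_reactive": [False] * 3,
                "snp_overlap": [False] * 3,
            },
            index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        )

    def test_empty_calls_empty_genes(self, manifest):
        calls = pd.DataFrame(index=pd.Index([], name="probe"))
        ann = annotate_genes(calls, manifest)
        assert ann.genes == [] and ann.promoter_genes == []

    def test_union_may_outnumber_probes(self, manifest):
        calls = pd.DataFrame(index=pd.Index(["p1", "p2"], name="probe"))
        ann = annotate_genes(calls, manifest)
        assert ann.genes == ["A", "B", "C"]
        assert ann.promoter_genes == ["A", "B"]  # only p1 is promoter-class

    def test_unannotated_probe_counted(self, manifest):
        calls = pd.DataFrame(index=pd.Index(["p3"], name="probe"))
        ann = annotate_genes(calls, manifest)
        assert ann.genes == []
        assert ann.n_probes_without_genes == 1


class TestPlantedRecovery:
    def test_sensitivity_and_direction_on_planted_cohort(self,
                                                         default_cohort):
        calls, thr, _ = find_specific_cpgs(default_cohort.methylation,
                                           default_cohort.true_labels,
                                           seed=2)
        truth = {p: (c, d) for c, lst in default_cohort.true_specific.items()
                 for p, d in lst}
        called = set(calls.index)
        tp = called & set(truth)
        sens = len(tp) / len(truth)
        assert sens >= 0.95
        correct = sum(calls.loc[p, "direction"] == truth[p][1]
                      and calls.loc[p, "cluster"] == truth[p][0]
                      for p in tp)
        assert correct == len(tp)
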