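"""Episodic sampling invariants and phenotype-adjacency laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metagcn import (
    TaskSamplingConfig,
    build_adjacency,
    build_task,
    pairwise_feature_indicator,
    sample_test_tasks,
    sample_train_tasks,
)
from metagcn.tasks import feature_ranges


def _labels(rng, C, sizes):
    return np.repeat(np.arange(C), sizes)[rng.permutation(sum(sizes))]


class TestTrainSampling:
    def test_exact_label_balance_over_many_tasks(self, rng):
        labels = _labels(rng, 3, (10, 25, 60))
        cfg = TaskSamplingConfig(C=3, k_train_s=3, k_train_q=5, M=1000, seed=1)
        for sup, qry in sample_train_tasks(labels, cfg):
            assert sup.size == 9 and qry.size == 15  # C*k each
            assert np.array_equal(np.bincount(labels[sup]), [3, 3, 3])
            assert np.array_equal(np.bincount(labels[qry]), [5, 5, 5])
            assert np.unique(np.concatenate([sup, qry])).size == 24

    def test_best_published_task_size(self, rng):
        labels = _labels(rng, 3, (12, 12, 12))
        cfg = TaskSamplingConfig(C=3, k_train_s=3, k_train_q=5, M=5, seed=0)
        sup, qry = sample_train_tasks(labels, cfg)[0]
        assert sup.size + qry.size == 24  # 3 * (3 + 5)

    def test_tiny_class_resamples_with_warning(self, caplog):
        labels = np.array([0, 1, 1, 1, 1])
        cfg = TaskSamplingConfig(C=2, k_train_s=2, k_train_q=1, M=3, seed=0)
        with caplog.at_level("WARNING"):
            tasks = sample_train_tasks(labels, cfg)
        assert any("replacement" in r.message for r in caplog.records)
        for sup, qry in tasks:
            assert np.array_equal(np.bincount(labels[sup], minlength=2), [2, 2])

    def test_missing_class_fails_by_name(self):
        with pytest.raises(ValueError, match="class 2"):
            sample_train_tasks(np.array([0, 1, 0, 1]), TaskSamplingConfig(C=3, M=1))


class TestTestSampling:
    def test_partition_counts_example(self, rng):
        train_labels = _labels(rng, 3, (20, 20, 20))
        test_ids = np.arange(100, 173)  # |Dtest| = 73
        cfg = TaskSamplingConfig(C=3, t=10, M=1, seed=5)
        tasks = sample_test_tasks(train_labels, test_ids, cfg)
        assert len(tasks) == 8
        assert tasks[-1][1].size == 3

    def test_single_subject_queries(self, rng):
        train_labels = _labels(rng, 2, (5, 5))
        test_ids = np.arange(50, 57)
        cfg = TaskSamplingConfig(C=2, t=1, M=1, seed=5)
        tasks = sample_test_tasks(train_labels, test_ids, cfg)
        assert len(tasks) == 7
        assert all(q.size == 1 for _, q in tasks)

    def test_queries_partition_test_set_randomized(self, rng):
        for trial in range(100):
            C = int(rng.integers(2, 5))
            sizes = rng.integers(3, 9, size=C)
            train_labels = _labels(rng, C, tuple(sizes))
            n_test = int(rng.integers(1, 40))
            test_ids = rng.choice(1000, size=n_test, replace=False) + 500
            t = int(rng.integers(1, 12))
            cfg = TaskSamplingConfig(C=C, t=t, k_test_s=2, M=1, seed=trial)
            tasks = sample_test_tasks(train_labels, test_ids, cfg)
            assert len(tasks) == int(np.ceil(n_test / t))
            qs = [q for _, q in tasks]
            allq = np.concatenate(qs)
            assert allq.size == n_test  # pairwise disjoint ...
            assert set(allq.tolist()) == set(test_ids.tolist())  # ... and exhaustive
            for sup, _ in tasks:
                assert sup.size == C * 2


class TestIndicator:
    def test_hand_arithmetic(self):
        assert pairwise_feature_indicator(60.0, 70.0, 40.0, 0.8) == 0  # 0.75 < 0.8
        assert pairwise_feature_indicator(60.0, 70.0, 40.0, 0.75) == 1
        assert pairwise_feature_indicator(5.0, 5.0, 10.0, 1.0) == 1  # zero distance
        assert pairwise_feature_indicator(0.0, 10.0, 10.0, 0.5) == 0  # maximal distance
        assert pairwise_feature_indicator(3.0, 7.0, 0.0, 0.9) == 1  # constant feature


def _random_phenotypes(rng, n):
    return np.column_stack(
        [
            rng.uniform(55, 90, n),
            rng.integers(0, 2, n).astype(float),
            rng.integers(0, 3, n).astype(float),
        ]
    )


class TestAdjacency:
    def test_identical_subjects_get_edge(self):
        ph = np.array([[70.0, 1, 2], [70.0, 1, 2]])
        A = build_adjacency(ph, 1.0, 1.0, np.array([30.0, 1.0, 2.0]))
        assert A[0, 1] == 1 and A[1, 0] == 1

    def test_two_of_three_rule(self):
        # indicators (1, 1, 0): same age and sex, different apoe4
        ph = np.array([[70.0, 1, 0], [70.0, 1, 2]])
        ranges = np.array([30.0, 1.0, 2.0])
        assert build_adjacency(ph, 0.9, 0.5, ranges)[0, 1] == 1  # 2/3 >= 0.5
        assert build_adjacency(ph, 0.9, 0.7, ranges)[0, 1] == 0  # 2/3 < 0.7

    def test_mean_and_sum_rules_agree(self, rng):
        ph = _random_phenotypes(rng, 30)
        ranges = feature_ranges(ph)
        for b2 in (0.0, 1 / 3, 0.5, 2 / 3, 1.0):
            a = build_adjacency(ph, 0.85, b2, ranges, rule="mean_ge")
            b = build_adjacency(ph, 0.85, b2, ranges, rule="sum_ge")
            assert np.array_equal(a, b)

    def test_structural_laws(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 25))
            ph = _random_phenotypes(rng, n)
            ranges = feature_ranges(ph)
            b1, b2 = rng.uniform(0, 1.2), rng.uniform(0, 1)
            A = build_adjacency(ph, b1, b2, ranges)
            assert np.array_equal(A, A.T)
            assert np.all(np.diag(A) == 0)
            assert set(np.unique(A)) <= {0.0, 1.0}

    def test_threshold_extremes(self, rng):
        ph = _random_phenotypes(rng, 20)
        ranges = feature_ranges(ph)
        # beta2 = 0: complete graph minus diagonal
        A = build_adjacency(ph, 0.9, 0.0, ranges)
        assert np.array_equal(A, 1 - np.eye(20))
        # beta1 > 1: no indicator fires (non-constant features), so empty graph
        assert not build_adjacency(ph, 1.01, 0.5, ranges).any()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        b1a=st.floats(0, 1.05),
        b1b=st.floats(0, 1.05),
        b2a=st.floats(0, 1),
        b2b=st.floats(0, 1),
    )
    def test_monotone_shrinkage_in_thresholds(self, seed, b1a, b1b, b2a, b2b):
        rng = np.random.default_rng(seed)
        ph = _random_phenotypes(rng, 12)
        ranges = feature_ranges(ph)
        lo = build_adjacency(ph, min(b1a, b1b), min(b2a, b2b), ranges)
        hi = build_adjacency(ph, max(b1a, b1b), max(b2a, b2b), ranges)
        assert np.all(hi <= lo)  # raising thresholds never adds edges

    def test_missing_feature_fails(self):
        ph = np.array([[70.0, 1, np.nan], [70.0, 1, 2]])
        with pytest.raises(ValueError, match="missing"):
            build_adjacency(ph, 0.9, 0.5, np.array([30.0, 1.0, 2.0]))


class TestBuildTask:
    def test_node_order_masks_and_hidden_labels(self, rng):
        n = 30
        X = rng.normal(size=(n, 4))
        y = rng.integers(0, 3, n)
        ph = _random_phenotypes(rng, n)
        sup = np.array([7, 3, 11])
        qry = np.array([20, 14])
        task = build_task(sup, qry, X, y, ph, 0.9, 0.5, feature_ranges(ph),
                          query_labels_known=False)
        assert task.node_ids.tolist() == [3, 7, 11, 14, 20]
        assert task.support_mask.tolist() == [True] * 3 + [False] * 2
        assert np.all(task.labels[task.query_mask] == -1)
        assert np.all(task.labels[task.support_mask] == y[[3, 7, 11]])
        assert np.array_equal(task.X, X[task.node_ids])
        assert not (task.support_mask & task.query_mask).any()
        assert (task.support_mask | task.query_mask).all()
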