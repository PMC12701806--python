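"""GCN forward/loss/gradient correctness and MAML loop behaviour."""

import numpy as np
import pytest

from metagcn import (
    MetaConfig,
    gcn_forward,
    inner_update,
    masked_ce_loss,
    meta_test,
    meta_train,
    meta_update,
    normalize_adjacency,
)
from metagcn.gcn import init_gcn_params, loss_and_grad, meta_gradient, softmax
from metagcn.tasks import MetaTask


def _random_adj(rng, n):
    A = (rng.random((n, n)) < 0.4).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    return A


def _random_task(rng, n=6, d=5, C=3, n_support=4, labeled_query=True):
    A = _random_adj(rng, n)
    labels = rng.integers(0, C, n)
    labels[:C] = np.arange(C)  # every class present in the support block
    support = np.zeros(n, dtype=bool)
    support[:n_support] = True
    if not labeled_query:
        labels = labels.copy()
        labels[~support] = -1
    return MetaTask(
        node_ids=np.arange(n),
        support_mask=support,
        query_mask=~support,
        labels=labels,
        A=A,
        X=rng.normal(size=(n, d)),
    )


class TestNormalizeAdjacency:
    def test_zero_adjacency_gives_identity(self):
        assert np.allclose(normalize_adjacency(np.zeros((4, 4))), np.eye(4))

    def test_two_node_path_hand_value(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(normalize_adjacency(A), 0.5 * np.ones((2, 2)))

    def test_matches_dense_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            A = _random_adj(rng, n)
            At = A + np.eye(n)
            D = np.diag(At.sum(axis=1))
            Dm = np.linalg.inv(np.sqrt(D))
            assert np.max(np.abs(normalize_adjacency(A) - Dm @ At @ Dm)) < 1e-10

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestForward:
    def test_identity_network_passes_features_through(self, rng):
        X = np.abs(rng.normal(size=(4, 4)))  # nonnegative so ReLU is identity
        theta = [np.eye(4), np.eye(4)]
        logits = gcn_forward(X, np.eye(4), theta)
        assert np.allclose(logits, X)

    def test_isolated_node_depends_only_on_itself(self, rng):
        n, d, h, C = 5, 4, 3, 2
        A = _random_adj(rng, n)
        A[0, :] = A[:, 0] = 0.0  # isolate node 0
        theta = init_gcn_params(d, h, C, rng)
        X = rng.normal(size=(n, d))
        base = gcn_forward(X, normalize_adjacency(A), theta)[0]
        X2 = X.copy()
        X2[1:] = rng.normal(size=(n - 1, d))  # perturb everyone else
        again = gcn_forward(X2, normalize_adjacency(A), theta)[0]
        assert np.allclose(base, again)

    def test_matches_dense_oracle(self, rng):
        for _ in range(30):
            n, d, h, C = 6, 5, 4, 3
            A_hat = normalize_adjacency(_random_adj(rng, n))
            theta = init_gcn_params(d, h, C, rng)
            X = rng.normal(size=(n, d))
            H1 = np.maximum(A_hat @ X @ theta[0], 0.0)
            oracle = A_hat @ H1 @ theta[1]
            assert np.max(np.abs(gcn_forward(X, A_hat, theta) - oracle)) < 1e-10

    def test_dropout_only_in_training(self, rng):
        n, d = 5, 4
        A_hat = normalize_adjacency(_random_adj(rng, n))
        theta = init_gcn_params(d, 3, 2, rng)
        X = rng.normal(size=(n, d))
        a = gcn_forward(X, A_hat, theta, dropout=0.5, training=False)
        b = gcn_forward(X, A_hat, theta, dropout=0.5, training=False)
        assert np.array_equal(a, b)
        c = gcn_forward(X, A_hat, theta, dropout=0.5, training=True,
                        rng=np.random.default_rng(0))
        assert not np.allclose(a, c)


class TestMaskedCE:
    def test_uniform_logits_give_log_C(self):
        logits = np.zeros((4, 3))
        labels = np.array([0, 1, 2, 0])
        loss = masked_ce_loss(logits, labels, np.ones(4, dtype=bool))
        assert abs(loss - np.log(3)) < 1e-12

    def test_confident_correct_logits_vanish(self):
        logits = np.full((3, 2), -50.0)
        labels = np.array([0, 1, 0])
        logits[np.arange(3), labels] = 50.0
        assert masked_ce_loss(logits, labels, np.ones(3, dtype=bool)) < 1e-12

    def test_matches_handrolled_softmax_oracle(self, rng):
        for _ in range(30):
            n, C = 7, 4
            logits = rng.normal(size=(n, C)) * 3
            labels = rng.integers(0, C, n)
            mask = rng.random(n) < 0.6
            if not mask.any():
                mask[0] = True
            probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
            oracle = -np.mean(np.log(probs[mask, labels[mask]]))
            assert abs(masked_ce_loss(logits, labels, mask) - oracle) < 1e-6

    def test_empty_mask_fails(self):
        with pytest.raises(ValueError, match="no nodes"):
            masked_ce_loss(np.zeros((2, 2)), np.zeros(2, int), np.zeros(2, bool))


class TestInnerUpdate:
    def test_gradient_matches_finite_differences(self, rng):
        task = _random_task(rng, n=6, d=5, C=3)
        cfg = MetaConfig(alpha1=0.01, dropout=0.0)
        A_hat = normalize_adjacency(task.A)
        theta = init_gcn_params(5, 4, 3, rng)
        _, g, _ = loss_and_grad(theta, task.X, A_hat, task.labels, task.support_mask)
        eps = 1e-6
        for li in range(2):
            it = np.nditer(theta[li], flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                tp = [t.copy() for t in theta]
                tm = [t.copy() for t in theta]
                tp[li][ix] += eps
                tm[li][ix] -= eps
                lp, _, _ = loss_and_grad(tp, task.X, A_hat, task.labels, task.support_mask)
                lm, _, _ = loss_and_grad(tm, task.X, A_hat, task.labels, task.support_mask)
                fd = (lp - lm) / (2 * eps)
                rel = abs(g[li][ix] - fd) / (abs(fd) + 1e-8)
                assert rel < 1e-4, f"layer {li} {ix}: analytic {g[li][ix]} vs FD {fd}"

    def test_update_moves_downhill_and_is_pure(self, rng):
        task = _random_task(rng)
        cfg = MetaConfig(dropout=0.0)
        theta = init_gcn_params(5, 4, 3, rng)
        before = [t.copy() for t in theta]
        A_hat = normalize_adjacency(task.A)
        l0, _, _ = loss_and_grad(theta, task.X, A_hat, task.labels, task.support_mask)
        adapted = inner_update(theta, task, cfg)
        l1, _, _ = loss_and_grad(adapted, task.X, A_hat, task.labels, task.support_mask)
        assert l1 < l0
        assert all(np.array_equal(a, b) for a, b in zip(theta, before))  # purity

    def test_stationary_point_is_fixed(self, rng):
        # Confident, correct logits => gradient ~ 0 => theta' ~ theta.
        n, C = 3, 3
        task = MetaTask(
            node_ids=np.arange(n),
            support_mask=np.ones(n, dtype=bool),
            query_mask=np.zeros(n, dtype=bool),
            labels=np.arange(C),
            A=np.zeros((n, n)),
            X=np.eye(C) * 50.0,
        )
        theta = [np.eye(C), np.eye(C)]  # identity net on one-hot features
        adapted = inner_update(theta, task, MetaConfig(dropout=0.0))
        assert all(np.max(np.abs(a - t)) < 1e-10 for a, t in zip(adapted, theta))


class TestMetaUpdate:
    def test_progress_on_fixed_easy_batch(self, rng):
        # Four linearly separable tasks; 50 meta-SGD steps cut query loss >= 30%.
        tasks = []
        for _ in range(4):
            t = _random_task(rng, n=9, d=4, C=3, n_support=6)
            centers = np.eye(3)[t.labels] * 2.0
            t.X = np.hstack([centers, np.zeros((9, 1))]) + 0.1 * rng.normal(size=(9, 4))
            tasks.append(t)
        cfg = MetaConfig(alpha2=0.05, dropout=0.0, second_order=True)
        theta = init_gcn_params(4, 4, 3, rng)
        _, stats0 = meta_gradient(theta, tasks, cfg)
        for _ in range(50):
            theta, stats = meta_update(theta, tasks, cfg)
        assert stats["query_loss"] <= 0.7 * stats0["query_loss"]

    def test_second_and_first_order_directions_differ(self, rng):
        task = _random_task(rng, n=8, d=5, C=3, n_support=5)
        theta = init_gcn_params(5, 4, 3, rng)
        g2, _ = meta_gradient(theta, [task], MetaConfig(dropout=0.0, second_order=True))
        g1, _ = meta_gradient(theta, [task], MetaConfig(dropout=0.0, second_order=False))
        assert any(not np.allclose(a, b) for a, b in zip(g2, g1))

    def test_second_order_matches_finite_difference_meta_gradient(self, rng):
        # d L_q(theta - a1 grad L_s(theta)) / d theta via central differences.
        task = _random_task(rng, n=6, d=4, C=2, n_support=4)
        cfg = MetaConfig(alpha1=0.05, dropout=0.0, second_order=True)
        theta = init_gcn_params(4, 3, 2, rng)
        A_hat = normalize_adjacency(task.A)

        def query_loss_after_adaptation(th):
            ad = inner_update(th, task, cfg, A_hat=A_hat)
            l, _, _ = loss_and_grad(ad, task.X, A_hat, task.labels, task.query_mask)
            return l

        g, _ = meta_gradient(theta, [task], cfg)
        eps = 1e-6
        rng2 = np.random.default_rng(1)
        for li in range(2):
            for _ in range(5):  # spot-check random coordinates
                ix = tuple(rng2.integers(0, s) for s in theta[li].shape)
                tp = [t.copy() for t in theta]
                tm = [t.copy() for t in theta]
                tp[li][ix] += eps
                tm[li][ix] -= eps
                fd = (query_loss_after_adaptation(tp) - query_loss_after_adaptation(tm)) / (2 * eps)
                assert abs(g[li][ix] - fd) / (abs(fd) + 1e-8) < 1e-4

    def test_empty_batch_rejected(self, rng):
        theta = init_gcn_params(4, 3, 2, rng)
        with pytest.raises(ValueError, match="empty"):
            meta_update(theta, [], MetaConfig())


class TestMetaTrainTest:
    def _pool(self, rng, m=20):
        return [_random_task(rng, n=10, d=4, C=3, n_support=6) for _ in range(m)]

    def test_meta_train_bit_deterministic(self, rng):
        pool = self._pool(rng)
        cfg = MetaConfig(iterations=20, seed=11)
        th1, log1 = meta_train(pool, cfg, 3)
        th2, log2 = meta_train(pool, cfg, 3)
        assert all(np.array_equal(a, b) for a, b in zip(th1, th2))
        assert log1 == log2

    def test_meta_test_predicts_each_query_once_and_is_pure(self, rng):
        pool = self._pool(rng, m=6)
        cfg = MetaConfig(iterations=5, seed=0)
        theta, _ = meta_train(pool, cfg, 3)
        before = [t.copy() for t in theta]
        test_tasks = [_random_task(rng, n=8, d=4, C=3, n_support=5, labeled_query=False)
                      for _ in range(3)]
        for i, t in enumerate(test_tasks):
            t.node_ids = np.arange(i * 8, (i + 1) * 8)
        preds = meta_test(theta, test_tasks, cfg)
        expected_queries = {int(i) for t in test_tasks for i in t.node_ids[t.query_mask]}
        assert set(preds) == expected_queries
        assert all(np.array_equal(a, b) for a, b in zip(theta, before))
        for label, scores in preds.values():
            assert 0 <= label < 3
            assert abs(scores.sum() - 1) < 1e-9

    def test_finetuning_changes_predictions(self, rng):
        pool = self._pool(rng, m=6)
        theta, _ = meta_train(pool, MetaConfig(iterations=5, seed=0), 3)
        task = _random_task(rng, n=8, d=4, C=3, n_support=5, labeled_query=False)
        p0 = meta_test(theta, [task], MetaConfig(finetune_steps=0))
        p5 = meta_test(theta, [task], MetaConfig(finetune_steps=25))
        s0 = np.stack([p0[k][1] for k in sorted(p0)])
        s5 = np.stack([p5[k][1] for k in sorted(p5)])
        assert not np.allclose(s0, s5)
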