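"""Contrastive loss, EMA update, FIFO queue and the training loop contract."""

import numpy as np
import pytest

from pawmoco import (EncoderConfig, MoCoQueue, MoCoTrainConfig, contrastive_loss,
                     ema_update, enqueue_dequeue, nn, train_moco)
from pawmoco.moco import cosine_lr


def _random_unit(rng, shape):
    v = rng.normal(size=shape)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


class TestContrastiveLoss:
    def test_positive_only_is_zero(self):
        q = np.array([[0.6, 0.8]])
        assert contrastive_loss(q, q, np.zeros((0, 2)), 1.0) == pytest.approx(0.0,
                                                                              abs=1e-9)

    def test_orthogonal_negative_hand_value_tau_1(self):
        q = np.array([[1.0, 0.0]])
        loss = contrastive_loss(q, q, np.array([[0.0, 1.0]]), 1.0)
        assert loss == pytest.approx(np.log(1 + np.exp(-1.0)), abs=1e-6)

    def test_orthogonal_negative_hand_value_tau_01(self):
        q = np.array([[1.0, 0.0]])
        loss = contrastive_loss(q, q, np.array([[0.0, 1.0]]), 0.1)
        assert loss == pytest.approx(np.log(1 + np.exp(-10.0)), abs=1e-6)

    def test_equals_independent_cross_entropy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            b = int(rng.integers(1, 5))
            k = int(rng.integers(0, 33))
            d = int(rng.integers(2, 9))
            tau = float(rng.uniform(0.05, 2.0))
            q = _random_unit(rng, (b, d))
            kp = _random_unit(rng, (b, d))
            queue = _random_unit(rng, (k, d)) if k else np.zeros((0, d))
            # oracle: explicit (1+K)-way log-softmax with target 0
            logits = np.concatenate(
                [np.sum(q * kp, axis=1, keepdims=True),
                 q @ queue.T if k else np.zeros((b, 0))], axis=1) / tau
            expected = np.mean([
                -(row[0] - np.log(np.exp(row - row.max()).sum()) - row.max())
                for row in logits])
            assert contrastive_loss(q, kp, queue, tau) == pytest.approx(
                expected, abs=1e-6)

    def test_loss_nonincreasing_as_temperature_drops_when_positive_dominates(self):
        rng = np.random.default_rng(1)
        q = _random_unit(rng, (1, 4))
        kp = q.copy()                                   # q . k+ = 1 > negatives
        queue = _random_unit(rng, (8, 4)) * 0.9
        losses = [contrastive_loss(q, kp, queue, t) for t in (1.0, 0.5, 0.2, 0.1)]
        assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_gradient_matches_numeric(self):
        rng = np.random.default_rng(2)
        q = _random_unit(rng, (3, 5))
        kp = _random_unit(rng, (3, 5))
        queue = _random_unit(rng, (6, 5))
        _, dq = contrastive_loss(q, kp, queue, 0.3, return_grad=True)
        eps = 1e-6
        for i in range(5):
            qp, qm = q.copy(), q.copy()
            qp[0, i] += eps
            qm[0, i] -= eps
            num = (contrastive_loss(qp, kp, queue, 0.3)
                   - contrastive_loss(qm, kp, queue, 0.3)) / (2 * eps)
            assert dq[0, i] == pytest.approx(num, abs=1e-4)

    def test_invalid_inputs(self):
        q = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError):
            contrastive_loss(q, q, np.zeros((0, 2)), 0.0)
        with pytest.raises(ValueError):
            contrastive_loss(q, np.array([[1.0, 0.0, 0.0]]), np.zeros((0, 2)), 1.0)


class TestEmaUpdate:
    def _pair(self):
        rng = np.random.default_rng(3)
        a = nn.Linear(4, 3, rng=rng)
        b = nn.Linear(4, 3, rng=rng)
        return a, b

    def test_m_equal_1_is_identity(self):
        q, k = self._pair()
        before = {n: p.data.copy() for n, p in k.named_parameters()}
        ema_update(q, k, 1.0)
        for n, p in k.named_parameters():
            assert np.array_equal(p.data, before[n])

    def test_m_equal_0_is_exact_copy(self):
        q, k = self._pair()
        ema_update(q, k, 0.0)
        for (_, pq), (_, pk) in zip(q.named_parameters(), k.named_parameters()):
            assert np.array_equal(pk.data, pq.data)

    def test_scalar_formula(self):
        q, k = self._pair()
        for _, p in q.named_parameters():
            p.data[...] = 1.0
        for _, p in k.named_parameters():
            p.data[...] = 0.0
        ema_update(q, k, 0.99)
        for _, p in k.named_parameters():
            assert np.allclose(p.data, 0.01, atol=1e-7)

    def test_frozen_key_stays_identical_through_a_training_loop(self):
        """With m = 1 the key encoder never moves, whatever SGD does to q."""
        rng = np.random.default_rng(4)
        q = nn.Linear(4, 3, rng=rng)
        import copy
        k = copy.deepcopy(q)
        before = {n: p.data.copy() for n, p in k.named_parameters()}
        opt = nn.SGD(q.parameters(), 0.1)
        for _ in range(5):
            x = rng.normal(size=(2, 4)).astype(np.float32)
            out = q.forward(x)
            opt.zero_grad()
            q.backward(np.ones_like(out))
            opt.step()
            ema_update(q, k, 1.0)
        for n, p in k.named_parameters():
            assert np.array_equal(p.data, before[n])

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            ema_update(nn.Linear(4, 3, rng=rng), nn.Linear(4, 2, rng=rng), 0.5)


class TestQueue:
    def test_wrap_arithmetic(self):
        queue = MoCoQueue(4, 3, np.random.default_rng(0))
        queue.ptr = 2
        old = queue.features.copy()
        keys = _random_unit(np.random.default_rng(1), (2, 3)).astype(np.float32)
        enqueue_dequeue(queue, keys)
        assert np.allclose(queue.features[2:], keys)
        assert np.array_equal(queue.features[:2], old[:2])
        assert queue.ptr == 0

    def test_every_row_replaced_exactly_once_per_cycle(self):
        """Simulation oracle: track per-row ages through a full queue cycle."""
        queue = MoCoQueue(12, 2, np.random.default_rng(2))
        rng = np.random.default_rng(3)
        age = np.full(12, -1)
        step = 0
        for _ in range(4):                     # 4 batches of 3 fill it once
            ptr = queue.ptr
            queue.enqueue(_random_unit(rng, (3, 2)).astype(np.float32))
            age[ptr:ptr + 3] = step
            step += 1
        assert (age >= 0).all()
        assert sorted(age) == [0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_size_conserved_and_unit_norm_preserved(self):
        queue = MoCoQueue(8, 4, np.random.default_rng(4))
        rng = np.random.default_rng(5)
        for _ in range(5):
            queue.enqueue(_random_unit(rng, (3, 4)).astype(np.float32))
            assert queue.features.shape == (8, 4)
            assert np.allclose(np.linalg.norm(queue.features, axis=1), 1.0,
                               atol=1e-5)

    def test_batch_larger_than_queue_rejected(self):
        queue = MoCoQueue(4, 2, np.random.default_rng(6))
        with pytest.raises(ValueError):
            queue.enqueue(np.zeros((5, 2), np.float32))


@pytest.fixture(scope="module")
def tiny_run(tiny_dataset):
    enc_cfg = EncoderConfig(arch="resnet18", width=4, num_bn_splits=2, seed=0)
    cfg = MoCoTrainConfig(batch_size=8, epochs=2, queue_size=16, knn_k=10,
                          image_resolution=32, seed=0)
    return train_moco(tiny_dataset, enc_cfg, cfg), (enc_cfg, cfg)


class TestTrainingLoop:
    def test_history_covers_every_epoch(self, tiny_run):
        (_, history), (_, cfg) = tiny_run
        assert len(history) == cfg.epochs
        assert list(history.columns) == ["epoch", "train_loss", "knn_accuracy_pct"]
        assert history["train_loss"].notna().all()
        assert history["knn_accuracy_pct"].notna().all()

    def test_training_is_deterministic_under_fixed_seed(self, tiny_run,
                                                        tiny_dataset):
        (_, history), (enc_cfg, cfg) = tiny_run
        _, again = train_moco(tiny_dataset, enc_cfg, cfg)
        assert np.array_equal(history["train_loss"].values,
                              again["train_loss"].values)
        assert np.array_equal(history["knn_accuracy_pct"].values,
                              again["knn_accuracy_pct"].values)

    def test_inbatch_loss_variant_runs(self, tiny_dataset):
        enc_cfg = EncoderConfig(arch="resnet18", width=4, num_bn_splits=2, seed=0)
        cfg = MoCoTrainConfig(batch_size=8, epochs=1, queue_size=16, knn_k=5,
                              image_resolution=32, seed=0, loss="inbatch")
        _, history = train_moco(tiny_dataset, enc_cfg, cfg, monitor=False)
        assert np.isfinite(history["train_loss"]).all()

    def test_batch_split_divisibility_enforced(self, tiny_dataset):
        enc_cfg = EncoderConfig(arch="resnet18", width=4, num_bn_splits=8)
        cfg = MoCoTrainConfig(batch_size=12, epochs=1, queue_size=16,
                              image_resolution=32)
        with pytest.raises(ValueError, match="divisible"):
            train_moco(tiny_dataset, enc_cfg, cfg)

    def test_cosine_schedule_endpoints(self):
        assert cosine_lr(0.3, 0, 100) == pytest.approx(0.3)
        assert cosine_lr(0.3, 50, 100) == pytest.approx(0.15)
        assert cosine_lr(0.3, 100, 100) == pytest.approx(0.0, abs=1e-12)


class TestMoCoEmbeddingEstimator:
    def test_fit_transform_interface(self, tiny_dataset):
        from pawmoco import MoCoEmbedding
        est = MoCoEmbedding(width=4, num_bn_splits=2, batch_size=8, epochs=1,
                            queue_size=16, knn_k=5, image_resolution=32,
                            feature_dim=16, random_state=0)
        assert est.get_params()["epochs"] == 1
        X = tiny_dataset.images
        est.fit(X, tiny_dataset.labels)
        feats = est.transform(X[:6])
        assert feats.shape == (6, 16)
        assert np.allclose(np.linalg.norm(feats, axis=1), 1.0, atol=1e-5)
        assert len(est.history_) == 1
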