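"""Age-order contrastive losses against hand-arithmetic and brute-force oracles."""

import numpy as np
import pytest

from omiclock.autodiff import Adam, Tensor
from omiclock.contrast import (
    ContrastBatch,
    ProxySet,
    direction_loss,
    init_proxies,
    negative_weights,
    order_loss,
    proxy_contrastive_loss,
    proxy_similarity,
)
from omiclock.errors import DegenerateInputError, ValidationError

TAU = 0.9


class TestProxySimilarity:
    def test_parallel_vectors(self):
        z = np.array([1.0, 0.0])
        assert proxy_similarity(z, 2.5 * z, TAU) == pytest.approx(np.exp(1 / TAU))
        assert proxy_similarity(z, 2.5 * z, TAU) == pytest.approx(3.0377, abs=1e-4)

    def test_orthogonal_vectors(self):
        assert proxy_similarity([1.0, 0.0], [0.0, 3.0], TAU) == pytest.approx(1.0)

    def test_antiparallel_vectors(self):
        assert proxy_similarity([1.0, 0.0], [-1.0, 0.0], TAU) == pytest.approx(
            0.3292, abs=1e-4
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            proxy_similarity([0.0, 0.0], [1.0, 0.0], TAU)


class TestNegativeWeights:
    def test_own_bucket_weight_is_zero(self):
        w = negative_weights(3, 10)
        assert w[3] == 0.0
        assert np.count_nonzero(w == 0.0) == 1

    def test_maximal_distance_weight(self):
        w = negative_weights(0, 10)
        assert w[9] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)))
        assert w[9] == pytest.approx(0.7311, abs=1e-4)

    def test_adjacent_bucket_weight(self):
        w = negative_weights(5, 10)
        # |5-6| / max_k |5-k| = 1/5
        assert w[6] == pytest.approx(1.0 / (1.0 + np.exp(-0.2)))

    @pytest.mark.parametrize("a_i", range(10))
    def test_negative_weights_lie_in_logistic_band(self, a_i):
        w = negative_weights(a_i, 10)
        others = np.delete(w, a_i)
        assert np.all(others > 0.5)
        assert np.all(others <= 1.0 / (1.0 + np.exp(-1.0)) + 1e-12)

    def test_single_bucket_rejected(self):
        with pytest.raises(DegenerateInputError):
            negative_weights(0, 1)


def _loss_oracle(z, labels, proxies, tau):
    """Straight re-implementation of the contrastive loss from its formula."""
    total = 0.0
    K = proxies.shape[0]
    for zi, a in zip(z, labels):
        pos = proxy_similarity(zi, proxies[a], tau)
        w = negative_weights(a, K)
        neg = sum(w[k] * proxy_similarity(zi, proxies[k], tau) for k in range(K) if k != a)
        total += -np.log(pos / (pos + neg))
    return total / len(labels)


def _direction_oracle(z, labels, proxies, tau):
    """Brute-force pairwise enumeration of the order-aware direction loss."""
    n = len(labels)
    terms = []
    for i in range(n):
        numer, denom = 0.0, 0.0
        any_masked = False
        for j in range(n):
            if j == i or labels[i] == labels[j]:
                continue
            dz = z[i] - z[j]
            if np.linalg.norm(dz) == 0:
                continue
            dp = proxies[labels[i]] - proxies[labels[j]]
            s = np.exp(
                np.dot(dz / np.linalg.norm(dz), dp / np.linalg.norm(dp)) / tau
            )
            denom += s
            if labels[i] > labels[j]:
                numer += s
                any_masked = True
        if any_masked:
            terms.append(-np.log(numer / denom))
    return float(np.mean(terms)) if terms else 0.0


class TestContrastiveLoss:
    def test_two_sample_hand_arithmetic(self):
        proxies = ProxySet(np.array([[1.0, 0.0], [0.0, 1.0]]))
        batch = ContrastBatch(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]))
        loss = proxy_contrastive_loss(batch, proxies, TAU)
        s_pos = np.exp(1 / TAU)
        w = 1.0 / (1.0 + np.exp(-1.0))
        expected = -np.log(s_pos / (s_pos + w * 1.0))  # cross-proxy cos = 0
        assert loss.item() == pytest.approx(expected, abs=1e-9)
        assert loss.item() == pytest.approx(0.2156, abs=1e-3)

    def test_matches_formula_oracle_on_random_batch(self, rng):
        K, d, n = 5, 4, 12
        proxies = rng.standard_normal((K, d))
        z = rng.standard_normal((n, d))
        labels = rng.integers(0, K, n)
        loss = proxy_contrastive_loss(ContrastBatch(z, labels), ProxySet(proxies), TAU)
        assert loss.item() == pytest.approx(_loss_oracle(z, labels, proxies, TAU), abs=1e-6)

    def test_aligning_with_own_proxy_decreases_loss(self):
        proxies = ProxySet(np.array([[1.0, 0.0], [0.0, 1.0]]))
        far = ContrastBatch(np.array([[-1.0, 0.0]]), np.array([0]))
        near = ContrastBatch(np.array([[1.0, 0.0]]), np.array([0]))
        assert (
            proxy_contrastive_loss(near, proxies, TAU).item()
            < proxy_contrastive_loss(far, proxies, TAU).item()
        )

    def test_strictly_positive_with_negatives_present(self, rng):
        proxies = ProxySet(rng.standard_normal((4, 3)))
        batch = ContrastBatch(rng.standard_normal((6, 3)), rng.integers(0, 4, 6))
        assert proxy_contrastive_loss(batch, proxies, TAU).item() > 0

    def test_empty_batch_rejected(self):
        proxies = ProxySet(np.ones((2, 2)))
        with pytest.raises(ValidationError):
            proxy_contrastive_loss(
                ContrastBatch(np.zeros((0, 2)), np.zeros(0, dtype=int)), proxies, TAU
            )

    def test_permutation_invariance(self, rng):
        K, d, n = 4, 3, 10
        proxies = ProxySet(rng.standard_normal((K, d)))
        z = rng.standard_normal((n, d))
        labels = rng.integers(0, K, n)
        perm = rng.permutation(n)
        a = proxy_contrastive_loss(ContrastBatch(z, labels), proxies, TAU).item()
        b = proxy_contrastive_loss(ContrastBatch(z[perm], labels[perm]), proxies, TAU).item()
        assert a == pytest.approx(b, rel=1e-12)


class TestDirectionLoss:
    def test_single_cross_bucket_pair_aligned_gives_zero(self):
        # embedding difference direction == proxy difference direction
        proxies = ProxySet(np.array([[0.0, 0.0], [1.0, 0.0]]))
        z = np.array([[0.2, 0.5], [1.2, 0.5]])  # z1 - z0 = (1, 0) = p1 - p0
        batch = ContrastBatch(z, np.array([0, 1]))
        assert direction_loss(batch, proxies, TAU).item() == pytest.approx(0.0, abs=1e-12)

    def test_all_labels_equal_returns_zero(self, rng):
        proxies = ProxySet(rng.standard_normal((3, 2)))
        batch = ContrastBatch(rng.standard_normal((4, 2)), np.zeros(4, dtype=int))
        assert direction_loss(batch, proxies, TAU).item() == 0.0

    def test_three_bucket_brute_force_oracle(self):
        proxies = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.5]])
        z = np.array([[0.3, -0.2], [1.0, 1.0], [-0.5, 0.8]])
        labels = np.array([0, 1, 2])
        mine = direction_loss(ContrastBatch(z, labels), ProxySet(proxies), TAU).item()
        assert mine == pytest.approx(_direction_oracle(z, labels, proxies, TAU), abs=1e-6)

    def test_matches_oracle_on_random_batches(self, rng):
        for _ in range(5):
            K, d, n = 4, 3, 8
            proxies = rng.standard_normal((K, d))
            z = rng.standard_normal((n, d))
            labels = rng.integers(0, K, n)
            mine = direction_loss(ContrastBatch(z, labels), ProxySet(proxies), TAU).item()
            assert mine == pytest.approx(
                _direction_oracle(z, labels, proxies, TAU), abs=1e-6
            )

    def test_invariant_to_positive_rescaling(self, rng):
        K, d, n = 3, 4, 7
        proxies = rng.standard_normal((K, d))
        z = rng.standard_normal((n, d))
        labels = rng.integers(0, K, n)
        a = direction_loss(ContrastBatch(z, labels), ProxySet(proxies), TAU).item()
        b = direction_loss(
            ContrastBatch(17.0 * z, labels), ProxySet(5.0 * proxies), TAU
        ).item()
        assert a == pytest.approx(b, rel=1e-8)


class TestOrderLoss:
    def test_lambda_zero_reduces_to_contrastive(self, rng):
        proxies = ProxySet(rng.standard_normal((3, 2)))
        batch = ContrastBatch(rng.standard_normal((5, 2)), rng.integers(0, 3, 5))
        assert order_loss(batch, proxies, TAU, lambda_dir=0.0).item() == pytest.approx(
            proxy_contrastive_loss(batch, proxies, TAU).item()
        )

    def test_weighted_combination_arithmetic(self, rng):
        proxies = ProxySet(rng.standard_normal((3, 2)))
        batch = ContrastBatch(rng.standard_normal((5, 2)), rng.integers(0, 3, 5))
        combined = order_loss(batch, proxies, TAU, lambda_dir=0.5).item()
        parts = (
            proxy_contrastive_loss(batch, proxies, TAU).item()
            + 0.5 * direction_loss(batch, proxies, TAU).item()
        )
        assert combined == pytest.approx(parts, rel=1e-12)

    def test_gradient_descent_decreases_loss_on_toy_batch(self):
        rng_np = np.random.default_rng(21)
        K, d, n = 5, 4, 20
        z = Tensor(rng_np.standard_normal((n, d)), requires_grad=True)
        proxies = init_proxies(K, d, seed=3)
        labels = rng_np.integers(0, K, n)
        opt = Adam([z, proxies.proxies], lr=0.05)
        initial = order_loss(ContrastBatch(z, labels), proxies, TAU).item()
        for _ in range(100):
            loss = order_loss(ContrastBatch(z, labels), proxies, TAU)
            opt.zero_grad()
            loss.backward()
            opt.step()
        final = order_loss(ContrastBatch(z, labels), proxies, TAU).item()
        assert final < initial


class TestInitProxies:
    def test_shape_seed_and_xavier_interval(self):
        a = init_proxies(10, 6, seed=4).proxies.data
        b = init_proxies(10, 6, seed=4).proxies.data
        np.testing.assert_array_equal(a, b)
        assert a.shape == (10, 6)
        limit = np.sqrt(6.0 / 16.0)
        assert np.all(np.abs(a) <= limit)
        assert init_proxies(10, 6, seed=5).proxies.data[0, 0] != a[0, 0]
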