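"""Age-order-enhanced contrastive learning on latent embeddings.

Two complementary losses shape the latent space during pre-training:

* a proxy-based contrastive loss that pulls each embedding toward a
  learnable proxy vector for its 10-year age bucket, with negative proxies
  down-weighted the closer their bucket is to the sample's own (weights are
  a logistic function of the normalized bucket distance, and the sample's
  own bucket gets weight zero);
* an order-aware direction loss that aligns the direction between two
  samples' embeddings with the direction between their buckets' proxies,
  so the latent space preserves the ordering of age, not just its grouping.

Similarities are ``exp(cos/tau)`` with temperature ``tau`` (default 0.9).
Both losses operate on embeddings and proxies through cosine geometry only
and are therefore invariant to positive rescaling of either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from omiclock.autodiff import Tensor, as_tensor
from omiclock.errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

_NORM_EPS = 1e-12


@dataclass
class ProxySet:
    """K learnable bucket-center vectors in the latent space (K x d)."""

    proxies: Tensor

    def __post_init__(self) -> None:
        if not isinstance(self.proxies, Tensor):
            self.proxies = Tensor(np.asarray(self.proxies, dtype=float), requires_grad=True)
        if self.proxies.ndim != 2:
            raise ValidationError("proxies must be a K x d matrix")
        if not np.all(np.isfinite(self.proxies.data)):
            raise ValidationError("proxies must be finite")

    @property
    def K(self) -> int:
        return self.proxies.shape[0]

    @property
    def dim(self) -> int:
        return self.proxies.shape[1]


@dataclass(frozen=True)
class ContrastBatch:
    """Embeddings (N x d) with one age-bucket label each."""

    embeddings: np.ndarray | Tensor
    bucket_labels: np.ndarray

    def __post_init__(self) -> None:
        emb = self.embeddings if isinstance(self.embeddings, Tensor) else Tensor(
            np.asarray(self.embeddings, dtype=float)
        )
        labels = np.asarray(self.bucket_labels, dtype=int)
        object.__setattr__(self, "embeddings", emb)
        object.__setattr__(self, "bucket_labels", labels)
        if emb.ndim != 2:
            raise ValidationError("embeddings must be N x d")
        if labels.shape != (emb.shape[0],):
            raise ValidationError("one bucket label required per embedding")

    @property
    def n(self) -> int:
        return self.embeddings.shape[0]


def init_proxies(K: int, d: int, seed: int = 0) -> ProxySet:
    """Xavier-uniform initialized proxies for a (K, d) matrix, seeded."""
    rng = np.random.default_rng(seed)
    limit = np.sqrt(6.0 / (K + d))
    return ProxySet(Tensor(rng.uniform(-limit, limit, size=(K, d)), requires_grad=True))


def proxy_similarity(z, p, tau: float) -> float:
    """exp(cos(z, p) / tau) between one embedding and one proxy."""
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    z = np.asarray(z.data if isinstance(z, Tensor) else z, dtype=float)
    p = np.asarray(p.data if isinstance(p, Tensor) else p, dtype=float)
    nz, np_ = np.linalg.norm(z), np.linalg.norm(p)
    if nz == 0 or np_ == 0:
        raise DegenerateInputError("cosine similarity undefined for a zero vector")
    return float(np.exp(np.dot(z, p) / (nz * np_) / tau))


def negative_weights(a_i: int, K: int) -> np.ndarray:
    """Logistic age-distance weights over the K proxies for anchor bucket a_i.

    w_k = sigmoid(|a_i - k| / max_k |a_i - k|) for k != a_i, and w_{a_i} = 0;
    the farthest bucket gets the largest weight, 1/(1 + e^{-1}).
    """
    if K < 2:
        raise DegenerateInputError("negative weights need K >= 2 buckets")
    if not 0 <= a_i < K:
        raise ValidationError(f"bucket label {a_i} outside [0, {K - 1}]")
    k = np.arange(K)
    dist = np.abs(a_i - k).astype(float)
    w = 1.0 / (1.0 + np.exp(-dist / dist.max()))
    w[a_i] = 0.0
    return w


def _cosine_matrix(z: Tensor, p: Tensor) -> Tensor:
    """Cosine similarities between rows of z (N x d) and rows of p (K x d)."""
    zn = (((z**2).sum(axis=1, keepdims=True)) + _NORM_EPS).sqrt()
    pn = (((p**2).sum(axis=1, keepdims=True)) + _NORM_EPS).sqrt()
    return (z / zn) @ (p / pn).T


def proxy_contrastive_loss(batch: ContrastBatch, proxies: ProxySet, tau: float = 0.9) -> Tensor:
    """Mean over samples of -log of the weighted positive-proxy odds.

    Per sample: -log[ s_pos / (s_pos + sum_k w_k s_k) ] with s = exp(cos/tau)
    against every proxy and w the age-distance negative weights.
    """
    if batch.n == 0:
        raise ValidationError("empty batch")
    K = proxies.K
    labels = batch.bucket_labels
    if np.any(labels < 0) or np.any(labels >= K):
        raise ValidationError("bucket label outside [0, K-1]")
    sims = (_cosine_matrix(batch.embeddings, proxies.proxies) / tau).exp()  # (N, K)
    if K == 1:
        weights = np.zeros((batch.n, 1))
    else:
        weights = np.stack([negative_weights(a, K) for a in labels])  # (N, K)
    onehot = np.zeros((batch.n, K))
    onehot[np.arange(batch.n), labels] = 1.0
    positive = (sims * Tensor(onehot)).sum(axis=1)
    negative = (sims * Tensor(weights)).sum(axis=1)
    return -(positive / (positive + negative)).log().mean()


def direction_loss(batch: ContrastBatch, proxies: ProxySet, tau: float = 0.9) -> Tensor:
    """Align embedding-difference directions with proxy-difference directions.

    For ordered pairs (i, j) with distinct buckets, the similarity is
    exp(<normalize(z_i - z_j), normalize(p_{a_i} - p_{a_j})> / tau); sample
    i's term is -log of the mass on pairs where i is the older one, averaged
    over samples that have at least one such pair. Same-bucket pairs (zero
    proxy difference) and coincident embeddings are excluded; a batch with
    all labels equal has no ordered pairs and scores 0.
    """
    if batch.n < 1:
        raise ValidationError("empty batch")
    labels = batch.bucket_labels
    if np.unique(labels).size < 2:
        logger.warning("direction loss degenerate: all bucket labels equal")
        return Tensor(0.0)
    z = batch.embeddings
    p = proxies.proxies
    n, d = z.shape

    # Pairwise differences via broadcasting: (n, n, d).
    dz = z.reshape(n, 1, d) - z.reshape(1, n, d)
    dp_full = p[labels].reshape(n, 1, d) - p[labels].reshape(1, n, d)

    cross_bucket = labels[:, None] != labels[None, :]
    distinct_z = np.linalg.norm(dz.data, axis=-1) > 0
    valid = cross_bucket & distinct_z & ~np.eye(n, dtype=bool)
    older = valid & (labels[:, None] > labels[None, :])

    dz_n = dz / ((dz**2).sum(axis=-1, keepdims=True) + _NORM_EPS).sqrt()
    dp_n = dp_full / ((dp_full**2).sum(axis=-1, keepdims=True) + _NORM_EPS).sqrt()
    s_dir = ((dz_n * dp_n).sum(axis=-1) / tau).exp()  # (n, n)

    has_older = older.any(axis=1)
    if not np.any(has_older):
        logger.warning("direction loss degenerate: no ordered pairs")
        return Tensor(0.0)
    numer = (s_dir * Tensor(older.astype(float))).sum(axis=1)
    denom = (s_dir * Tensor(valid.astype(float))).sum(axis=1)
    keep = np.nonzero(has_older)[0]
    return -(numer[keep] / denom[keep]).log().mean()


def order_loss(
    batch: ContrastBatch,
    proxies: ProxySet,
    tau: float = 0.9,
    lambda_dir: float = 0.5,
) -> Tensor:
    """Combined age-order objective: contrastive + lambda * direction."""
    contrast = proxy_contrastive_loss(batch, proxies, tau)
    if lambda_dir == 0.0:
        return contrast
    return contrast + lambda_dir * direction_loss(batch, proxies, tau)
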