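"""Pre-training, fine-tuning, and the soft-label age-prediction head.

Pre-training minimizes the negative multi-omics ELBO plus the age-order
contrastive objective computed on the joint posterior means:

    L_pretrain = recon_loss + beta1 * KL + beta2 * L_order

Fine-tuning attaches an MLP head mapping the joint posterior mean to B=101
logits over integer ages 0..100. The target for each sample is a Gaussian
soft label centered at its chronological age (width sigma, default 3
years), and the loss combines soft-label cross-entropy with a mean-absolute
error between the probability-weighted expected age and the chronological
age:

    L_finetune = L_CE + beta * L_reg

Both stages use Adam with per-epoch multiplicative learning-rate decay and
early stopping on a held-out validation split. Fine-tuning updates the
encoders at a much smaller learning rate than the head (defaults 1e-6 vs
1e-3); decoders and proxies stay frozen. Inference is deterministic: it
uses the joint posterior mean, never a latent sample.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from omiclock.autodiff import Adam, Tensor, softmax as softmax_t, logsumexp
from omiclock.contrast import ContrastBatch, init_proxies, order_loss
from omiclock.data import MultiOmicsDataset
from omiclock.errors import DomainError, ValidationError
from omiclock.poe import ModelConfig, ModelState, elbo_t, _batch_posterior

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SoftTarget:
    """Gaussian soft label over B integer-age bins; probabilities sum to 1."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < 0):
            raise ValidationError("soft-target probabilities must be >= 0")
        if abs(float(p.sum(axis=-1).max(initial=1.0)) - 1.0) > 1e-6 or abs(
            float(p.sum(axis=-1).min(initial=1.0)) - 1.0
        ) > 1e-6:
            raise ValidationError("soft-target probabilities must sum to 1")


@dataclass(frozen=True)
class AgePrediction:
    """Per-sample logits, softmax probabilities and expected age in years."""

    logits: np.ndarray
    probabilities: np.ndarray
    expected_age: np.ndarray

    def to_frame(self, sample_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(sample_ids), "predicted_age": self.expected_age}
        )


@dataclass
class TrainHistory:
    """Per-epoch loss components plus the validation metric and best epoch."""

    components: list[dict[str, float]] = field(default_factory=list)
    validation: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.components)
        frame.insert(0, "epoch", np.arange(len(self.components)))
        frame["validation"] = self.validation
        return frame

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def desk_scale_config(seed: int = 0, **overrides) -> ModelConfig:
    """Configuration for small cohorts (hundreds of samples).

    The stock learning rate (1e-4) is matched to cohort-scale training where
    an epoch holds tens of optimizer steps and the lr x steps budget is
    large; at a few hundred samples and <= 30 epochs the same budget needs
    lr 1e-3 and batch 64. Fine-tuning rates are unchanged (the head's 1e-3
    already trains from scratch at this scale).
    """
    settings = dict(learning_rate=1e-3, batch_size=64, epochs=30, latent_dim=8, seed=seed)
    settings.update(overrides)
    return ModelConfig(**settings)


# ---------------------------------------------------------------------------
# Soft targets and head losses


def soft_target(a_i: float, B: int = 101, sigma: float = 3.0, eps: float = 1e-8) -> SoftTarget:
    """Gaussian soft label centered at age ``a_i`` over bins 0..B-1.

    Unnormalized weights exp(-(k - a)^2 / (2 sigma^2)) are divided by their
    sum plus ``eps``. Ages outside [0, B-1] are clamped with a warning.
    """
    if sigma <= 0:
        raise DomainError("sigma must be > 0")
    a = float(a_i)
    if a < 0 or a > B - 1:
        logger.warning("age %.2f outside [0, %d]; clamping", a, B - 1)
        a = min(max(a, 0.0), float(B - 1))
    k = np.arange(B, dtype=float)
    d = np.exp(-((k - a) ** 2) / (2.0 * sigma**2))
    p = d / (d.sum() + eps)  # eps guards the degenerate all-zero case
    return SoftTarget(p / p.sum())


def soft_target_matrix(
    ages: np.ndarray, B: int = 101, sigma: float = 3.0, eps: float = 1e-8
) -> np.ndarray:
    """Vectorized :func:`soft_target` over a cohort; returns (n, B)."""
    a = np.clip(np.asarray(ages, dtype=float), 0.0, float(B - 1))
    k = np.arange(B, dtype=float)
    d = np.exp(-((k[None, :] - a[:, None]) ** 2) / (2.0 * sigma**2))
    p = d / (d.sum(axis=1, keepdims=True) + eps)
    return p / p.sum(axis=1, keepdims=True)


def expected_age(probabilities: np.ndarray) -> np.ndarray | float:
    """Probability-weighted mean bin value, sum_k p_k * k over bins 0..B-1."""
    p = np.asarray(probabilities, dtype=float)
    bins = np.arange(p.shape[-1], dtype=float)
    out = p @ bins
    return float(out) if out.ndim == 0 else out


def cross_entropy_loss(predictions, targets) -> float:
    """Soft-label cross-entropy -1/N sum_i sum_k d_ik log p_ik."""
    p = predictions.probabilities if isinstance(predictions, AgePrediction) else predictions
    d = targets.probabilities if isinstance(targets, SoftTarget) else targets
    p = np.atleast_2d(np.asarray(p, dtype=float))
    d = np.atleast_2d(np.asarray(d, dtype=float))
    if p.shape != d.shape:
        raise ValidationError(f"prediction shape {p.shape} != target shape {d.shape}")
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    logp = np.where(d > 0, logp, 0.0)  # 0 * log 0 = 0 convention
    return float(-(d * logp).sum(axis=1).mean())


def regression_loss(predictions, ages) -> float:
    """Mean absolute deviation of expected age from chronological age."""
    if isinstance(predictions, AgePrediction):
        a_hat = predictions.expected_age
    else:
        a_hat = expected_age(predictions)
    a_hat = np.atleast_1d(np.asarray(a_hat, dtype=float))
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if a_hat.shape != ages.shape:
        raise ValidationError("expected-age and age vectors differ in length")
    return float(np.abs(a_hat - ages).mean())


def finetune_loss(predictions, ages, targets, beta: float = 1.0) -> float:
    """L = cross-entropy + beta * expected-age regression."""
    return cross_entropy_loss(predictions, targets) + beta * regression_loss(predictions, ages)


# ---------------------------------------------------------------------------
# Tensor-valued head forward (used inside fine-tuning)


def _head_losses_t(
    state: ModelState, mean: Tensor, ages: np.ndarray, config: ModelConfig
) -> tuple[Tensor, Tensor, Tensor]:
    """(total, ce, reg) fine-tuning losses for a batch of posterior means."""
    logits = state.head(mean)
    logp = logits - logsumexp(logits, axis=-1, keepdims=True)
    targets = soft_target_matrix(ages, config.B, config.sigma_target, config.eps)
    ce = -(Tensor(targets) * logp).sum(axis=1).mean()
    probs = logp.exp()
    bins = np.arange(config.B, dtype=float)
    a_hat = probs @ Tensor(bins)
    reg = (a_hat - Tensor(np.asarray(ages, dtype=float))).abs().mean()
    return ce + config.beta_finetune * reg, ce, reg


# ---------------------------------------------------------------------------
# Optimization loops


def _split_validation(
    n: int, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    if val_fraction > 0:
        n_val = max(1, min(n - 1, n_val))
    return perm[n_val:], perm[:n_val]


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start : start + batch_size]


def _snapshot(state: ModelState) -> dict[str, np.ndarray]:
    return {k: p.data.copy() for k, p in state._named_parameters().items()}


def _restore(state: ModelState, snapshot: dict[str, np.ndarray]) -> None:
    for k, p in state._named_parameters().items():
        p.data = snapshot[k].copy()


def _dataset_arrays(dataset: MultiOmicsDataset):
    arrays = {m: dataset.matrices[m].values for m in dataset.matrices}
    mask = {m: np.asarray(v, dtype=bool) for m, v in dataset.presence_mask.items()}
    return arrays, mask


def _pretrain_batch_loss(
    state: ModelState,
    arrays,
    mask,
    buckets: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
    contrastive: bool,
) -> tuple[Tensor, dict[str, float]]:
    elbo, recon, kl, (joint_mean, _) = elbo_t(state, arrays, mask, beta=0.0, rng=rng)
    recon_loss = -elbo  # beta=0: pure reconstruction
    loss = recon_loss + config.beta1 * kl
    comps = {
        "recon": recon_loss.item(),
        "kl": kl.item(),
        "contrast": 0.0,
        "direction": 0.0,
    }
    if contrastive and config.beta2 != 0.0:
        from omiclock.contrast import ProxySet, direction_loss, proxy_contrastive_loss

        batch = ContrastBatch(joint_mean, buckets)
        proxy_set = ProxySet(state.proxies)
        contrast = proxy_contrastive_loss(batch, proxy_set, config.tau)
        direction = (
            direction_loss(batch, proxy_set, config.tau)
            if config.lambda_dir != 0.0
            else Tensor(0.0)
        )
        loss = loss + config.beta2 * (contrast + config.lambda_dir * direction)
        comps["contrast"] = contrast.item()
        comps["direction"] = direction.item()
    comps["total"] = loss.item()
    return loss, comps


def _finetune_batch_loss(
    state: ModelState, arrays, mask, ages: np.ndarray, config: ModelConfig
) -> tuple[Tensor, dict[str, float]]:
    joint_mean, _ = _batch_posterior(state, arrays, mask)
    total, ce, reg = _head_losses_t(state, joint_mean, ages, config)
    return total, {"ce": ce.item(), "reg": reg.item(), "total": total.item()}


def _epoch_loop(
    dataset: MultiOmicsDataset,
    state: ModelState,
    config: ModelConfig,
    optimizer: Adam,
    batch_loss_fn,
    val_loss_fn,
) -> TrainHistory:
    """Shared epoch/early-stopping loop; restores the best parameters."""
    n = dataset.n_samples
    train_idx, val_idx = _split_validation(n, config.val_fraction, config.seed)
    if val_idx.size == 0:
        val_idx = train_idx  # degenerate fallback: validate on training data
    arrays, mask = _dataset_arrays(dataset)
    history = TrainHistory()
    best_val = np.inf
    best_params = _snapshot(state)
    since_best = 0
    shuffle_rng = np.random.default_rng(config.seed + 1)
    noise_rng = np.random.default_rng(config.seed + 2)
    for epoch in range(config.epochs):
        epoch_comps: list[dict[str, float]] = []
        sizes: list[int] = []
        for rows in _batches(train_idx.size, config.batch_size, shuffle_rng):
            idx = train_idx[rows]
            batch_arrays = {m: arr[idx] for m, arr in arrays.items()}
            batch_mask = {m: v[idx] for m, v in mask.items()}
            loss, comps = batch_loss_fn(state, batch_arrays, batch_mask, idx, noise_rng)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step(lr_scale=config.lr_decay**epoch)
            epoch_comps.append(comps)
            sizes.append(idx.size)
        weights = np.asarray(sizes, dtype=float) / float(sum(sizes))
        mean_comps = {
            k: float(sum(w * c[k] for w, c in zip(weights, epoch_comps)))
            for k in epoch_comps[0]
        }
        val = val_loss_fn(state, arrays, mask, val_idx)
        history.components.append(mean_comps)
        history.validation.append(val)
        if val < best_val - 1e-12:
            best_val = val
            best_params = _snapshot(state)
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                logger.info("early stopping at epoch %d (best %d)", epoch, history.best_epoch)
                break
    _restore(state, best_params)
    return history


def pretrain(
    dataset: MultiOmicsDataset, config: ModelConfig
) -> tuple[ModelState, TrainHistory]:
    """Pre-train the PoE-VAE with the age-order contrastive objective.

    Minimizes recon + beta1*KL + beta2*(contrast + lambda*direction) with
    Adam (default lr 1e-4, weight decay 1e-6), multiplicative per-epoch
    learning-rate decay, at most ``config.epochs`` epochs and early stopping
    after ``config.patience`` epochs without validation improvement. The
    contrastive losses act on the joint posterior means. The cohort must
    carry age buckets; with a single represented bucket the direction loss
    degenerates to 0 and a warning is emitted.
    """
    cohort = dataset.cohort
    if cohort.age_bucket is None:
        raise ValidationError("cohort has no age buckets; call assign_age_buckets first")
    if np.unique(cohort.age_bucket).size < 2:
        logger.warning("only one age bucket represented; direction loss will be 0")
    state = ModelState(config, dataset.feature_counts())
    state.proxies = init_proxies(config.K, config.latent_dim, config.seed).proxies
    optimizer = Adam(
        state.encoder_parameters() + state.decoder_parameters() + [state.proxies],
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    buckets = np.asarray(cohort.age_bucket, dtype=int)

    def batch_loss(state_, arrays_, mask_, idx, noise_rng):
        return _pretrain_batch_loss(
            state_, arrays_, mask_, buckets[idx], config, noise_rng, contrastive=True
        )

    def val_loss(state_, arrays_, mask_, idx):
        val_arrays = {m: a[idx] for m, a in arrays_.items()}
        val_mask = {m: v[idx] for m, v in mask_.items()}
        rng = np.random.default_rng(config.seed + 3)  # same draws every epoch
        loss, _ = _pretrain_batch_loss(
            state_, val_arrays, val_mask, buckets[idx], config, rng, contrastive=True
        )
        return loss.item()

    history = _epoch_loop(dataset, state, config, optimizer, batch_loss, val_loss)
    return state, history


def finetune(
    dataset: MultiOmicsDataset, pretrained: ModelState, config: ModelConfig | None = None
) -> tuple[ModelState, TrainHistory]:
    """Fine-tune the age head (and, gently, the encoders) for age prediction.

    Two Adam parameter groups: encoders at ``config.encoder_lr_finetune``
    (default 1e-6) and the head at ``config.head_lr_finetune`` (default
    1e-3). Decoders and proxies are frozen. Optimizes soft-label
    cross-entropy plus ``beta_finetune`` times the mean-absolute
    expected-age error, with the same epoch/early-stopping scheme as
    pre-training. Returns a fine-tuned copy; the input state is untouched.
    """
    config = config or pretrained.config
    state = copy.deepcopy(pretrained)
    state.config = config
    optimizer = Adam(
        state.head_parameters(),
        lr=config.head_lr_finetune,
        weight_decay=config.weight_decay,
    )
    optimizer.add_param_group(
        state.encoder_parameters(),
        lr=config.encoder_lr_finetune,
        weight_decay=config.weight_decay,
    )
    ages = np.asarray(dataset.cohort.chronological_age, dtype=float)

    def batch_loss(state_, arrays_, mask_, idx, noise_rng):
        return _finetune_batch_loss(state_, arrays_, mask_, ages[idx], config)

    def val_loss(state_, arrays_, mask_, idx):
        val_arrays = {m: a[idx] for m, a in arrays_.items()}
        val_mask = {m: v[idx] for m, v in mask_.items()}
        loss, _ = _finetune_batch_loss(state_, val_arrays, val_mask, ages[idx], config)
        return loss.item()

    history = _epoch_loop(dataset, state, config, optimizer, batch_loss, val_loss)
    return state, history


def predict_biological_age(dataset: MultiOmicsDataset, state: ModelState) -> AgePrediction:
    """Deterministic inference: joint posterior mean -> logits -> expected age."""
    arrays, mask = _dataset_arrays(dataset)
    joint_mean, _ = _batch_posterior(state, arrays, mask)
    logits = state.head(joint_mean)
    probabilities = softmax_t(logits, axis=-1).data
    return AgePrediction(
        logits=logits.data,
        probabilities=probabilities,
        expected_age=expected_age(probabilities),
    )
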