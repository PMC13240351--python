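"""Product-of-experts multi-omics variational autoencoder.

Each modality gets its own encoder (a small MLP producing a diagonal
Gaussian "expert" over the shared latent space) and decoder. The joint
posterior over the latent variable z combines the experts of whatever
modalities a sample actually has by multiplying Gaussian densities —
precisions add, and the joint mean is the precision-weighted average of the
expert means — optionally together with the standard-normal prior treated
as one more expert. Missing modalities therefore need no imputation: their
experts are simply absent from the product. With a single expert and the
prior expert excluded, the joint posterior is exactly that expert.

The evidence lower bound (ELBO) for a sample is the sum over present
modalities of the Gaussian reconstruction log-likelihood of a
reparameterized latent draw, minus a weighted KL divergence from the joint
posterior to the prior. Reconstruction likelihoods are unit-variance
Gaussians with additive constants dropped, so a perfect reconstruction
scores 0 and the reconstruction term is minus half the squared error.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from omiclock.autodiff import Tensor, concatenate
from omiclock.errors import DomainError, ShapeError, ValidationError

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GaussianPosterior:
    """Diagonal Gaussian over the latent space: mean and (positive) variance."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        variance = np.asarray(self.variance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "variance", variance)
        if mean.shape != variance.shape:
            raise ShapeError(f"mean shape {mean.shape} != variance shape {variance.shape}")
        if np.any(variance <= 0):
            raise DomainError("posterior variance must be strictly positive")

    @property
    def dim(self) -> int:
        return self.mean.shape[-1]

    @classmethod
    def standard(cls, d: int) -> "GaussianPosterior":
        return cls(mean=np.zeros(d), variance=np.ones(d))


@dataclass
class ModelConfig:
    """Architecture, loss weights and optimization settings.

    Loss weights: ``beta1`` scales the KL term and ``beta2`` the
    age-order contrastive term during pre-training; ``beta_finetune``
    balances the expected-age regression loss against the soft-label
    cross-entropy during fine-tuning. ``tau`` is the similarity
    temperature, ``lambda_dir`` the direction-loss weight,
    ``sigma_target`` the soft-label Gaussian width in years. ``K`` age
    buckets of ``bucket_width`` years feed the contrastive losses; the
    age head has ``B`` integer-age bins (ages 0..B-1).
    """

    latent_dim: int = 16
    hidden_sizes: tuple[int, ...] = (64,)
    head_hidden: tuple[int, ...] = (64,)
    beta1: float = 1.0
    beta2: float = 1.0
    beta_finetune: float = 1.0
    tau: float = 0.9
    lambda_dir: float = 0.5
    sigma_target: float = 3.0
    K: int = 10
    bucket_width: float = 10.0
    B: int = 101
    include_prior_expert: bool = True
    seed: int = 0
    learning_rate: float = 1e-4
    weight_decay: float = 1e-6
    encoder_lr_finetune: float = 1e-6
    head_lr_finetune: float = 1e-3
    epochs: int = 50
    patience: int = 10
    batch_size: int = 256
    lr_decay: float = 0.97
    val_fraction: float = 0.1
    variance_floor: float = 1e-6
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")
        if self.sigma_target <= 0:
            raise ValidationError("sigma_target must be > 0")
        if self.B < 2:
            raise ValidationError("B must be >= 2")
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        self.head_hidden = tuple(int(h) for h in self.head_hidden)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["hidden_sizes"] = list(self.hidden_sizes)
        out["head_hidden"] = list(self.head_hidden)
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("hidden_sizes", "head_hidden"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class MLP:
    """Dense tanh network; the final affine layer has no activation."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator, name: str) -> None:
        self.name = name
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.weights.append(Tensor(_xavier_uniform(rng, fan_in, fan_out), requires_grad=True))
            self.biases.append(Tensor(np.zeros(fan_out), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i != last:
                h = h.tanh()
        return h

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]


class ModelState:
    """All learnable parameters: per-modality encoders/decoders, age head, proxies.

    Encoders output a concatenated [mean, log-variance] vector of width
    2*latent_dim; variances are exponentiated log-variances clipped below at
    ``config.variance_floor``. The age head maps the joint posterior mean to
    B logits. Proxies (one latent vector per age bucket) belong to the
    contrastive objective and are created by the pre-training routine.
    """

    def __init__(self, config: ModelConfig, feature_counts: Mapping[str, int]) -> None:
        self.config = config
        self.feature_counts = dict(feature_counts)
        rng = np.random.default_rng(config.seed)
        d = config.latent_dim
        self.encoders: dict[str, MLP] = {}
        self.decoders: dict[str, MLP] = {}
        for modality in sorted(self.feature_counts):
            n_feat = self.feature_counts[modality]
            self.encoders[modality] = MLP(
                [n_feat, *config.hidden_sizes, 2 * d], rng, f"enc:{modality}"
            )
            self.decoders[modality] = MLP(
                [d, *tuple(reversed(config.hidden_sizes)), n_feat], rng, f"dec:{modality}"
            )
        self.head = MLP([d, *config.head_hidden, config.B], rng, "age_head")
        self.proxies: Tensor | None = None  # set by pre-training (ProxySet lives here)

    # -- parameter access ---------------------------------------------------

    def encoder_parameters(self) -> list[Tensor]:
        return [p for enc in self.encoders.values() for p in enc.parameters()]

    def decoder_parameters(self) -> list[Tensor]:
        return [p for dec in self.decoders.values() for p in dec.parameters()]

    def head_parameters(self) -> list[Tensor]:
        return self.head.parameters()

    def parameters(self) -> list[Tensor]:
        params = self.encoder_parameters() + self.decoder_parameters() + self.head_parameters()
        if self.proxies is not None:
            params.append(self.proxies)
        return params

    # -- forward passes (Tensor-valued, used by training) -------------------

    def encode_t(self, x: Tensor, modality: str) -> tuple[Tensor, Tensor]:
        """Expert posterior for a batch: (mean, variance), each (n, d)."""
        if modality not in self.encoders:
            raise KeyError(f"unknown modality {modality!r}")
        expected = self.feature_counts[modality]
        if x.shape[-1] != expected:
            raise ShapeError(
                f"{modality}: input has {x.shape[-1]} features, encoder expects {expected}"
            )
        out = self.encoders[modality](x)
        d = self.config.latent_dim
        mean = out[..., :d]
        variance = out[..., d:].exp().clip_min(self.config.variance_floor)
        return mean, variance

    def decode_t(self, z: Tensor, modality: str) -> Tensor:
        if modality not in self.decoders:
            raise KeyError(f"unknown modality {modality!r}")
        if z.shape[-1] != self.config.latent_dim:
            raise ShapeError(f"z has dim {z.shape[-1]}, expected {self.config.latent_dim}")
        return self.decoders[modality](z)

    # -- numpy-facing convenience ------------------------------------------

    def encode(self, modality_input: np.ndarray, modality: str) -> GaussianPosterior:
        """Expert posterior q(z | x_modality) for one sample or a batch."""
        x = np.atleast_2d(np.asarray(modality_input, dtype=float))
        mean, variance = self.encode_t(Tensor(x), modality)
        if np.asarray(modality_input).ndim == 1:
            return GaussianPosterior(mean.data[0], variance.data[0])
        return GaussianPosterior(mean.data, variance.data)

    def decode(self, z: np.ndarray, modality: str) -> np.ndarray:
        z2 = np.atleast_2d(np.asarray(z, dtype=float))
        out = self.decode_t(Tensor(z2), modality).data
        return out[0] if np.asarray(z).ndim == 1 else out

    # -- checkpointing ------------------------------------------------------

    def _named_parameters(self) -> dict[str, Tensor]:
        named: dict[str, Tensor] = {}
        for modality, enc in self.encoders.items():
            for i, p in enumerate(enc.parameters()):
                named[f"encoder/{modality}/{i}"] = p
        for modality, dec in self.decoders.items():
            for i, p in enumerate(dec.parameters()):
                named[f"decoder/{modality}/{i}"] = p
        for i, p in enumerate(self.head.parameters()):
            named[f"head/{i}"] = p
        if self.proxies is not None:
            named["proxies"] = self.proxies
        return named

    def save(self, path: str | Path) -> None:
        """Write a single-archive checkpoint (versioned JSON config + arrays)."""
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": self.config.to_dict(),
            "feature_counts": self.feature_counts,
        }
        named = self._named_parameters()
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=1))
            buf = io.BytesIO()
            np.savez(buf, **{k: v.data for k, v in named.items()})
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        with zipfile.ZipFile(path, "r") as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
                raise ValidationError(
                    f"unsupported checkpoint format version {meta.get('format_version')}"
                )
            arrays = np.load(io.BytesIO(zf.read("params.npz")))
            config = ModelConfig.from_dict(meta["config"])
            state = cls(config, meta["feature_counts"])
            named = state._named_parameters()
            if "proxies" in arrays and "proxies" not in named:
                state.proxies = Tensor(arrays["proxies"], requires_grad=True)
                named = state._named_parameters()
            for key in arrays.files:
                named[key].data = np.array(arrays[key])
        return state


# ---------------------------------------------------------------------------
# Product-of-experts combination and KL divergence


def poe_combine(
    experts: Sequence[GaussianPosterior],
    prior: GaussianPosterior | None = None,
    include_prior: bool = True,
) -> GaussianPosterior:
    """Multiply Gaussian experts (and optionally the prior) into one Gaussian.

    Precisions add elementwise; the joint mean is the precision-weighted
    average of expert means. With one expert and ``include_prior=False`` the
    expert is returned unchanged — the exact single-modality collapse.
    """
    experts = list(experts)
    if not experts and not include_prior:
        raise ValidationError("no experts and no prior: joint posterior undefined")
    dims = {e.dim for e in experts}
    if prior is not None:
        dims.add(prior.dim)
    if len(dims) > 1:
        raise ShapeError(f"experts disagree on latent dimension: {sorted(dims)}")
    d = dims.pop()
    if include_prior and prior is None:
        prior = GaussianPosterior.standard(d)
    terms = list(experts) + ([prior] if include_prior else [])
    precision = sum(1.0 / t.variance for t in terms)
    mean = sum(t.mean / t.variance for t in terms) / precision
    return GaussianPosterior(mean=mean, variance=1.0 / precision)


def kl_to_prior(q: GaussianPosterior, prior: GaussianPosterior | None = None) -> float:
    """Closed-form KL divergence between diagonal Gaussians, KL(q || prior)."""
    if prior is None:
        prior = GaussianPosterior.standard(q.dim)
    if q.mean.shape != prior.mean.shape:
        raise ShapeError("posterior and prior dimensions differ")
    ratio = q.variance / prior.variance
    kl = 0.5 * np.sum(ratio + (q.mean - prior.mean) ** 2 / prior.variance - 1.0 - np.log(ratio))
    return float(kl)


def poe_combine_t(
    means: Sequence[Tensor],
    variances: Sequence[Tensor],
    include_prior: bool,
    variance_floor: float,
) -> tuple[Tensor, Tensor]:
    """Tensor version of :func:`poe_combine` for standard-normal prior.

    ``means[i]``/``variances[i]`` are (n, d) batches from modality i's
    encoder. Exact single-expert collapse is preserved when the prior is
    excluded.
    """
    if not means:
        raise ValidationError("poe_combine_t requires at least one expert")
    if len(means) == 1 and not include_prior:
        return means[0], variances[0]
    precision = Tensor(np.ones(1)) if include_prior else Tensor(np.zeros(1))
    weighted = Tensor(np.zeros(1))
    for mu, var in zip(means, variances):
        prec = 1.0 / var
        precision = precision + prec
        weighted = weighted + mu * prec
    variance = (1.0 / precision).clip_min(variance_floor)
    return weighted / precision, variance


def kl_standard_normal_t(mean: Tensor, variance: Tensor) -> Tensor:
    """Per-sample KL(N(mean, diag variance) || N(0, I)); returns (n,)."""
    return 0.5 * (variance + mean**2 - 1.0 - variance.log()).sum(axis=-1)


# ---------------------------------------------------------------------------
# ELBO


def _batch_posterior(
    state: ModelState,
    arrays: Mapping[str, np.ndarray],
    mask: Mapping[str, np.ndarray],
) -> tuple[Tensor, Tensor]:
    """Joint posterior (mean, variance) for a batch with mixed presence.

    Samples are grouped by modality-presence pattern so each group's experts
    are combined in one vectorized product; results are re-scattered into
    batch order. Modalities the model knows but the batch does not supply
    are simply absent from the product.
    """
    modalities = sorted(set(state.encoders) & set(arrays))
    if not modalities:
        raise ValidationError("batch supplies no modality known to the model")
    n = next(iter(arrays.values())).shape[0]
    pattern = np.stack([np.asarray(mask[m], dtype=bool) for m in modalities], axis=1)
    if np.any(~pattern.any(axis=1)):
        raise ValidationError("sample with zero present modalities in batch")
    encoded = {m: state.encode_t(Tensor(arrays[m]), m) for m in modalities}

    mean_parts: list[Tensor] = []
    var_parts: list[Tensor] = []
    row_order: list[np.ndarray] = []
    for pat in np.unique(pattern, axis=0):
        rows = np.nonzero((pattern == pat).all(axis=1))[0]
        present = [m for m, flag in zip(modalities, pat) if flag]
        mu, var = poe_combine_t(
            [encoded[m][0][rows] for m in present],
            [encoded[m][1][rows] for m in present],
            include_prior=state.config.include_prior_expert,
            variance_floor=state.config.variance_floor,
        )
        mean_parts.append(mu)
        var_parts.append(var)
        row_order.append(rows)
    perm = np.concatenate(row_order)
    inverse = np.empty(n, dtype=int)
    inverse[perm] = np.arange(n)
    return concatenate(mean_parts, axis=0)[inverse], concatenate(var_parts, axis=0)[inverse]


def elbo_t(
    state: ModelState,
    arrays: Mapping[str, np.ndarray],
    mask: Mapping[str, np.ndarray],
    beta: float,
    rng: np.random.Generator,
) -> tuple[Tensor, dict[str, Tensor], Tensor, tuple[Tensor, Tensor]]:
    """Batch-mean ELBO with one reparameterized latent draw per sample.

    Returns (elbo, per-modality reconstruction terms, KL term, joint
    posterior); reconstruction terms are batch means over the samples that
    actually carry the modality (0 if none do).
    """
    modalities = sorted(set(state.encoders) & set(arrays))
    n = next(iter(arrays.values())).shape[0]
    if n == 0:
        raise ValidationError("empty batch")
    joint_mean, joint_var = _batch_posterior(state, arrays, mask)
    noise = rng.standard_normal(joint_mean.shape)
    z = joint_mean + joint_var.sqrt() * Tensor(noise)
    recon_terms: dict[str, Tensor] = {}
    total_recon = Tensor(0.0)
    for m in modalities:
        present = np.asarray(mask[m], dtype=float)
        x_hat = state.decode_t(z, m)
        sq = ((Tensor(arrays[m]) - x_hat) ** 2).sum(axis=-1)
        loglik = -0.5 * (sq * Tensor(present)).sum() / float(n)
        recon_terms[m] = loglik
        total_recon = total_recon + loglik
    kl = kl_standard_normal_t(joint_mean, joint_var).mean()
    elbo = total_recon - beta * kl
    return elbo, recon_terms, kl, (joint_mean, joint_var)


def multiomics_elbo(
    dataset,
    state: ModelState,
    config: ModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, float], float]:
    """ELBO of a :class:`~omiclock.data.MultiOmicsDataset` (batch mean).

    Experts come only from modalities marked present for each sample; the
    reconstruction term sums only over those modalities; KL is taken between
    the joint posterior and the standard-normal prior, weighted by
    ``config.beta1``.
    """
    config = config or state.config
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    arrays = {m: dataset.matrices[m].values for m in dataset.matrices}
    mask = dict(dataset.presence_mask)
    elbo, recon, kl, _ = elbo_t(state, arrays, mask, beta=config.beta1, rng=rng)
    return elbo.item(), {m: t.item() for m, t in recon.items()}, kl.item()
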