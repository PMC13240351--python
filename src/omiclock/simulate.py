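"""Synthetic multi-omics cohorts with known age structure and survival.

The generator realizes the structure the model assumes, so every claim the
pipeline makes is falsifiable against a planted ground truth: a
low-dimensional latent state moves monotonically with *effective* age along
a fixed direction (plus isotropic latent noise); each modality observes the
latent state through a linear loading matrix in which only a chosen subset
of features carries age signal, the rest being pure noise; a planted
"accelerated" subgroup has an effective age older than its chronological
label by a fixed shift; modalities go missing at random per sample; and
survival times follow an exponential hazard that rises with the planted
age deviation.

Expression features are emitted on the TPM scale (non-negative, so the
standard log2(TPM+1) transform applies downstream); methylation features
are squashed through a logistic to beta values in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from omiclock.data import (
    CohortTable,
    MultiOmicsDataset,
    OmicsMatrix,
    align_dataset,
    assign_age_buckets,
)
from omiclock.errors import ValidationError
from omiclock.evaluate import SurvivalData

EXPRESSION_MODALITY = "rna"
METHYLATION_MODALITY = "methylation"


@dataclass(frozen=True)
class SimulationSpec:
    """Cohort-generator settings; defaults are the package's study conditions.

    Ages are uniform on ``age_range``; a fraction ``accel_fraction`` of
    samples is shifted ``accel_shift`` years older in effective age.
    ``n_informative_features`` features per modality load on the latent
    state (scaled by ``loading_scale``); the rest are noise.
    ``noise_sd`` is the per-modality observation noise on the pre-squash
    scale and ``latent_noise_sd`` the isotropic latent jitter. Survival:
    exponential event times with per-year baseline hazard
    ``baseline_hazard`` and log-hazard slope ``survival_effect`` per year
    of planted age deviation; a fraction ``censoring_rate`` of samples is
    independently censored uniformly before their event.
    """

    n_samples: int = 600
    age_range: tuple[float, float] = (20.0, 90.0)
    latent_dim_true: int = 4
    n_features: dict = field(
        default_factory=lambda: {EXPRESSION_MODALITY: 200, METHYLATION_MODALITY: 200}
    )
    n_informative_features: dict = field(
        default_factory=lambda: {EXPRESSION_MODALITY: 10, METHYLATION_MODALITY: 10}
    )
    loading_scale: float = 1.5
    noise_sd: dict = field(
        default_factory=lambda: {EXPRESSION_MODALITY: 0.15, METHYLATION_MODALITY: 0.15}
    )
    latent_noise_sd: float = 0.05
    accel_fraction: float = 0.2
    accel_shift: float = 8.0
    missing_fraction: dict = field(
        default_factory=lambda: {EXPRESSION_MODALITY: 0.1, METHYLATION_MODALITY: 0.1}
    )
    baseline_hazard: float = 0.02
    survival_effect: float = 0.12
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not 0.0 <= self.accel_fraction <= 1.0:
            raise ValidationError("accel_fraction must lie in [0, 1]")
        if self.accel_shift < 0:
            raise ValidationError("accel_shift must be >= 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValidationError("censoring_rate must lie in [0, 1]")
        if self.age_range[0] < 0 or self.age_range[1] <= self.age_range[0]:
            raise ValidationError("age_range must be ordered and non-negative")
        for mapping, what in (
            (self.noise_sd, "noise_sd"),
            (self.missing_fraction, "missing_fraction"),
        ):
            for m, v in mapping.items():
                if v < 0 or (what == "missing_fraction" and v > 1):
                    raise ValidationError(f"{what}[{m!r}] out of range")
        for m in self.n_features:
            if self.n_informative_features.get(m, 0) > self.n_features[m]:
                raise ValidationError(f"more informative than total features for {m!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for validation only (never model input)."""

    sample_ids: tuple[str, ...]
    chronological_age: np.ndarray
    effective_age: np.ndarray
    accelerated: np.ndarray  # boolean indicator
    latent: np.ndarray  # (n, latent_dim_true)
    informative_features: dict  # modality -> tuple of feature ids


def _age_scale(ages: np.ndarray, age_range: tuple[float, float]) -> np.ndarray:
    lo, hi = age_range
    return (ages - (lo + hi) / 2.0) / ((hi - lo) / 2.0)


def simulate_cohort(spec: SimulationSpec) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw a cohort under ``spec``; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = tuple(f"s{i:04d}" for i in range(n))
    ages = rng.uniform(*spec.age_range, size=n)
    accelerated = rng.random(n) < spec.accel_fraction
    effective = ages + spec.accel_shift * accelerated

    # Latent state: effective age (standardized) along the first latent axis,
    # isotropic jitter everywhere.
    d_true = spec.latent_dim_true
    latent = spec.latent_noise_sd * rng.standard_normal((n, d_true))
    latent[:, 0] += _age_scale(effective, spec.age_range)

    matrices: list[OmicsMatrix] = []
    informative: dict[str, tuple[str, ...]] = {}
    for modality in sorted(spec.n_features):
        p = spec.n_features[modality]
        n_info = spec.n_informative_features.get(modality, 0)
        info_idx = rng.choice(p, size=n_info, replace=False)
        loadings = np.zeros((d_true, p))
        # Age axis: strong loadings of random sign; other axes: weak nuisance.
        signs = rng.choice([-1.0, 1.0], size=n_info)
        loadings[0, info_idx] = signs * rng.uniform(0.5, 1.0, size=n_info) * spec.loading_scale
        if d_true > 1:
            loadings[1:, info_idx] = 0.3 * spec.loading_scale * rng.uniform(
                -1.0, 1.0, size=(d_true - 1, n_info)
            )
        noise = spec.noise_sd[modality] * rng.standard_normal((n, p))
        signal = latent @ loadings + noise
        if modality == METHYLATION_MODALITY:
            logit_base = rng.uniform(-2.0, 2.0, size=p)
            values = 1.0 / (1.0 + np.exp(-(logit_base + signal)))
        else:
            log_base = rng.uniform(1.0, 6.0, size=p)
            values = np.exp2(np.maximum(log_base + signal, 0.0)) - 1.0
        feature_ids = tuple(f"{modality[0]}f{j:04d}" for j in range(p))
        matrices.append(OmicsMatrix(modality, sample_ids, feature_ids, values))
        informative[modality] = tuple(feature_ids[j] for j in sorted(info_idx))

    # Modality-level missingness; every sample keeps at least one modality.
    present = {
        m.modality_name: rng.random(n) >= spec.missing_fraction.get(m.modality_name, 0.0)
        for m in matrices
    }
    if matrices:
        none_present = ~np.logical_or.reduce([present[m.modality_name] for m in matrices])
        for i in np.nonzero(none_present)[0]:
            keep = rng.integers(len(matrices))
            present[matrices[keep].modality_name][i] = True

    observed = [
        OmicsMatrix(
            m.modality_name,
            tuple(s for s, keep in zip(sample_ids, present[m.modality_name]) if keep),
            m.feature_ids,
            m.values[present[m.modality_name]],
        )
        for m in matrices
    ]
    cohort = assign_age_buckets(CohortTable(sample_ids=sample_ids, chronological_age=ages))
    dataset = align_dataset(observed, cohort)
    truth = GroundTruth(
        sample_ids=sample_ids,
        chronological_age=ages,
        effective_age=effective,
        accelerated=accelerated,
        latent=latent,
        informative_features=informative,
    )
    return dataset, truth


def simulate_survival(truth: GroundTruth, spec: SimulationSpec) -> SurvivalData:
    """Exponential event times whose hazard grows with planted age deviation.

    log hazard = log(baseline_hazard) + survival_effect * (effective - chron);
    a ``censoring_rate`` fraction of samples is censored at a uniform time
    before the event (rate 1.0 censors everyone).
    """
    rng = np.random.default_rng(spec.seed + 1)
    deviation = truth.effective_age - truth.chronological_age
    hazard = spec.baseline_hazard * np.exp(spec.survival_effect * deviation)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(truth.chronological_age.shape[0]) < spec.censoring_rate
    observed_time = np.where(censored, rng.uniform(0.0, 1.0, event_time.shape) * event_time, event_time)
    observed_time = np.maximum(observed_time, 1e-9)  # keep times strictly positive
    return SurvivalData(time=observed_time, event=(~censored).astype(float))
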