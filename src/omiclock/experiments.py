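"""Desk-scale validation study: simulate, train, stratify, evaluate.

One study = one synthetic cohort (default generator settings: 600 samples,
200 expression + 200 methylation features with 10 planted age markers each,
a 20% subgroup aged 8 years beyond its chronological label, 10% random
modality missingness, survival linked to the planted deviation).

Per cohort the study measures:

* held-out accuracy — an 80/20 split model's Pearson r between predicted
  and chronological age on the held-out 20%;
* acceleration detection — the clock is refit on the whole cohort, PAAG
  gaps are computed against chronological-age anchors, and the gap's
  ROC-AUC for the planted accelerated subgroup is recorded;
* survival — the three-way PAAG stratification is tested with the k-group
  log-rank statistic, and the gap's censoring-aware C-index is recorded;
* missing-modality robustness — correlation between expression-only and
  full-input predictions from the same checkpoint.

Studies are replicated over independent cohort seeds; replicate log-rank
evidence is combined with Fisher's method (single desk-scale cohorts have
limited power for the diluted three-group comparison — see the methods
note for the power analysis).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from omiclock.data import preprocess_dataset
from omiclock.evaluate import (
    concordance_index,
    multivariate_logrank,
    rank_features_by_attribution,
)
from omiclock.paag import compute_paag, stratify
from omiclock.poe import ModelConfig, ModelState
from omiclock.simulate import SimulationSpec, simulate_cohort, simulate_survival
from omiclock.train import desk_scale_config, finetune, predict_biological_age, pretrain

HELD_OUT_FRACTION = 0.2
FINETUNE_EPOCHS = 50


@dataclass(frozen=True)
class StudyResult:
    """Metrics of one simulated cohort study."""

    seed: int
    n_samples: int
    held_out_r: float
    paag_auc: float
    logrank_chi2: float
    logrank_df: int
    logrank_p: float
    c_index: float
    missing_modality_r: float
    epsilon_years: float
    accelerated_group_fraction: float


def roc_auc(score: np.ndarray, label: np.ndarray) -> float:
    """Rank-based ROC-AUC (Mann-Whitney U / (n_pos * n_neg))."""
    label = np.asarray(label, dtype=bool)
    u = stats.mannwhitneyu(score[label], score[~label], alternative="greater").statistic
    return float(u / (label.sum() * (~label).sum()))


def _train_clock(dataset, config: ModelConfig) -> ModelState:
    pretrained, _ = pretrain(dataset, config)
    finetuned, _ = finetune(
        dataset, pretrained, dataclasses.replace(config, epochs=FINETUNE_EPOCHS)
    )
    return finetuned


def run_study(
    seed: int,
    spec: SimulationSpec | None = None,
    config: ModelConfig | None = None,
    paag_group_width: float = 1.0,
) -> tuple[StudyResult, dict]:
    """Run one full desk-scale study; returns metrics plus working objects.

    The second element exposes the cohort, ground truth, full-cohort model
    and PAAG table for follow-up analyses (e.g. feature attribution).
    """
    spec = spec if spec is not None else SimulationSpec(seed=seed)
    if spec.seed != seed:
        spec = dataclasses.replace(spec, seed=seed)
    config = config if config is not None else desk_scale_config(seed)
    dataset, truth = simulate_cohort(spec)
    survival = simulate_survival(truth, spec)
    prepared = preprocess_dataset(dataset)
    n = prepared.n_samples

    # Held-out accuracy from an 80/20 split refit.
    split_rng = np.random.default_rng(seed + 100)
    test_idx = split_rng.choice(n, int(round(HELD_OUT_FRACTION * n)), replace=False)
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    split_model = _train_clock(prepared.subset(train_idx), config)
    test_pred = predict_biological_age(prepared.subset(test_idx), split_model)
    held_out_r = float(
        np.corrcoef(test_pred.expected_age, dataset.cohort.chronological_age[test_idx])[0, 1]
    )

    # Full-cohort clock for the PAAG analyses.
    model = _train_clock(prepared, config)
    prediction = predict_biological_age(prepared, model)
    paag = stratify(
        compute_paag(
            prediction.expected_age,
            dataset.cohort.chronological_age,
            group_width=paag_group_width,
        )
    )
    auc = roc_auc(paag.gap, truth.accelerated)
    logrank = multivariate_logrank(survival, paag.group_label)
    c_index = concordance_index(paag.gap, survival)

    # Missing-modality contract: expression-only vs full-input predictions.
    rna_only = dataclasses.replace(
        prepared,
        presence_mask={
            "rna": np.ones(n, dtype=bool),
            "methylation": np.zeros(n, dtype=bool),
        },
    )
    rna_pred = predict_biological_age(rna_only, model)
    missing_r = float(np.corrcoef(rna_pred.expected_age, prediction.expected_age)[0, 1])

    result = StudyResult(
        seed=seed,
        n_samples=n,
        held_out_r=held_out_r,
        paag_auc=auc,
        logrank_chi2=logrank.statistic,
        logrank_df=logrank.degrees_of_freedom,
        logrank_p=logrank.p_value,
        c_index=c_index,
        missing_modality_r=missing_r,
        epsilon_years=float(paag.epsilon),
        accelerated_group_fraction=float(np.mean(paag.group_label == "accelerated")),
    )
    extras = {
        "dataset": dataset,
        "prepared": prepared,
        "truth": truth,
        "survival": survival,
        "model": model,
        "prediction": prediction,
        "paag": paag,
    }
    return result, extras


def fisher_combined_p(p_values) -> tuple[float, float]:
    """Fisher's method over replicate p-values: (chi2, combined p)."""
    p = np.asarray(list(p_values), dtype=float)
    chi2 = float(-2.0 * np.log(np.clip(p, 1e-300, 1.0)).sum())
    return chi2, float(stats.chi2.sf(chi2, 2 * p.size))


def run_replicated_study(
    seeds=(1, 2, 3),
    spec: SimulationSpec | None = None,
    config_factory=None,
) -> tuple[list[StudyResult], dict]:
    """Triplicate study: per-seed metrics + replicate-aggregated summary."""
    factory = config_factory or desk_scale_config
    results = []
    last_extras: dict = {}
    for seed in seeds:
        result, extras = run_study(seed, spec=spec, config=factory(seed))
        results.append(result)
        last_extras = extras
    chi2, p = fisher_combined_p(r.logrank_p for r in results)
    summary = {
        "mean_held_out_r": float(np.mean([r.held_out_r for r in results])),
        "min_held_out_r": float(np.min([r.held_out_r for r in results])),
        "mean_paag_auc": float(np.mean([r.paag_auc for r in results])),
        "min_paag_auc": float(np.min([r.paag_auc for r in results])),
        "logrank_fisher_chi2": chi2,
        "logrank_fisher_p": p,
        "per_seed_logrank_p": [r.logrank_p for r in results],
        "mean_c_index": float(np.mean([r.c_index for r in results])),
        "min_missing_modality_r": float(np.min([r.missing_modality_r for r in results])),
    }
    return results, {"summary": summary, "last_extras": last_extras}


def planted_feature_recovery(
    extras: dict, n_background: int = 32, n_samples: int = 64, seed: int = 0
) -> tuple[int, object]:
    """Top-10 planted-marker overlap of the attribution ranking.

    Uses the full-cohort model of a completed study; returns the number of
    planted informative features among the 10 highest-ranked features and
    the full ranking.
    """
    prepared = extras["prepared"]
    truth = extras["truth"]
    model = extras["model"]
    rng = np.random.default_rng(seed)
    n = prepared.n_samples
    background = rng.choice(n, min(n_background, n), replace=False)
    samples = rng.choice(n, min(n_samples, n), replace=False)
    ranking = rank_features_by_attribution(model, prepared, background, samples)
    planted = {f for ids in truth.informative_features.values() for f in ids}
    overlap = len(set(ranking.top(10)["feature_id"]) & planted)
    return overlap, ranking
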