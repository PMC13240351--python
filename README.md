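# omiclock

Multi-omics biological-age modelling: a product-of-experts variational
autoencoder over RNA-seq expression and DNA-methylation profiles,
pre-trained with age-order-enhanced contrastive learning, fine-tuned to
predict biological age through a soft-label classification head, and
scored with the **personalized-context-aware age gap (PAAG)** — a
population-anchored alternative to the conventional age gap — validated
with censoring-aware concordance and k-group log-rank statistics.

The package is aimed at researchers studying aging clocks and
age-acceleration metrics who want a fully testable, desk-scale
implementation: a bundled synthetic-cohort simulator plants a known
accelerated subgroup, modality missingness and linked survival, so every
stage of the pipeline can be validated against ground truth without any
external cohort.

## The model

For modalities i = 1..N with observations x_i, each encoder yields a
diagonal-Gaussian expert q(z | x_i) over a shared latent z. The joint
posterior is a product of experts (optionally including the N(0, I)
prior): precisions add,

    1/sigma^2 = 1/sigma_0^2 + sum_i 1/sigma_i^2,
    mu = (mu_0/sigma_0^2 + sum_i mu_i/sigma_i^2) * sigma^2,

so a sample missing a modality simply contributes fewer experts, and a
single expert (prior excluded) passes through unchanged. Training
maximizes the multi-omics ELBO — reconstruction over present modalities
minus beta_1 x KL(q(z|X) || N(0, I)) — plus an age-order contrastive
objective on the latent means: a proxy-based term that pulls embeddings
toward a learnable proxy of their 10-year age bucket, with negatives
weighted by bucket distance, and a direction term aligning
normalize(z_i - z_j) with normalize(p_{a_i} - p_{a_j}) for cross-bucket
pairs (older-minus-younger in the numerator mask).

Fine-tuning attaches an MLP head producing B = 101 logits over integer
ages; targets are Gaussian soft labels centered at chronological age
(sigma = 3 y), and the loss is cross-entropy plus beta x |expected age -
chronological age|. The predicted biological age is the
probability-weighted expected age.

PAAG anchors each sample to its chronological-age group:

    g_i = a_hat_i - mean{ a_hat_j : a_j in group(a_i) },

which cancels group-level clock bias (gaps sum to zero within every
anchor group). Cohorts are stratified at epsilon = SD(g): accelerated
(g > epsilon), decelerated (g < -epsilon), normal otherwise.

## Worked example

```python
import dataclasses
import numpy as np
import omiclock as oc
from omiclock.train import desk_scale_config
from omiclock.experiments import roc_auc

spec = oc.SimulationSpec(n_samples=600, seed=3)       # generator defaults
dataset, truth = oc.simulate_cohort(spec)
prepared = oc.preprocess_dataset(dataset)             # log2(TPM+1), probe filter, z-score

config = desk_scale_config(seed=3)
pretrained, _ = oc.pretrain(prepared, config)          # PoE-VAE + contrastive, <= 30 epochs
model, _ = oc.finetune(prepared, pretrained,
                       dataclasses.replace(config, epochs=50))

prediction = oc.predict_biological_age(prepared, model)
r = np.corrcoef(prediction.expected_age, dataset.cohort.chronological_age)[0, 1]
print(f"Pearson r(predicted, chronological) = {r:.3f}")

paag = oc.stratify(oc.compute_paag(prediction.expected_age,
                                   dataset.cohort.chronological_age))
print(f"PAAG threshold epsilon = {paag.epsilon:.2f} years")
for label in ("decelerated", "normal", "accelerated"):
    print(f"  {label:<12} n = {int(np.sum(paag.group_label == label))}")
print(f"ROC-AUC for planted accelerated subgroup: "
      f"{roc_auc(paag.gap, truth.accelerated):.3f}")

survival = oc.simulate_survival(truth, spec)
res = oc.multivariate_logrank(survival, paag.group_label)
print(f"3-group log-rank: chi2 = {res.statistic:.2f} "
      f"(df={res.degrees_of_freedom}), p = {res.p_value:.3g}")
```

Output:

```
Pearson r(predicted, chronological) = 0.967
PAAG threshold epsilon = 3.91 years
  decelerated  n = 75
  normal       n = 445
  accelerated  n = 80
ROC-AUC for planted accelerated subgroup: 0.866
3-group log-rank: chi2 = 15.96 (df=2), p = 0.000342
```

The clock tracks chronological age closely (r = 0.967); the gap statistic
flags the planted accelerated subgroup (ROC-AUC 0.866 against a 20%
subgroup aged 8 years beyond its label); and the three aging strata show
significantly different survival in this cohort. Note that single-cohort
log-rank power at n = 600 is limited — the validation study replicates
cohorts and combines log-rank evidence across replicates (see
`docs/methods.md`).

## Command line

The same pipeline is available as subcommands, each taking a YAML config
plus flag overrides and writing its artifacts into a run directory:

```bash
omiclock simulate --config run.yaml --out-dir data/
omiclock pretrain --config run.yaml --data-dir data/ --out-dir pre/
omiclock finetune --config run.yaml --data-dir data/ \
    --checkpoint pre/pretrained.ckpt --out-dir fine/
omiclock predict  --data-dir data/ --checkpoint fine/finetuned.ckpt --out pred.tsv
omiclock paag     --predictions pred.tsv --out paag.tsv
omiclock evaluate --paag-table paag.tsv --data-dir data/ \
    --checkpoint fine/finetuned.ckpt --out-dir eval/
```

`predict` handles a missing modality file through the product-of-experts
path — supply only `rna.tsv` and predictions come from the expression
expert alone.

## Layout

    src/omiclock/
      data.py         containers, TSV/CSV/HDF5 I/O, preprocessing, buckets
      autodiff.py     numpy reverse-mode autodiff + Adam
      poe.py          encoders/decoders, product of experts, ELBO
      contrast.py     proxy-contrastive + order-aware direction losses
      train.py        pre-training, fine-tuning, soft-label age head
      paag.py         context-aware age gap + stratification
      evaluate.py     C-index, k-group log-rank, feature attribution
      simulate.py     synthetic cohort + survival generator
      experiments.py  desk-scale validation studies
      cli.py          command-line pipeline
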