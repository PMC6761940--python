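# drvae

Semi-supervised variational autoencoders for **joint modeling of drug
perturbation signatures and drug response** in cancer cell lines.

Predicting whether a cell line (ultimately, a patient) will respond to a
drug from pre-treatment gene expression is hard: thousands of genes, few
labeled samples.  High-throughput perturbation screens (L1000-style
case/control experiments) measure *how a drug shifts expression*, but do
not measure viability; viability screens (AAC, area above the
dose-response curve) measure response but not perturbation.  DrVAE ties
the two together in one probabilistic model:

    p(x1, x2, z1, z2, z3, y)
        = p(x1|z1) p(x2|z2) p(z2|z1) p(z1|z3,y) p(z3) p(y)

where `x1, x2` are pre-/post-treatment expression, `z1, z2` their shared
latent embeddings, `y` the binary response, and `z3` a class-independent
latent.  The drug's latent effect is a near-identity linear map
`E[z2|z1] = z1 + W z1 + b`; a linear softmax on `[z1, z2 - z1]` predicts
response.  Training maximizes the summed evidence lower bounds of four
data regimes (labeled/unlabeled x pairs/singletons) plus a weighted
classifier cross-entropy, with Adam on reparameterized single-sample
gradients.  The package also provides the model's ablations (SSVAE,
PertVAE, identity-perturbation), the preprocessing pipeline
(batch/bead-matched case-control pairing, correlation filtering, per-gene
standardization, first-PC removal, waterfall binarization of AAC, drug
selection), the grouped/stratified repeated cross-validation protocol
with AUROC/AUPR/Wilcoxon comparison and ERVR statistics, and a seeded
synthetic-data generator with known ground truth that makes the whole
system testable offline.

It is aimed at computational pharmacogenomics researchers who want a
transparent, dependency-light (numpy/autograd) reference implementation
to study, extend or benchmark against.

## Worked example

```python
import numpy as np
from drvae import (SyntheticConfig, generate, ModelConfig, fit, Batch,
                   predict_response_batch, predict_posttreatment,
                   set_identity_perturbation, auroc, rmse_pred)

# a small synthetic cohort: 10 perturbed cell lines (2 pairs each) and
# 100 viability-only cell lines with binary response labels
data = generate(SyntheticConfig(n_genes=30, latent_dim_true=3,
                                n_cell_lines_pairs=10, pairs_per_cell_line=2,
                                n_singletons=100, label_scale=6.0,
                                noise_sd_gene=0.2, decoder_gain=0.0, seed=42))
X, y = data.singles_x1, data.singles_labels
train_idx, test_idx = np.arange(70), np.arange(70, 100)

train = Batch.from_lists(
    pairs=[(p.x1, p.x2, p.y) for p in data.pairs],
    singletons=[(X[i], int(y[i])) for i in train_idx], n_genes=30)
val = Batch.from_lists(
    singletons=[(X[i], int(y[i])) for i in test_idx], n_genes=30)

config = ModelConfig(n_genes=30, latent_dim=3, z3_dim=3, enc_hidden=16,
                     aux_hidden=8, max_epochs=80, patience=20,
                     class_weight_grid=(1.0, 10.0), batch_size=128,
                     learning_rate=3e-3)
params, log = fit(train, val, config, seed=0)
print(f"selected class-loss weight: {log['selected_weight']}")

prob, _, _ = predict_response_batch(X[test_idx], params)
print(f"held-out AUROC: {auroc(prob, y[test_idx]):.3f}")

x1 = np.stack([p.x1 for p in data.pairs])
rmse = rmse_pred(predict_posttreatment(x1, params), data.truth.x2_clean_pairs)
rmse_id = rmse_pred(predict_posttreatment(x1, set_identity_perturbation(params)),
                    data.truth.x2_clean_pairs)
print(f"post-treatment RMSE: {rmse:.3f} (learned W,b) vs {rmse_id:.3f} (identity)")
```

Output:

```
selected class-loss weight: 10.0
held-out AUROC: 0.949
post-treatment RMSE: 0.311 (learned W,b) vs 0.313 (identity)
```

The classifier separates responders well (AUROC 0.949 on held-out cell
lines).  With only 20 perturbation pairs the learned perturbation barely
improves post-treatment prediction over the identity ablation — exactly
the data-limitation behavior the ERVR x sample-size analysis quantifies;
with ~1000 pairs at low noise the learned map cuts the RMSE to a fraction
of the identity baseline (see `tests/test_acceptance.py`).

A command-line interface mirrors the library:

```sh
drvae simulate --seed 3 --out-dir data/
drvae preprocess --expression data/expression.tsv \
    --pairs-manifest data/pairs.csv --sensitivity data/sensitivity.csv \
    --out-dir prep/
drvae train --expression data/expression.tsv --pairs-manifest data/pairs.csv \
    --seed 0 --out model.npz
drvae predict --model model.npz --expression data/expression.tsv --out pred.csv
drvae ablate-identity --model model.npz --out model_identity.npz
```

## Layout

- `src/drvae/gaussian.py` — diagonal-Gaussian primitives (density, KL,
  reparameterization, BCE)
- `src/drvae/models.py` — DrVAE, SSVAE, PertVAE, training, prediction,
  checkpoints
- `src/drvae/preprocess.py` — pairing, filtering, standardization,
  first-PC removal, waterfall labels, drug selection
- `src/drvae/evaluation.py` — splits, AUROC/AUPR, Wilcoxon, RMSE, ERVR
- `src/drvae/synthetic.py` — ground-truth generator and sweeps
- `docs/methods.md` — model, estimator and protocol details
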