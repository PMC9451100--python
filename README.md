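# toxmlpath

Multi-label prediction of drug-induced pathological findings — liver- and
kidney-style histopathology labels — from dose-response gene expression.

Toxicogenomic screens expose animals to a compound at several dose levels
and record both genome-wide expression and the pathological findings
(necrosis, hypertrophy, cellular infiltration, ...) observed by
histopathology. Predicting the *set* of findings a compound will induce is
a multi-label problem with strong label correlation and severe class
imbalance: a few findings are common, most are rare. `toxmlpath`
implements an end-to-end pipeline for this setting:

1. **Dose-response featurization.** For every (compound, gene) pair the
   expression values at the three dose levels (low/middle/high, coded
   d = 1, 2, 3) are fitted with a logistic dose-response curve
   r(d) = baseline + (R_max − baseline) / (1 + e^(−slope·(d − ec50))),
   and the maximal response **R_max** becomes the per-gene feature. Genes
   whose triples cannot form a curve (flat, non-monotone, poor fit) are
   filtered out.
2. **Improved MLSMOTE.** Multi-label SMOTE oversampling of minority
   findings — synthetic samples interpolated between bag neighbours, with
   labels assigned by neighbour majority vote — with a guard that prevents
   all-zero label vectors. Imbalance is tracked by per-label IRLbl and
   MeanIR.
3. **Att-RethinkNet.** A recurrent "rethinking" classifier: the input is
   fed to an LSTM (or simple recurrent) cell for T iterations, each
   iteration's hidden state decodes to a tentative label-score vector
   Ŷ⁽ᵗ⁾, and the recurrent memory carries tentative predictions forward so
   later iterations can exploit label correlations; Ŷ⁽ᵀ⁾ is the final
   prediction. A softmax attention block between input and recurrent layer
   learns per-gene importance weights. Training uses a cost-sensitive
   label-weighted binary cross-entropy (inverse-prevalence weights,
   normalised to mean 1). Implemented in pure numpy with hand-derived
   gradients (verified against numerical differentiation in the tests).
4. **Baselines.** Binary relevance (BR), classifier chains (CC) with
   injected scikit-learn base learners (logistic regression, random
   forest, linear SVM), and a per-label 5-nearest-neighbour model; plus a
   multi-label F-statistic gene ranking with an amplified fitness
   Fitness = α·ACC + (1 − α)·(D_total − λ·D_selected)/D_total (α = 0.6,
   λ = 10) for selecting compact gene subsets.
5. **Evaluation.** Subset accuracy (ACC), per-sample Jaccard (ACC_pair),
   per-label accuracy (ACC_lab), per-label confusion counts, macro
   ACC_avelab / SEN / SPE / F1, and micro-averaged ROC/AUC.
6. **Synthetic data.** A generator of study-shaped fixtures — per-compound
   expression at three dose levels with planted sigmoid responses,
   correlated imbalanced 20-dimensional finding vectors — so the whole
   pipeline runs and is tested without any external database.

## Worked example

```python
import numpy as np
from toxmlpath import (SyntheticConfig, simulate_dataset, dataset_from_expression,
                       PipelineConfig, RethinkConfig, MlsmoteConfig, run_crossval)

records, labels, compounds, names, truth = simulate_dataset(SyntheticConfig(seed=1))
ds = dataset_from_expression(records, labels, compounds, names)
print(f"{ds.n} compounds x {ds.dim} curve-forming genes, {ds.L} findings")

res = run_crossval(ds, PipelineConfig(seed=1, folds=5, augment_mode="leak_free"),
                   RethinkConfig(seed=1), MlsmoteConfig(seed=1))
agg = {k: round(v, 3) for k, v in res.aggregate.items() if k != "acc_lab"}
print(agg)
```

prints (exact numbers depend only on the seed):

```
200 compounds x 12 curve-forming genes, 20 findings
{'acc': 0.15, 'acc_pair': 0.539, 'acc_avelab': 0.896, 'sen': 0.469,
 'spe': 0.961, 'f1': 0.504, 'auc': 0.868}
```

Of 120 simulated genes, exactly the 12 with a planted dose response
survive the curve filter. Subset accuracy (`acc`, every one of the 20
labels correct simultaneously) is strict by construction; `acc_pair`
(partial credit via Jaccard overlap) and the per-label average
(`acc_avelab` ≈ 0.90) show most individual findings are predicted well,
and the micro-AUC of ≈ 0.87 summarises ranking quality over all
(sample, label) decisions. Eight of the twenty simulated findings carry no
marker gene, which caps attainable subset accuracy — see
`docs/methods.md`.

The `examples/` directory holds one short script per capability
(dose-response fitting, oversampling, feature selection, model training,
baselines, the full pipeline). A thin CLI mirrors the stages:
`toxmlpath simulate | fit-dose | augment | select-features | baseline |
train | predict | crossval | holdout`.

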