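# mmsurv

Hierarchical cross-attention fusion of multimodal clinical feature streams
for recurrence-risk prediction with right-censored outcomes.

## The problem

Estimating long-term recurrence risk in HR+/HER2− early breast cancer from
data that clinics already collect: digitized pathology slides, grayscale
ultrasound images and their diagnostic reports, and structured
clinicopathologic variables. Each modality arrives as pre-extracted numeric
feature streams — patch-level deep features plus morphological and
topological summaries for pathology; image tokens, radiomics and a report
embedding for ultrasound — and the outcome is right-censored recurrence-free
survival in months.

`mmsurv` provides:

* a **fusion network** that combines the streams hierarchically —
  cross-attention within each imaging modality (query stream attending to the
  other feature types, residual-summed and pooled), a configurable
  intermodality combination of the pathology and ultrasound vectors, and a
  final cross-attention over per-variable clinical tokens with a residual
  connection — ending in a scalar log-relative-hazard
  `r = affine(f_final)`;
* **Cox partial-likelihood training** (Breslow ties):
  `L(r) = −Σ_{i:δᵢ=1}[rᵢ − log Σ_{tⱼ≥tᵢ} e^{rⱼ}]`, Adam with weight decay
  4×10⁻⁶, dropout 0.2 in the intermodal stage, single attention head;
* **missing-modality compensation**: a zero-initialized learnable embedding
  substituted for an absent modality's fused input, selected by the
  availability mask and trained end-to-end;
* a **survival metric suite** — Harrell's C, IPCW time-dependent AUC, Brier
  score and calibration with a Breslow baseline, Kaplan–Meier, log-rank,
  univariate hazard ratios, bootstrap CIs, decision-curve analysis, quantile
  risk stratification;
* a **synthetic cohort generator** with planted proportional-hazards risk,
  calibrated censoring (16.2% event rate by default) and configurable
  per-modality signal and missingness, so everything is testable without
  clinical data.

Since the network is trained on small tabular feature bundles, the whole
stack runs on plain numpy (float64) with a minimal reverse-mode autodiff
engine included in the package; no GPU framework is required.

## Worked example

```python
import numpy as np
from mmsurv import CohortSimConfig, FusionConfig, TrainConfig, SplitSpec
from mmsurv import simulate_cohort, split_cohort, train_model, cohort_to_batch
from mmsurv.metrics import evaluate_risk_scores

sim = CohortSimConfig(
    n_patients=720,
    signal_weights={"pathology": 2.0, "ultrasound": 0.5, "clinical": 0.5},
    baseline_hazard=0.001,   # ~115 months of calibrated follow-up
    seed=0,
)
cohort, truth = simulate_cohort(sim)
train, test = split_cohort(cohort, SplitSpec(seed=0))   # 600 / 120, stratified

model, history = train_model(
    train,
    FusionConfig(embed_dim=64, dropout=0.2),
    TrainConfig(learning_rate=2e-3, max_epochs=60, seed=0),
    sim.clinical_schema,
)

tb_tr, tb_te = cohort_to_batch(train, sim.clinical_schema), cohort_to_batch(test, sim.clinical_schema)
report = evaluate_risk_scores(
    model.predict_risk(tb_tr), tb_tr["time"], tb_tr["event"],
    model.predict_risk(tb_te), tb_te["time"], tb_te["event"],
    horizons=(36, 60, 84),
)
print(f"held-out C-index  {report.c_index:.3f}")
for h, a in report.td_auc.items():
    print(f"td-AUC @ {h:>4.0f} mo   {a:.3f}")
print(f"HR high vs low    {report.hazard_ratio.hazard_ratio:.2f}")
```

Output:

```
held-out C-index  0.870
td-AUC @   36 mo   0.858
td-AUC @   60 mo   0.864
td-AUC @   84 mo   0.915
HR high vs low    7.36
```

The C-index is the probability that, of two comparable test patients, the one
with the higher predicted risk relapses first (0.5 = random); the
time-dependent AUCs measure discrimination of events by 3/5/7 years; the
hazard ratio compares test patients above vs below the training-risk median.
Here the model nearly reaches the cohort's true-risk ceiling (the planted
log-hazard scores a C-index of 0.894 on the same split).

## Command line

```bash
mmsurv simulate --config config.yaml --out cohort/
mmsurv train    --config config.yaml --cohort cohort/ --out run/
mmsurv evaluate --checkpoint run/checkpoint.npz --cohort cohort/ --out eval/ --horizons 36,60,84
mmsurv ablate   --config config.yaml --cohort cohort/ --grid grid.yaml --out ablation/
```

Each command writes a `manifest.json` (config snapshot, seeds, paths) that
suffices to reproduce the run.

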