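# Methods

## Model

`mmsurv` implements a hierarchical cross-attention fusion network that maps a
patient's multimodal feature bundle to a scalar log-relative-hazard, trained
end-to-end with the Cox partial-likelihood objective. The setting it targets
is recurrence-risk prediction in HR+/HER2− early breast cancer from routinely
collected data: pre-extracted pathology whole-slide features (patch-level deep
features plus patient-level morphological and topological summaries),
ultrasound features (image deep-feature tokens, radiomics, report-text
embedding), and structured clinicopathologic variables. Raw image/text
processing and pretrained encoders are out of scope; the package consumes
numeric token matrices.

The network has three stages:

1. **Intramodality fusion.** Within pathology, the query stream (patch-level
   deep features by default) attends separately to the topological and
   morphological streams with scaled dot-product cross-attention
   (`softmax(QW_q(KW_k)ᵀ/√d)·VW_v·W_o`, single head by default); the two
   attention outputs are element-wise summed with the query tokens and the
   result is pooled (mean by default, attention pooling optional) into
   `f_path`. Ultrasound is fused symmetrically into `f_us`. The residual sum
   is applied at token level before pooling; under mean pooling with equal
   token counts this equals the pooled-level formulation while preserving
   per-token structure for attention export. Query assignment is
   configurable (`wsi_query` ∈ {deep, morph, top}; `us_query` ∈ {deep, omic,
   text}) to support query-reassignment ablations.
2. **Intermodality fusion.** `f_path` and `f_us` are combined into `f_inter`
   by one of four strategies: bidirectional single-token cross-attention
   (default; the two directed attention outputs are summed), affine-aligned
   concatenation, element-wise addition, or multiplication. Dropout
   (default 0.2) is applied here, and only here, during training. Note that
   with single-token inputs the softmax over one key is identically 1, so
   the cross-attention strategy is algebraically an additive combination
   through learned maps; it differs from `add` in parameterization, not in
   interaction order.
3. **Clinical residual fusion.** The clinical encoder produces one
   1024-dimensional token per variable (configurable width; learnable affine
   map for continuous variables, learnable lookup table for categorical
   ones; Ki67 is a low/high band by default, schema-configurable).
   `f_inter` serves as a single query over the clinical tokens and the
   attention output is added back: `f_final = f_inter + CA(f_inter,
   clinical)`. The recorded attention weights double as a variable-importance
   ranking. The risk head is a single affine map to a scalar with no final
   nonlinearity (log-relative-hazard convention).

Clinical tokens are kept separate (not pooled) before serving as key–value
pairs; this is what makes attention-based variable ranking possible. One
cross-attention layer per stage is used; stacking depth is configurable in
principle but deliberately minimal, consistent with the single-head choice.

**Missing modalities.** Each imaging modality carries a binary availability
mask. With compensation enabled, an unavailable modality's fused vector is
replaced by a learnable embedding, initialized to zeros and shaped like the
fused representation; the replacement is a convex blend `a·f + (1−a)·e`, so
the embedding receives gradient exactly from patients missing that modality
and is trained jointly with everything else. With compensation disabled the
missing contribution is zeroed. The clinical modality is assumed always
available. For the *ignore* baseline of the compensation comparison we use a
model without the modality altogether (see "Compensation comparison" below).

## Training

Negative log Cox partial likelihood, Breslow convention for ties:
`L(r) = −Σ_{i:δᵢ=1}[rᵢ − log Σ_{tⱼ≥tᵢ} exp(rⱼ)]`. The public `cox_loss`
returns this sum (0 with no events); the trainer minimizes the per-event
mean of the same quantity so the gradient scale is independent of cohort
size. Optimization is Adam with weight decay 4e-6 (classic L2-in-gradient
form); the library default learning rate is 1e-4, and the canned desk-scale
experiments use 2e-3 with 60 full-cohort epochs, which reaches a stable
held-out plateau for the small models they train. Full-cohort risk sets are
the default; a `large_batch` mode deals events round-robin into batches and
computes the partial likelihood within each batch (a documented
approximation for cohorts too large for one risk set). Early stopping on
validation C-index with configurable patience is available and off by
default; every run is reproducible from its seed. All computation is
float64 numpy via a small reverse-mode autodiff engine written for this
package (`mmsurv.autodiff`); gradients are verified against central finite
differences in the test suite.

Splits are event-stratified: train size is `round(fraction·n)` with
largest-remainder allocation across the event/censored strata, so each
part's event fraction is within one patient of proportional (768 patients at
5:1 give exactly 640/128). Repeated stratified k-fold CV deals events
round-robin across folds and re-draws (bounded) if a fold ends up eventless.

## Synthetic cohorts

The generator emulates the *structure* of a multimodal breast-cancer cohort
at the feature level; it makes no claim about the distribution of real
extracted features, which the source setting does not publish.

* Each modality m ∈ {pathology, ultrasound, clinical} has a latent factor
  vector `f_m ~ N(0, I_k)` per patient (k = 4 by default); its unit-scaled
  score `s_m = Σf_m/√k` contributes `w_m·s_m` to the true log-hazard `z`.
  Default weights are pathology 1.0, ultrasound 0.4, clinical 0.4 —
  pathology-dominant with auxiliary imaging/clinical signal, mirroring the
  relative modality contributions seen in this application area.
* Event times are exponential given z: `T = −log(U)/(h₀·e^z)` with
  `h₀ = 0.002`/month, chosen so follow-up spans a realistic 10–15-year
  scale. Censoring is uniform on (0, a); the administrative cutoff `a` is
  calibrated by bisection on the closed-form event-probability integral
  (Gauss–Hermite over z) so the expected event fraction hits the target,
  default 16.2% — the event rate typical of HR+/HER2− cohorts over ~10
  years. Constant baseline hazard buys exact sampling and analytic
  calibration; it also yields the proportional-hazards check that doubling
  h₀ halves the median event time.
* Stream s of modality m emits tokens `μ_s + A_s f_m + ε`, with a fixed
  seeded mixing map `A_s` (so each stream is informative of exactly one
  modality), a fixed seeded mean offset `μ_s` (sd 1.0), and i.i.d. noise
  (sd 0.5 by default). The nonzero offsets reflect that real deep-feature
  and radiomics vectors are not centered at zero — consequently
  zero-imputing a missing modality lands off the feature manifold, as it
  would on real data. Token counts default to 32 WSI patches and 16
  ultrasound tokens with stream widths 32–64: feature-level emulation does
  not need the raw-scale geometry (thousands of patches, 1024-d encoder
  outputs) to exercise the architecture.
* Continuous clinical variables are noisy copies of the clinical score
  mapped to plausible scales (age, tumor size); categorical ones are
  equiprobable quantile bins of an independent noisy copy.
* Missingness is injected independently per patient and modality at
  configurable rates; stream content is retained and only flagged.

What passing tests on this generator do show: the architecture can recover a
planted multimodal proportional-hazards signal, attributes it to the correct
modality under ablation, and the metric stack is numerically correct. What
they do not show: performance on real images/text, robustness to
non-linear feature–risk relationships, inter-scanner variation, or informative
censoring — none of which the linear-factor emulation represents.

## Canned experiments and problem sizes

`mmsurv.experiments` pins the package's standard study conditions
(single-CPU scale; sizes chosen once and shared by the test suite and the
reproduction script):

* **Parameter recovery** — 720 patients (600/120 stratified split), strong
  pathology-dominant weights (2.0/0.5/0.5; the true-risk C ceiling of this
  condition is ≈0.88, measured by the ranking oracle at n = 4000),
  embed_dim 64. Reports held-out C-index and Spearman correlation between
  predicted risk and planted log-risk.
* **Modality ablation** — 432 patients, embed_dim 32; C-index of the full
  model and each single-modality-removed model on a shared split.
* **Compensation comparison** — same cohort scale, 30% missing pathology
  (shared mask across arms): fully observed model, learnable compensation,
  the ignore-pathology baseline, and a zero-substitution variant.

**Compensation comparison, baseline choice.** The classical baseline that
"ignores" an unavailable modality is a model that does not use it at all;
the compensated model should land between that baseline and the fully
observed model. A subtler variant — zeroing the missing patients' fused
input inside the full architecture — is also reported. On this generator
the zero vector acts as a learnable missing-indicator that downstream layers
can process, so the zero-substitution variant tracks the compensated model
closely (differences within seed noise); the decisive gap is against the
no-modality baseline. Both numbers are emitted so the distinction stays
visible.

## Numerical choices

* float64 throughout; attention softmax is max-shifted; the Cox loss
  denominator is computed with a global max shift.
* Risk-set mask built as an explicit (events × n) matrix — fine for
  desk-scale cohorts, quadratic in memory by design honesty.
* Harrell's C is the headline discrimination number (risk ties count 1/2);
  IPCW weighting is used only inside the cumulative/dynamic td-AUC and the
  Brier score. Risk-to-probability conversion uses the Breslow baseline
  estimated on training data only.
* The univariate hazard ratio is fitted by Newton iteration on the Breslow
  partial likelihood with steps clipped to ±2; monotone likelihood (no
  events in a group, or |β| > 20) is flagged and the Wald CI reported as
  unbounded.
* Decision curves use the Kaplan–Meier-within-positives net benefit, which
  reduces to the classification formula `TP/n − FP/n · p/(1−p)` without
  censoring. Log-rank is two-sided, chi-square with 1 df, no continuity
  correction.
* Bootstrap CIs are percentile CIs over patient-level resamples; resamples
  on which the metric is undefined are redrawn (bounded); a constant metric
  yields a zero-width CI with cv = 0.
* Quantile cutoffs use linear-interpolation quantiles of the training risks;
  test values equal to a cutoff go to the upper group.
* Degenerate inputs raise: empty cohorts, no comparable pairs, horizons
  beyond follow-up, all-equal training risks, out-of-vocabulary categorical
  codes (named in the error).

## Known limitations

* No competing risks, no multivariable adjusted Cox models, no
  restricted-mean survival.
* `large_batch` Cox training is an approximation to the full-cohort partial
  likelihood.
* The synthetic generator's linear-Gaussian feature model cannot probe
  encoder quality, nonlinear feature interactions, or calibration drift
  between scanners/sites.
* Multi-head attention is supported but the package's reference
  configuration is single-head; head counts must divide the embedding width.
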