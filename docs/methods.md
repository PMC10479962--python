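# Methods

## Overview

`omicsimage` integrates gene-level multi-omics data by rasterizing a cohort
into multi-channel *genome images* (one pixel per gene, one channel per
omics source), fitting a convolutional encoder/decoder/extractor network
against an outcome, and attributing the trained model's predictions back to
individual genes and data sources with Integrated Gradients (IG). This note
records the model, its assumptions, the parameters that matter, the design
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Gene-level summarization

* **Mutation.** Each gene/sample cell holds the *maximum* PolyPhen score
  over that sample's mutations in the gene (0 when unmutated).
  Most-damaging-event semantics: a single deleterious hit should not be
  diluted by benign passengers in the same gene.
* **Expression.** TPM (or any per-gene quantification), aligned to the gene
  catalog; unmeasured genes sit at 0, which after scaling is the source's
  minimum ("no signal") rather than an imputation.
* **Methylation.** Arithmetic mean beta value of the probes mapped to each
  gene.
* **Copy number.** Segments are converted to
  `logR = log2(total_cn / ploidy)`; `total_cn = 0` maps to −∞ and is always
  a deletion. A gene is called **amplified** only when its entire interval
  (1-based, inclusive coordinates) lies inside a single segment with
  `logR > log2(5/2)`, and **deleted** when it overlaps any segment with
  `logR < log2(0.5/2) = −2` by at least one base. The asymmetry is
  intentional: high-level amplification acts through complete extra copies,
  whereas partial deletion suffices to disrupt a gene. Adjacent same-state
  segments are *not* merged before the containment test; a gene straddling
  two abutting amplified segments is therefore not called amplified. This
  is a documented edge-case choice, conservative in the direction of fewer
  gain calls.
* **Scaling.** Every channel is min–max scaled to [0, 1] over the whole
  cohort jointly (one scaler per data source). A constant channel maps to
  all zeros, keeping the [0, 1] contract without 0/0. Cohort-wide fitting
  mirrors common practice for unsupervised rescaling but does leak range
  information across the holdout split; `minmax_scale(fit_samples=...)`
  fits on the training split only and clips the holdout, for users who
  prefer strict separation (off by default).
* **wGII.** Per autosome with segment coverage: the fraction of segmented
  length whose *rounded* total copy number differs from the *rounded*
  sample ploidy; wGII is the unweighted mean of these fractions, so each
  autosome contributes equally regardless of physical size. X is excluded.
  Using segmented length as the denominator keeps the index well defined on
  partially covered chromosomes, and the index is invariant to subdividing
  a segment at constant copy number.

## Image layouts

Four layouts share one invertible gene↔pixel contract (injective mapping,
padding pixels exactly 0, excluded from attribution):

* `square` — genes sorted by (chromosome rank, start, gene id) fill the
  grid row-major. Chromosome rank follows the Hi-C interaction ordering
  4, X, 7, 2, 5, 6, 13, 3, 8, 9, 18, 12, 1, 10, 11, 14, 22, 19, 17, 20, 16,
  15, 21, so chromosomes adjacent in 3-D nuclear space are adjacent on the
  image. Published mode fixes 198×198; auto mode uses side = ceil(√n_genes)
  and restricts the ordering to the chromosomes present.
* `chromosome_rows` — one chromosome per row; published mode is 24×3760 (3760
  = the most gene-rich chromosome; with 23 mapped chromosomes the 24th row
  is padding).
* `square_shuffled`, `flat` — seeded random orderings used as
  spatial-structure controls.

Layouts serialize to JSON and carry a content hash; checkpoints record the
hash, and attribution refuses to run a model against a different layout.

## Network

Four stages (all widths configurable):

1. **Encoder** — 3×3 stride-2 convolution blocks (default widths
   8/16/32/64, batch-norm + leaky-ReLU), then a dense layer to the latent
   vector **L** (default 128).
2. **Decoder** — dense layer from L back to the encoder's final feature
   map, then mirrored 3×3 transposed convolutions that invert each
   encoder size exactly. **The reconstruction is not penalized**: no term
   in the objective compares it to the input, so the network redraws the
   genome however best serves the prediction.
3. **Extractor** — 3×3 stride-1 convolution + 2×2 max-pool blocks (default
   8/16/32) applied to the reconstruction.
4. **Head** — extracted features flattened and concatenated with L (the
   model sees the genome both before and after redrawing), then dense
   layers (default hidden 64) to a 2-unit softmax (binary; cross entropy),
   k-unit softmax (multiclass), or a linear unit (regression; MSE — an
   unconstrained output rather than a squashing activation, since outcomes
   such as wGII are not bounded away from their range edges).

Transposed convolutions are implemented as the exact adjoint of strided
convolution with the target output size given explicitly, so odd input
sizes (198, flat 1×W vectors) invert without output-padding bookkeeping;
pooling degenerates to 1-D on flat layouts. The whole stack — including the
reverse-mode gradients that IG differentiates and the Adagrad optimizer —
is implemented in numpy in `omicsimage.autodiff`; every layer's analytic
gradient is verified against central finite differences in the test suite.

Default encoder/extractor widths are sized for desk-scale cohorts (a few
hundred samples, ~10³ genes): at four times these widths the network
memorizes a 300-sample training split before the planted signal is learned
(validation AUC stays near chance), while the narrower stack generalizes.
The four-stage structure, the latent length 128, and the twice-used latent
are the architectural contract; widths are capacity knobs.

## Training

`TrainConfig()` defaults document the published recipe: Adagrad, starting
learning rate 9.9e−5, learning-rate decay and weight decay 1e−6, batch size
256, a single stratified 75/25 holdout, and patience-based early stopping
(default 10 epochs) with best-validation-loss weights restored. That
learning rate was tuned for a ~2300-sample cohort trained for hours; at a
few hundred samples and a minutes-scale step budget it moves validation AUC
by ~0.01 per 50 epochs. `TrainConfig.desk_scale()` is the package's
scaled-down training condition: starting learning rate 1e−2, at most 80
epochs, patience 20 (long enough to ride out the flat early phase that
small cohorts show before the loss drops). Batch size is automatically
reduced to the training-split size when smaller than one batch. Loss is
computed in `training.head_loss`, whose only inputs are logits and labels —
the code-level guarantee that no reconstruction term enters the objective.

Metrics: ROC AUC (binary), macro-averaged F1 (multiclass; macro chosen so
minority classes weigh equally), RMSE (regression). Latent vectors can be
embedded to 2-D with UMAP for visual diagnostics of whether the model
separates the outcome.

## Integrated Gradients

Right-endpoint Riemann approximation with m = 50 steps by default:
`A = (x − x′) ⊙ (1/m) Σ_{k=1..m} ∇F(x′ + (k/m)(x − x′))`. The baseline x′
is the all-zeros image — semantically "every source at its minimum", since
channels are min–max scaled. F is the logit of the attributed class (each
sample's true class for classification; the scalar output for regression).
The per-sample completeness gap `|ΣA − (F(x) − F(x′))|` is returned with
every attribution and reported by the pipeline; it is exactly zero for
linear models at any m and shrinks as 1/m otherwise.

Downstream: pixel attributions map back through the layout (padding
dropped), are min–max scaled within each sample group (e.g. cancer type)
jointly across channels — preserving relative channel magnitudes within a
group; a per-channel switch exists — then averaged over samples. Gene
rankings combine selected channels by sum (default) or max, ties broken by
gene id; channel importance is the per-group mean scaled attribution with
shares normalized to 1. A helper filter retains genes whose expression and
methylation correlate significantly negatively (Pearson,
Benjamini–Hochberg at α), the standard screen for methylation-driven
silencing before combining those two channels.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes of a
real cohort, not its marginal distributions. Default preset: 400 samples,
1024 genes on 16 chromosomes (a 32×32 auto-square image), binary label at
π = 0.5, 20 signal genes per channel drawn independently per channel,
expression shift 2 SD in cases, methylation beta-mean shift 0.3
(beta-distributed values, concentration 30), mutation rate 0.02 baseline
vs 5× in cases with damaging PolyPhen scores ~ U(0.5, 1), and per
chromosome a 0.4 probability of one copy-number event per sample (total
copy number drawn from {0, 1, 3, 5, 6} at ploidy 2). wGII computed from the
generated segments is the continuous target. Chosen once as a plausible
desk-scale caricature of a cancer cohort: effect sizes at the optimistic
end of real bulk data, CPU-minutes training.

What the generator does **not** emulate: realistic expression/methylation
marginals, batch effects, purity contamination, linkage between channels
(events are drawn independently), or correlation between copy-number events
and outcome. Passing tests therefore demonstrate that the machinery —
transformation, optimization, attribution — behaves correctly when signal
exists, not that the pipeline will reach comparable performance on real
tumors.

## Known limitations

* **Partial recovery of redundant planted signal.** With ~60 planted genes
  (20 per channel) each individually informative, the classifier reaches
  validation AUC 0.95–0.98 while *using only a subset of them* — nothing
  pushes a converged discriminative model to consult all redundant
  features. IG faithfully reports the genes the model uses, so about a
  quarter of the planted union appears in the top-50 ranking (methylation
  genes recover best; their per-gene effect is largest relative to noise).
  This is a property of discriminative training on redundant signal, not an
  attribution failure: the completeness and linear-exactness axioms hold to
  numerical precision. Users ranking genes on real data should expect the
  list to be a *sufficient* predictive set, not an exhaustive one.
* **wGII regression on synthetic data is near-uninformative.** The
  generator draws copy-number events independently of every other channel,
  and events at total copy number 1 or 3 (ploidy 2) — the majority — fall
  inside the gain/loss call thresholds and are invisible in the image. A
  linear probe on the raw pixels does no better than predicting the cohort
  mean, so the network cannot either; the pipeline reports the honest RMSE
  next to the cohort SD. Real tumors violate both independences, which is
  why the task is meaningful there.
* Min–max scaling is outlier-sensitive by construction; a single extreme
  value compresses the rest of its channel.
* The early-stopping criterion (validation loss) can latch onto a transient
  dip in small-cohort regression runs; the regression preset therefore uses
  a longer patience.
* No learning-rate schedule beyond Adagrad's internal decay; no multi-GPU
  or mini-batch-free paths; layouts are fixed, not learned.
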