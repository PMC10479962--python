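# omicsimage

Deep-learning analysis of integrated multi-omics cancer data via **genome
images**: every gene becomes one pixel, every omics source one image
channel, and a convolutional network trained against a clinical outcome is
interrogated with **Integrated Gradients** to rank the genes (and data
sources) driving its predictions.

## Who this is for

Computational cancer-genomics groups who have gene-level multi-omics tables
for a cohort — mutation calls with PolyPhen damage scores, expression (TPM),
per-gene methylation beta values, and ASCAT-style copy-number segments with
ploidy — plus an outcome of interest (metastasis, subtype, chromosomal
instability), and who want a single integrated model whose feature
attributions are interpretable at the gene level, instead of thousands of
independent univariate tests.

## The method

1. **Gene-level channels.** Each source is summarized per gene and sample:
   max PolyPhen score per gene; TPM; mean methylation beta; and binary
   copy-number gain/loss calls from segment log ratios
   `logR = log2(total_cn / ploidy)` — a gene is *amplified* when it lies
   entirely inside a segment with `logR > log2(5/2)` and *deleted* when it
   overlaps any segment with `logR < log2(0.5/2)`. Every channel is min–max
   scaled to [0, 1]. The weighted genome integrity index (wGII) — the mean
   over autosomes of the fraction of segmented length at a rounded copy
   number different from rounded ploidy — is computed as a continuous
   chromosomal-instability outcome.
2. **Genome image.** Genes are mapped bijectively to pixels. The default
   square layout orders genes by chromosome and position, with chromosomes
   arranged by their Hi-C interaction ordering
   (4, X, 7, 2, 5, 6, 13, 3, 8, 9, 18, 12, 1, 10, 11, 14, 22, 19, 17, 20,
   16, 15, 21); published dimensions (198×198 square, 24×3760
   chromosome-rows) are available as `mode="published"`, and shuffled / flat
   layouts serve as spatial-structure controls. The transform is exactly
   invertible, so pixel attributions map back to genes.
3. **Network.** A four-stage architecture: a strided-convolution encoder
   compresses the image to a latent vector **L** (length 128); a
   transposed-convolution decoder redraws the image from L *without any
   reconstruction loss*; a convolution+max-pool extractor mines the redrawn
   image; and a dense head sees the extracted features concatenated with L.
   Heads: 2-unit softmax (binary), k-unit softmax (multiclass), or linear
   (regression). Training uses Adagrad with holdout validation (75/25) and
   patience-based early stopping on validation loss.
4. **Attribution.** Integrated Gradients, implemented from first principles:
   `A_i = (x_i − x'_i) · (1/m) Σ_k ∂F/∂x_i` along the straight path from an
   all-zeros baseline, with the completeness gap `|ΣA − (F(x) − F(x'))|`
   reported as a diagnostic. Attributions are min–max scaled within sample
   groups (e.g. cancer types), averaged, and ranked per gene and channel.

The network, its gradients, and the optimizer are implemented in numpy
within this package (`omicsimage.autodiff`); no deep-learning framework is
required.

## Worked example

A fully synthetic cohort with known ("planted") signal genes exercises the
entire pipeline — no data download needed:

```bash
omicsimage simulate  --workdir run --config examples/config.yaml
omicsimage transform --workdir run --config examples/config.yaml
omicsimage train     --workdir run --config examples/config.yaml
omicsimage attribute --workdir run --config examples/config.yaml
omicsimage report    --workdir run --config examples/config.yaml
```

With the bundled example configuration (48 samples, 64 genes, 6 signal
genes with a 3-SD expression shift) the report prints:

```
pipeline report
===============
validation auc: 0.8857 (best epoch 5, max epochs)
integrated-gradients completeness |sum(A) - (F(x)-F(baseline))|: median 0.06064, max 0.1977 at 32 steps
top genes: G00002, G00009, G00006, G00011, G00038, G00030, G00024, G00018, G00031, G00026
planted-gene recovery at top-10: 0.500
```

Reading: on the 12-sample holdout the classifier separates cases from
controls with AUC 0.886; the Integrated-Gradients completeness gap is small
relative to the logit differences (the attribution is a near-exact
decomposition of the prediction); and 5 of the 10 top-ranked genes are
genuinely planted signal genes.
The same pipeline runs on real cohorts by placing your own
`genes.bed`, `expression.tsv`, `methylation.tsv`, `mutations.tsv`,
`segments.tsv`, and `samples.tsv` under `run/data/` (formats in
`omicsimage.omics_ingest`).

Library use mirrors the commands:

```python
from omicsimage.synthetic_data import SyntheticConfig, generate_cohort
from omicsimage.pipeline import cohort_image, train_on_images, attribute_run
from omicsimage.attribution import rank_genes
from omicsimage.training import TrainConfig

cohort = generate_cohort(SyntheticConfig(seed=1))     # 400 samples, 1024 genes
image = cohort_image(cohort)                          # (400, 5, 32, 32)
run = train_on_images(image, cohort.labels, task="binary",
                      train_config=TrainConfig.desk_scale(seed=1), seed=1)
result, gaps = attribute_run(run, image, cohort.labels, cohort.genes.gene_ids)
top = rank_genes(result, k=50)
```

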