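# Miniature end-to-end example: a synthetic cohort small enough to run in
# under a minute on one CPU. Scale n_samples/n_genes up for real use.
simulate:
  n_samples: 48
  n_genes: 64
  n_chromosomes: 8
  n_signal_genes: 6
  delta_expression: 3.0
  seed: 11
layout:
  kind: square
  mode: auto
  seed: 0
train:
  lr: 0.02
  batch_size: 16
  max_epochs: 6
  patience: 6
  seed: 0
model:
  encoder_widths: [4, 8]
  extractor_widths: [4]
  head_hidden: 8
  latent_dim: 16
attribution:
  steps: 32
  top_k: 10
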