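"""End-to-end orchestration: cohort -> scaled channels -> image -> trained
model -> gene attributions.

Thin glue over the library modules so the command-line interface, the test
suite, and reproduction scripts all run the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from omicsimage.attribution import (
    AttributionResult,
    IGConfig,
    attributions_to_genes,
    integrated_gradients,
    scale_by_group,
)
from omicsimage.genome_image import GenomeImage, LayoutSpec, build_layout, image_from_table
from omicsimage.network import GenomeNet, ModelConfig, build_model
from omicsimage.omics_ingest import call_cn_channels, minmax_scale
from omicsimage.synthetic_data import SyntheticCohort
from omicsimage.training import (
    TrainConfig,
    TrainHistory,
    evaluate,
    logits_to_predictions,
    predict_logits,
    split_cohort,
    train_model,
)
from omicsimage.types import CHANNEL_ORDER, ChannelMatrix, CnThresholds, GeneAnnotation


def scaled_channels(
    raw_channels: Mapping[str, ChannelMatrix],
    fit_samples: Sequence[str] | None = None,
) -> list[ChannelMatrix]:
    """Min-max scale every channel that is not already scaled (binary
    copy-number channels pass through)."""
    out = []
    for name in CHANNEL_ORDER:
        if name not in raw_channels:
            continue
        cm = raw_channels[name]
        out.append(cm if cm.scaled else minmax_scale(cm, fit_samples=fit_samples))
    return out


def cohort_image(
    cohort: SyntheticCohort,
    layout_kind: str = "square",
    layout_mode: str = "auto",
    layout_seed: int | None = 0,
) -> GenomeImage:
    """Build the five-channel genome image of a synthetic cohort."""
    gain, loss = call_cn_channels(
        cohort.segments, cohort.profiles, cohort.genes, CnThresholds(), cohort.sample_ids
    )
    channels = dict(cohort.channels)
    channels["cn_gain"] = gain
    channels["cn_loss"] = loss
    layout = build_layout(cohort.genes, kind=layout_kind, mode=layout_mode, seed=layout_seed)
    return image_from_table(scaled_channels(channels), layout)


@dataclass
class TrainedRun:
    model: GenomeNet
    history: TrainHistory
    train_idx: np.ndarray
    val_idx: np.ndarray
    val_metric: float
    task: str


def train_on_images(
    image: GenomeImage,
    labels: np.ndarray,
    task: str = "binary",
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    seed: int = 0,
) -> TrainedRun:
    """Split 75/25, train with Adagrad + early stopping, report the
    validation metric (AUC / macro-F1 / RMSE by task)."""
    train_config = train_config or TrainConfig(seed=seed)
    labels = np.asarray(labels)
    n, c, h, w = image.values.shape
    if model_config is None:
        n_classes = int(labels.max()) + 1 if task == "multiclass" else 2
        model_config = ModelConfig(
            image_height=h, image_width=w, image_channels=c,
            head=task if task != "binary" else "binary",
            n_classes=n_classes,
        )
    model = build_model(model_config, seed=seed)

    idx = np.arange(n)
    stratify = task != "regression"
    tr, va = split_cohort(
        [str(i) for i in idx],
        labels if stratify else None,
        train_config.holdout_fraction,
        stratify=stratify,
        seed=train_config.seed,
    )
    tr_idx = np.array([int(i) for i in tr])
    va_idx = np.array([int(i) for i in va])

    model, history = train_model(
        model,
        image.values[tr_idx],
        labels[tr_idx],
        task,
        train_config,
        val_images=image.values[va_idx],
        val_labels=labels[va_idx],
    )
    val_logits = predict_logits(model, image.values[va_idx], batch=train_config.batch_size)
    metric = evaluate(logits_to_predictions(val_logits, task), labels[va_idx], task)
    return TrainedRun(model, history, tr_idx, va_idx, metric, task)


def attribute_run(
    run: TrainedRun,
    image: GenomeImage,
    labels: np.ndarray,
    gene_ids: Sequence[str],
    group_ids: Sequence[str] | None = None,
    ig_config: IGConfig | None = None,
) -> tuple[AttributionResult, np.ndarray]:
    """Integrated Gradients over all samples, mapped to genes and group
    scaled.  Classification targets are each sample's true class; for
    regression the scalar output is attributed directly.  Returns the
    scaled result and the per-sample completeness gaps."""
    labels = np.asarray(labels)
    target = None if run.task == "regression" else labels.astype(int)
    attr, gaps = integrated_gradients(run.model, image.values, ig_config, target=target)
    result = attributions_to_genes(
        attr, image.layout, image.sample_ids, image.channel_names, list(gene_ids)
    )
    groups = list(group_ids) if group_ids is not None else ["all"] * len(image.sample_ids)
    return scale_by_group(result, groups), gaps
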