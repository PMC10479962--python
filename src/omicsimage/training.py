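"""Holdout training with Adagrad and early stopping, metrics, and latent
embedding.

The objective is the head loss only — cross entropy for binary/multiclass
softmax heads, mean squared error for regression.  The reconstruction
produced by the decoder never enters the loss; :func:`head_loss` is the
single place the training loss is computed, and it sees nothing but logits
and labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import train_test_split

from omicsimage.autodiff import Adagrad, mse_loss, softmax, softmax_cross_entropy
from omicsimage.network import GenomeNet


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The defaults follow the published training recipe: Adagrad with a
    starting learning rate of 9.9e-05, learning-rate decay and weight decay
    of 1e-6, batch size 256, and patience-based early stopping on the
    validation loss of a 75/25 holdout split.  The batch size is reduced
    automatically when the training split is smaller than one batch.
    """

    lr: float = 9.9e-5
    lr_decay: float = 1e-6
    weight_decay: float = 1e-6
    batch_size: int = 256
    max_epochs: int = 150
    patience: int = 10
    holdout_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience < 1 or self.batch_size < 1:
            raise ValueError("patience and batch_size must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Preset for minutes-scale CPU runs on synthetic cohorts.

        The published starting learning rate was chosen for a cohort of
        ~2300 samples trained for hours; at a few hundred samples and a few
        dozen epochs the same Adagrad step is far too small to converge.
        This preset compensates the much smaller step budget with a larger
        starting step (1e-2) and a patience long enough (20 epochs) to ride
        out the flat early phase of small-cohort training.
        """
        defaults = dict(lr=1e-2, max_epochs=80, patience=20, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainHistory:
    """Per-epoch losses/metrics and the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_metric": self.val_metric,
            }
        )


def split_cohort(
    samples: Sequence[str],
    labels: np.ndarray | None = None,
    holdout_fraction: float = 0.25,
    stratify: bool = True,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/validation split (default 75/25).

    Stratification preserves label proportions within rounding and requires
    at least two samples per class.
    """
    if not (0 < holdout_fraction < 1):
        raise ValueError("holdout_fraction must lie in (0, 1)")
    samples = list(samples)
    strat = None
    if stratify:
        if labels is None:
            raise ValueError("stratified split needs labels")
        values, counts = np.unique(np.asarray(labels), return_counts=True)
        if counts.min() < 2:
            raise ValueError("stratified split needs >= 2 samples per class")
        strat = np.asarray(labels)
    train, val = train_test_split(
        samples, test_size=holdout_fraction, stratify=strat, random_state=seed
    )
    return list(train), list(val)


def head_loss(
    logits: np.ndarray, labels: np.ndarray, task: str
) -> tuple[float, np.ndarray]:
    """The full training objective: head loss only, no reconstruction term."""
    if task == "regression":
        return mse_loss(logits, labels)
    return softmax_cross_entropy(logits, np.asarray(labels, dtype=int))


def train_model(
    model: GenomeNet,
    images: np.ndarray,
    labels: np.ndarray,
    task: str,
    config: TrainConfig,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> tuple[GenomeNet, TrainHistory]:
    """Adagrad training with early stopping on validation loss.

    If no explicit validation set is given, a stratified (classification)
    or plain (regression) holdout of ``config.holdout_fraction`` is carved
    out of ``images``.  Training stops once the validation loss has not
    improved for ``config.patience`` epochs; the best-validation-loss
    weights are restored before returning.
    """
    if task not in ("binary", "multiclass", "regression"):
        raise ValueError(f"unknown task {task!r}")
    labels = np.asarray(labels)
    if val_images is None:
        idx = np.arange(len(images))
        stratify = task != "regression"
        tr_idx, va_idx = split_cohort(
            [str(i) for i in idx],
            labels if stratify else None,
            config.holdout_fraction,
            stratify=stratify,
            seed=config.seed,
        )
        tr_idx = np.array([int(i) for i in tr_idx])
        va_idx = np.array([int(i) for i in va_idx])
        val_images, val_labels = images[va_idx], labels[va_idx]
        images, labels = images[tr_idx], labels[tr_idx]

    n = len(images)
    batch = min(config.batch_size, n)
    opt = Adagrad(
        model.parameters(),
        lr=config.lr,
        lr_decay=config.lr_decay,
        weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_loss = np.inf
    best_state = model.get_state()
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            sel = order[start : start + batch]
            out = model.forward(images[sel], train=True)
            loss, dlogits = head_loss(out.logits, labels[sel], task)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            model.backward(dlogits)
            opt.step()
            opt.zero_grad()
            epoch_loss += loss * len(sel)
        history.train_loss.append(epoch_loss / n)

        val_logits = predict_logits(model, val_images, batch=batch)
        vloss, _ = head_loss(val_logits, val_labels, task)
        history.val_loss.append(vloss)
        try:
            metric = evaluate(logits_to_predictions(val_logits, task), val_labels, task)
        except ValueError:
            metric = float("nan")
        history.val_metric.append(metric)

        if vloss < best_loss - 1e-9:
            best_loss = vloss
            best_state = model.get_state()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                history.stopped_early = True
                break

    model.set_state(best_state)
    return model, history


def predict_logits(model: GenomeNet, images: np.ndarray, batch: int = 256) -> np.ndarray:
    """Evaluation-mode logits, batched to bound memory."""
    chunks = [
        model.forward(images[i : i + batch], train=False).logits
        for i in range(0, len(images), batch)
    ]
    return np.concatenate(chunks, axis=0)


def logits_to_predictions(logits: np.ndarray, task: str) -> np.ndarray:
    if task == "regression":
        return logits[:, 0].astype(np.float64)
    return softmax(logits.astype(np.float64))


def evaluate(predictions: np.ndarray, truth: np.ndarray, task: str) -> float:
    """Task metric: AUC (binary), macro F1 (multiclass), RMSE (regression).

    Binary predictions are class probabilities (the positive-class column is
    used for the ROC); multiclass predictions are argmaxed.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) == 0 or len(predictions) != len(truth):
        raise ValueError("predictions and truth must be non-empty and aligned")
    if task == "binary":
        if len(np.unique(truth)) < 2:
            raise ValueError("AUC undefined: truth contains a single class")
        scores = predictions[:, 1] if predictions.ndim == 2 else predictions
        return float(roc_auc_score(truth.astype(int), scores))
    if task == "multiclass":
        pred_labels = predictions.argmax(axis=1) if predictions.ndim == 2 else predictions
        return float(f1_score(truth.astype(int), pred_labels, average="macro"))
    if task == "regression":
        return float(np.sqrt(np.mean((predictions.reshape(-1) - truth.reshape(-1)) ** 2)))
    raise ValueError(f"unknown task {task!r}")


def extract_latents(model: GenomeNet, images: np.ndarray, batch: int = 256) -> np.ndarray:
    """Evaluation-mode latent vectors for a stack of images."""
    chunks = [
        model.forward(images[i : i + batch], train=False).latent
        for i in range(0, len(images), batch)
    ]
    return np.concatenate(chunks, axis=0).astype(np.float64)


def embed_latent(latents: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP embedding of latent vectors for visual diagnostics."""
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2 or len(latents) < 4:
        raise ValueError("embed_latent needs an (n >= 4) x latent_dim matrix")
    import umap  # deferred: numba-jitted import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            random_state=seed,
            n_neighbors=min(n_neighbors, len(latents) - 1),
        )
        return np.asarray(reducer.fit_transform(latents), dtype=np.float64)
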