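"""Integrated Gradients and downstream gene-level importance analysis.

Integrated Gradients (IG) attributes a model output F to each input feature
as the path integral of the gradient along the straight line from a baseline
image x' to the input x:

    A_i = (x_i - x'_i) * (1/m) * sum_{k=1..m} dF/dx_i evaluated at
          x' + (k/m) * (x - x')

(a right-endpoint Riemann approximation with m steps).  IG satisfies the
completeness axiom — the attributions sum to F(x) - F(x') — up to the
Riemann discretization error, which shrinks as m grows; the implementation
reports this gap as a diagnostic.

The attribution image is then read back through the layout to per-gene,
per-channel scores, min-max rescaled within sample groups (e.g. cancer
types) to make groups comparable, and aggregated into gene rankings and
per-channel importance shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from omicsimage.genome_image import GenomeImage, LayoutSpec

#: Anything exposing ``output_and_input_grad(x, target) -> (F, dF/dx)``.
Differentiable = object


@dataclass
class IGConfig:
    """Integrated-gradients settings.

    ``steps`` is the Riemann step count m (more steps, smaller completeness
    gap).  The default baseline is the all-zeros image: channels are min-max
    scaled so zero is each source's minimum, i.e. "no signal".
    """

    steps: int = 50
    baseline: np.ndarray | None = None
    batch: int = 256

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class AttributionResult:
    """Per-sample, per-channel, per-gene attribution scores."""

    raw: np.ndarray  # (samples, channels, genes)
    sample_ids: list[str]
    channel_names: list[str]
    gene_ids: list[str]
    group_ids: list[str] | None = None
    group_scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = (len(self.sample_ids), len(self.channel_names), len(self.gene_ids))
        if self.raw.shape != expected:
            raise ValueError(f"raw shape {self.raw.shape} != {expected}")


def integrated_gradients(
    model: Differentiable,
    x: np.ndarray,
    config: IGConfig | None = None,
    target: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrated Gradients for a batch of images.

    Parameters
    ----------
    model:
        Any object with ``output_and_input_grad(x, target)`` returning the
        scalar output F per sample and dF/dx (a :class:`GenomeNet`, or a
        simple differentiable probe in tests).
    x:
        Input images, shape (B, C, H, W).
    target:
        Per-sample output index for classification models (ignored by
        regression models).

    Returns
    -------
    attributions:
        Array shaped like ``x``.
    completeness_gap:
        Per-sample |sum(A) - (F(x) - F(x'))|, the Riemann-approximation
        error of the completeness axiom.
    """
    config = config or IGConfig()
    x = np.asarray(x, dtype=np.float64)
    baseline = (
        np.zeros_like(x) if config.baseline is None else np.broadcast_to(config.baseline, x.shape)
    )
    if baseline.shape != x.shape:
        raise ValueError("baseline shape must match input shape")
    diff = x - baseline
    m = config.steps
    grad_sum = np.zeros_like(x)
    for k in range(1, m + 1):
        point = baseline + (k / m) * diff
        _, g = _grad_in_batches(model, point, target, config.batch)
        if not np.isfinite(g).all():
            raise FloatingPointError(f"non-finite gradient at interpolation step {k}")
        grad_sum += g
    attributions = diff * grad_sum / m

    f_x, _ = _grad_in_batches(model, x, target, config.batch)
    f_base, _ = _grad_in_batches(model, baseline, target, config.batch)
    sums = attributions.reshape(len(x), -1).sum(axis=1)
    gap = np.abs(sums - (f_x - f_base))
    return attributions, gap


def _grad_in_batches(
    model: Differentiable, x: np.ndarray, target: np.ndarray | None, batch: int
) -> tuple[np.ndarray, np.ndarray]:
    fs, gs = [], []
    for i in range(0, len(x), batch):
        t = None if target is None else np.asarray(target)[i : i + batch]
        f, g = model.output_and_input_grad(x[i : i + batch], t)
        fs.append(np.asarray(f, dtype=np.float64))
        gs.append(np.asarray(g, dtype=np.float64))
    return np.concatenate(fs), np.concatenate(gs)


def attributions_to_genes(
    attr_images: np.ndarray,
    layout: LayoutSpec,
    sample_ids: Sequence[str],
    channel_names: Sequence[str],
    gene_ids: Sequence[str],
) -> AttributionResult:
    """Read pixel attributions back to genes; padding pixels are dropped."""
    for g in gene_ids:
        if g not in layout.gene_to_pixel:
            raise ValueError(f"gene {g} not present in layout")
    rows = np.array([layout.gene_to_pixel[g][0] for g in gene_ids])
    cols = np.array([layout.gene_to_pixel[g][1] for g in gene_ids])
    raw = attr_images[:, :, rows, cols]
    return AttributionResult(
        raw=np.asarray(raw, dtype=np.float64),
        sample_ids=list(sample_ids),
        channel_names=list(channel_names),
        gene_ids=list(gene_ids),
    )


def scale_by_group(
    result: AttributionResult,
    group_ids: Sequence[str],
    per_channel: bool = False,
) -> AttributionResult:
    """Min-max scale attributions to [0, 1] within each sample group.

    By default one scaler per group covers all its samples, channels and
    genes jointly, preserving relative channel magnitudes within a group;
    ``per_channel=True`` fits one scaler per (group, channel) instead.
    A constant group maps to zeros.
    """
    group_ids = list(group_ids)
    if len(group_ids) != len(result.sample_ids):
        raise ValueError("one group id per sample required")
    scaled = np.zeros_like(result.raw)
    for group in dict.fromkeys(group_ids):
        sel = np.array([g == group for g in group_ids])
        if not sel.any():
            raise ValueError(f"empty group {group}")
        block = result.raw[sel]
        if per_channel:
            for c in range(block.shape[1]):
                scaled[np.ix_(sel.nonzero()[0], [c])] = _minmax(block[:, [c]])
        else:
            scaled[sel] = _minmax(block)
    return AttributionResult(
        raw=result.raw,
        sample_ids=result.sample_ids,
        channel_names=result.channel_names,
        gene_ids=result.gene_ids,
        group_ids=group_ids,
        group_scaled=scaled,
    )


def _minmax(block: np.ndarray) -> np.ndarray:
    lo, hi = float(block.min()), float(block.max())
    if hi == lo:
        return np.zeros_like(block)
    return (block - lo) / (hi - lo)


def rank_genes(
    result: AttributionResult,
    channels: Sequence[str] | None = None,
    k: int | None = None,
    combine: str = "sum",
) -> pd.DataFrame:
    """Top-k genes by combined group-scaled attribution.

    Per gene and channel, the group-scaled attribution is averaged over
    samples; the selected channels are then combined by ``sum`` or ``max``.
    Ties break lexicographically by gene id.  Returns a DataFrame with
    columns ``gene_id``, ``score`` and one column per selected channel.
    """
    if result.group_scaled is None:
        raise ValueError("call scale_by_group before ranking")
    channels = list(channels) if channels is not None else list(result.channel_names)
    if not channels:
        raise ValueError("empty channel subset")
    for c in channels:
        if c not in result.channel_names:
            raise ValueError(f"unknown channel {c}")
    if combine not in ("sum", "max"):
        raise ValueError("combine must be 'sum' or 'max'")
    k = k if k is not None else len(result.gene_ids)
    if k > len(result.gene_ids):
        raise ValueError("k exceeds the number of genes")

    idx = [result.channel_names.index(c) for c in channels]
    per_gene_channel = result.group_scaled[:, idx, :].mean(axis=0)  # (channels, genes)
    score = per_gene_channel.sum(axis=0) if combine == "sum" else per_gene_channel.max(axis=0)
    tab = pd.DataFrame({"gene_id": result.gene_ids, "score": score})
    for ci, c in zip(idx, channels):
        tab[c] = result.group_scaled[:, ci, :].mean(axis=0)
    tab = tab.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    return tab.head(k).reset_index(drop=True)


def channel_importance(result: AttributionResult) -> pd.DataFrame:
    """Mean group-scaled attribution per (group, channel), with shares.

    Shares are normalized to sum to 1 within each group, giving the relative
    importance of each omics source for that group's predictions.
    """
    if result.group_scaled is None or result.group_ids is None:
        raise ValueError("call scale_by_group first")
    rows = []
    for group in dict.fromkeys(result.group_ids):
        sel = np.array([g == group for g in result.group_ids])
        means = result.group_scaled[sel].mean(axis=(0, 2))
        total = means.sum()
        shares = means / total if total > 0 else np.full_like(means, 1 / len(means))
        for c, m, s in zip(result.channel_names, means, shares):
            rows.append({"group": group, "channel": c, "mean_attribution": m, "share": s})
    return pd.DataFrame(rows)


def expr_meth_filter(
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    alpha: float = 0.05,
) -> list[str]:
    """Genes whose expression and methylation are significantly negatively
    correlated (Pearson, Benjamini-Hochberg adjusted at ``alpha``).

    Both inputs are samples x genes DataFrames with aligned indices and
    columns.  Genes with zero variance in either source are excluded.
    """
    if list(expression.index) != list(methylation.index) or list(
        expression.columns
    ) != list(methylation.columns):
        raise ValueError("expression and methylation must share samples and genes")
    if len(expression) < 3:
        raise ValueError("need at least 3 samples to test correlations")
    genes = list(expression.columns)
    r = np.full(len(genes), np.nan)
    p = np.full(len(genes), np.nan)
    for i, g in enumerate(genes):
        e, m = expression[g].to_numpy(), methylation[g].to_numpy()
        if e.std() == 0 or m.std() == 0:
            continue
        r[i], p[i] = stats.pearsonr(e, m)
    testable = ~np.isnan(p)
    keep = np.zeros(len(genes), dtype=bool)
    if testable.any():
        rejected, _, _, _ = multipletests(p[testable], alpha=alpha, method="fdr_bh")
        keep[testable] = rejected & (r[testable] < 0)
    return [g for g, kept in zip(genes, keep) if kept]


def attribution_table(result: AttributionResult) -> pd.DataFrame:
    """Long-format per-gene report (gene, channel, mean raw/scaled, rank)."""
    if result.group_scaled is None:
        raise ValueError("call scale_by_group first")
    rows = []
    mean_raw = result.raw.mean(axis=0)
    mean_scaled = result.group_scaled.mean(axis=0)
    for ci, channel in enumerate(result.channel_names):
        order = np.argsort(-mean_scaled[ci], kind="mergesort")
        rank = np.empty(len(result.gene_ids), dtype=int)
        rank[order] = np.arange(1, len(result.gene_ids) + 1)
        for gi, gene in enumerate(result.gene_ids):
            rows.append(
                {
                    "gene_id": gene,
                    "channel": channel,
                    "mean_raw": mean_raw[ci, gi],
                    "mean_scaled": mean_scaled[ci, gi],
                    "rank_in_channel": int(rank[gi]),
                }
            )
    return pd.DataFrame(rows)
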