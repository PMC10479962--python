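"""Gene-level ingestion of raw multi-omics tables.

Turns per-sample inputs — mutation calls with PolyPhen scores, expression
and methylation matrices, and ASCAT-style copy-number segments with sample
ploidy — into [0, 1]-scaled samples x genes channel matrices plus the
weighted genome integrity index (wGII).

Copy-number calling works on the log ratio ``logR = log2(total_cn / ploidy)``.
A gene is called *amplified* only when its full interval lies inside a single
segment with ``logR > log2(5/2)``; it is called *deleted* when it overlaps
(by at least one base) any segment with ``logR < log2(0.5/2)``.  The
asymmetry is deliberate: focal high-level amplification is required to cover
the whole gene, while even a partial deletion can disrupt it.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from omicsimage.types import (
    ChannelMatrix,
    CnThresholds,
    GeneAnnotation,
    MutationRecord,
    SampleProfile,
    Segment,
    check_segments_disjoint,
)

logger = logging.getLogger(__name__)

#: Autosomes entering the wGII; X is excluded.
_AUTOSOMES = tuple(str(c) for c in range(1, 23))


def compute_logR(total_cn: float, ploidy: float) -> float:
    """Ploidy-normalized copy-number log ratio, log2(total_cn / ploidy).

    ``total_cn == 0`` (homozygous deletion) maps to ``-inf``, which always
    falls below any deletion threshold and above no amplification threshold.
    """
    if ploidy <= 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    if total_cn < 0:
        raise ValueError(f"total_cn must be non-negative, got {total_cn}")
    if total_cn == 0:
        return float("-inf")
    return float(np.log2(total_cn / ploidy))


def call_cn_channels(
    segments: Iterable[Segment],
    profiles: Mapping[str, SampleProfile],
    genes: GeneAnnotation,
    thresholds: CnThresholds | None = None,
    samples: Sequence[str] | None = None,
) -> tuple[ChannelMatrix, ChannelMatrix]:
    """Gene-level binary amplification / deletion calls from segments.

    Returns the ``cn_gain`` and ``cn_loss`` channel matrices (already binary
    and therefore marked scaled).  Genes on chromosomes without segments for
    a sample stay 0 in both channels.
    """
    thresholds = thresholds or CnThresholds()
    segments = list(segments)
    check_segments_disjoint(segments)
    if samples is None:
        samples = list(profiles)
    sample_index = {s: i for i, s in enumerate(samples)}

    gene_tab = genes.table
    n = genes.n_genes
    gain = np.zeros((len(samples), n), dtype=np.float64)
    loss = np.zeros((len(samples), n), dtype=np.float64)

    # Gene lookup per chromosome (sorted by start for interval scans).
    by_chrom: dict[str, pd.DataFrame] = {
        c: gene_tab[gene_tab["chromosome"] == c] for c in genes.chromosomes()
    }

    for seg in segments:
        if seg.sample_id not in sample_index:
            continue
        if seg.chromosome not in by_chrom:
            warnings.warn(
                f"segment on chromosome {seg.chromosome!r} matches no annotated gene",
                stacklevel=2,
            )
            continue
        profile = profiles[seg.sample_id]
        logr = compute_logR(seg.total_cn, profile.ploidy)
        if not (logr > thresholds.tau_amp or logr < thresholds.tau_del):
            continue
        si = sample_index[seg.sample_id]
        sub = by_chrom[seg.chromosome]
        if logr > thresholds.tau_amp:
            # Amplified: the entire gene must sit inside this one segment.
            hit = (sub["start"] >= seg.start) & (sub["end"] <= seg.end)
            gain[si, sub.index[hit]] = 1.0
        if logr < thresholds.tau_del:
            # Deleted: any overlap with the segment suffices.
            hit = (sub["start"] <= seg.end) & (sub["end"] >= seg.start)
            loss[si, sub.index[hit]] = 1.0

    gene_ids = genes.gene_ids
    return (
        ChannelMatrix("cn_gain", list(samples), gene_ids, gain, scaled=True),
        ChannelMatrix("cn_loss", list(samples), gene_ids, loss, scaled=True),
    )


def summarize_mutations(
    records: Iterable[MutationRecord],
    genes: GeneAnnotation,
    samples: Sequence[str],
) -> ChannelMatrix:
    """Per-gene mutation score: the maximum PolyPhen score over a sample's
    mutations in the gene (most-damaging-event semantics); 0 when unmutated.
    """
    sample_index = {s: i for i, s in enumerate(samples)}
    values = np.zeros((len(samples), genes.n_genes), dtype=np.float64)
    skipped: set[str] = set()
    for rec in records:
        if rec.gene_id not in genes:
            skipped.add(rec.gene_id)
            continue
        if rec.sample_id not in sample_index:
            continue
        gi = genes.index_of(rec.gene_id)
        si = sample_index[rec.sample_id]
        if rec.polyphen > values[si, gi]:
            values[si, gi] = rec.polyphen
    if skipped:
        warnings.warn(
            f"skipped mutations in {len(skipped)} unannotated genes "
            f"(e.g. {sorted(skipped)[:3]})",
            stacklevel=2,
        )
    return ChannelMatrix("mutation", list(samples), genes.gene_ids, values)


def summarize_methylation(
    scores: pd.DataFrame,
    genes: GeneAnnotation,
    samples: Sequence[str],
) -> ChannelMatrix:
    """Mean methylation beta value per gene.

    ``scores`` is a long table with columns ``sample_id``, ``gene_id``,
    ``beta`` (one row per probe or per pre-summarized gene).  Genes without
    any measurement stay 0.
    """
    values = np.zeros((len(samples), genes.n_genes), dtype=np.float64)
    if len(scores) == 0:
        warnings.warn("empty methylation input; returning all-zero channel", stacklevel=2)
        return ChannelMatrix("methylation", list(samples), genes.gene_ids, values)
    if ((scores["beta"] < 0) | (scores["beta"] > 1)).any():
        raise ValueError("methylation beta values must lie in [0, 1]")
    known = scores["gene_id"].isin(set(genes.gene_ids))
    if not known.all():
        warnings.warn(
            f"skipped methylation for {int((~known).sum())} rows in unannotated genes",
            stacklevel=2,
        )
        scores = scores[known]
    mean = scores.groupby(["sample_id", "gene_id"], sort=False)["beta"].mean()
    sample_index = {s: i for i, s in enumerate(samples)}
    for (sample, gene), beta in mean.items():
        if sample in sample_index:
            values[sample_index[sample], genes.index_of(gene)] = beta
    return ChannelMatrix("methylation", list(samples), genes.gene_ids, values)


def expression_channel(
    matrix: pd.DataFrame,
    genes: GeneAnnotation,
    samples: Sequence[str],
) -> ChannelMatrix:
    """Align a genes x samples expression matrix (e.g. TPM) to the canonical
    gene and sample order; unmeasured genes stay 0 (baseline after scaling).
    """
    values = np.zeros((len(samples), genes.n_genes), dtype=np.float64)
    common = [g for g in genes.gene_ids if g in matrix.index]
    missing = genes.n_genes - len(common)
    if missing:
        logger.info("expression: %d annotated genes unmeasured, left at 0", missing)
    sub = matrix.loc[common, list(samples)].T.to_numpy(dtype=np.float64)
    cols = [genes.index_of(g) for g in common]
    values[:, cols] = sub
    return ChannelMatrix("expression", list(samples), genes.gene_ids, values)


def minmax_scale(
    channel: ChannelMatrix,
    fit_samples: Sequence[str] | None = None,
) -> ChannelMatrix:
    """Min-max scale one whole channel to [0, 1].

    By default the scaler is fit over every value of the channel (all
    samples and genes jointly), mirroring per-data-source scaling across a
    full cohort.  Pass ``fit_samples`` (e.g. the training split) to fit the
    scaler on those rows only and avoid leakage; values of held-out samples
    are then clipped into [0, 1].  A constant channel maps to all zeros.
    """
    x = channel.values
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError(f"channel {channel.channel_name} has no finite values")
    if not finite.all():
        raise ValueError(f"channel {channel.channel_name} contains non-finite values")
    if fit_samples is not None:
        rows = [channel.sample_ids.index(s) for s in fit_samples]
        if not rows:
            raise ValueError("fit_samples selects no rows")
        fit = x[rows]
    else:
        fit = x
    lo, hi = float(fit.min()), float(fit.max())
    if hi == lo:
        scaled = np.zeros_like(x)
    else:
        scaled = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return ChannelMatrix(
        channel.channel_name,
        list(channel.sample_ids),
        list(channel.gene_ids),
        scaled,
        scaled=True,
    )


def compute_wgii(
    segments: Iterable[Segment],
    profile: SampleProfile,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> float:
    """Weighted genome integrity index of one sample.

    For each autosome with segment coverage, the aberrant fraction is the
    segmented length whose rounded total copy number differs from the
    rounded sample ploidy, divided by the total segmented length of that
    chromosome.  wGII is the unweighted mean of these fractions, so every
    covered autosome contributes equally regardless of its physical size.
    ``chromosome_lengths`` is accepted for interface symmetry but the
    denominator is the segmented length, which keeps the index well defined
    on partially covered chromosomes.
    """
    ref_cn = round(profile.ploidy)
    covered: dict[str, float] = {}
    aberrant: dict[str, float] = {}
    for seg in segments:
        if seg.sample_id != profile.sample_id:
            continue
        if seg.chromosome not in _AUTOSOMES:
            continue
        covered[seg.chromosome] = covered.get(seg.chromosome, 0.0) + seg.length
        if round(seg.total_cn) != ref_cn:
            aberrant[seg.chromosome] = aberrant.get(seg.chromosome, 0.0) + seg.length
    if not covered:
        raise ValueError(f"no segmented autosome for sample {profile.sample_id}")
    fractions = [aberrant.get(c, 0.0) / covered[c] for c in covered]
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# Readers for the on-disk interchange formats.
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a BED-like annotation: chrom, start, end, gene_id (tab separated,
    headerless, BED 0-based half-open converted to 1-based inclusive)."""
    tab = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "gene_id"],
        dtype={"chromosome": str, "gene_id": str},
        comment="#",
    )
    tab["chromosome"] = tab["chromosome"].str.removeprefix("chr")
    tab["start"] = tab["start"].astype(int) + 1
    tab["end"] = tab["end"].astype(int)
    return GeneAnnotation(tab[["gene_id", "chromosome", "start", "end"]])


def read_segments(path: str | Path) -> list[Segment]:
    """Read an ASCAT-style segment table.

    Expected columns: ``sample``, ``chr``, ``startpos``, ``endpos`` and
    either ``total_cn`` or the allele-specific pair ``nMajor``/``nMinor``
    (summed into total copy number).
    """
    tab = pd.read_csv(path, sep="\t", dtype={"sample": str, "chr": str})
    if "total_cn" in tab.columns:
        total = tab["total_cn"].astype(float)
    elif {"nMajor", "nMinor"} <= set(tab.columns):
        total = tab["nMajor"].astype(float) + tab["nMinor"].astype(float)
    else:
        raise ValueError("segment table needs total_cn or nMajor/nMinor columns")
    return [
        Segment(
            sample_id=row["sample"],
            chromosome=str(row["chr"]).removeprefix("chr"),
            start=int(row["startpos"]),
            end=int(row["endpos"]),
            total_cn=float(t),
        )
        for (_, row), t in zip(tab.iterrows(), total)
    ]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with at least ``sample_id``, ``ploidy``, ``purity``
    plus any outcome-label columns; returns it indexed by sample order."""
    tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "ploidy"}
    if not required <= set(tab.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    if tab["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return tab.reset_index(drop=True)


def profiles_from_sheet(sheet: pd.DataFrame) -> dict[str, SampleProfile]:
    purity = sheet["purity"] if "purity" in sheet.columns else pd.Series(1.0, index=sheet.index)
    return {
        row["sample_id"]: SampleProfile(
            sample_id=row["sample_id"], ploidy=float(row["ploidy"]), purity=float(p)
        )
        for (_, row), p in zip(sheet.iterrows(), purity)
    }


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """MAF-like mutation TSV with columns ``sample_id``, ``gene_id``,
    ``polyphen``."""
    tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    return [
        MutationRecord(row["sample_id"], row["gene_id"], float(row["polyphen"]))
        for _, row in tab.iterrows()
    ]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV matrix with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)
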