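"""Self-contained synthetic multi-omics cohorts with planted signal genes.

The generator emulates the statistical structure the pipeline assumes in a
real cancer cohort: a toy genome of ``n_chromosomes`` chromosomes carrying
non-overlapping genes; a binary outcome label; label-associated effects
planted in the expression, methylation, and mutation channels on known gene
sets; and piecewise-constant copy-number segments from which gain/loss
channels and a per-sample wGII are derived.  Everything is deterministic
given the seed, and the cohort can be written to disk in exactly the file
formats :mod:`omicsimage.omics_ingest` reads, so the full command-line
pipeline runs end-to-end on generated files.

Default condition (the "desk-scale preset"): 400 samples, 1024 genes on 16
chromosomes (a 32x32 auto square image), 20 signal genes per channel, an
expression shift of 2 standard deviations, a methylation beta shift of 0.3,
and a 5x mutation-rate ratio in cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from omicsimage.omics_ingest import (
    call_cn_channels,
    compute_wgii,
    summarize_mutations,
)
from omicsimage.types import (
    ChannelMatrix,
    CnThresholds,
    GeneAnnotation,
    MutationRecord,
    SampleProfile,
    Segment,
)

#: Gene interval width and intergenic gap of the toy genome (bp).
GENE_WIDTH = 10_000
GENE_GAP = 2_000


@dataclass
class SyntheticConfig:
    """Cohort-generation parameters.

    ``delta_expression`` is the mean expression shift of signal genes in
    cases, in within-gene standard-deviation units; ``delta_methylation``
    the shift of the methylation beta mean; ``mutation_rate_ratio`` the
    case/control ratio of the per-gene mutation probability of signal
    genes; ``segment_event_rate`` the per-chromosome probability of one
    copy-number event per sample.
    """

    n_samples: int = 400
    n_genes: int = 1024
    n_chromosomes: int = 16
    n_signal_genes: int = 20
    delta_expression: float = 2.0
    delta_methylation: float = 0.3
    mutation_rate_ratio: float = 5.0
    base_mutation_rate: float = 0.02
    label_fraction: float = 0.5
    segment_event_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")
        if self.n_chromosomes > 22:
            raise ValueError("toy genomes use autosome names 1..22")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes exceeds n_genes")
        if not (0 < self.label_fraction < 1):
            raise ValueError("label_fraction must lie in (0, 1)")
        if self.label_fraction * self.n_samples < 2:
            raise ValueError("degenerate config: fewer than 2 expected cases")
        if self.delta_expression < 0 or self.mutation_rate_ratio < 0:
            raise ValueError("effect sizes must be non-negative")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth of planted genes."""

    config: SyntheticConfig
    genes: GeneAnnotation
    channels: dict[str, ChannelMatrix]  # unscaled mutation/expression/methylation
    segments: list[Segment]
    profiles: dict[str, SampleProfile]
    labels: np.ndarray  # binary 0/1 per sample
    wgii: np.ndarray  # continuous target per sample
    planted_genes: dict[str, list[str]]  # channel -> gene ids

    @property
    def sample_ids(self) -> list[str]:
        return list(self.channels["expression"].sample_ids)

    def planted_union(self) -> list[str]:
        out: dict[str, None] = {}
        for genes in self.planted_genes.values():
            for g in genes:
                out.setdefault(g, None)
        return list(out)


def generate_genome(config: SyntheticConfig) -> GeneAnnotation:
    """Toy genome: genes assigned round-robin to chromosomes, laid out as
    non-overlapping fixed-width intervals with fixed gaps."""
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    counts = {c: 0 for c in chroms}
    rows = []
    for i in range(config.n_genes):
        chrom = chroms[i % config.n_chromosomes]
        pos = counts[chrom]
        counts[chrom] += 1
        start = 1 + pos * (GENE_WIDTH + GENE_GAP)
        rows.append(
            {
                "gene_id": f"G{i:05d}",
                "chromosome": chrom,
                "start": start,
                "end": start + GENE_WIDTH - 1,
            }
        )
    return GeneAnnotation(pd.DataFrame(rows))


def _chromosome_spans(genes: GeneAnnotation) -> dict[str, int]:
    spans = {}
    for chrom in genes.chromosomes():
        spans[chrom] = int(genes.genes_on(chrom)["end"].max()) + GENE_GAP
    return spans


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort with planted label-associated effects.

    Expression of signal genes is shifted by ``delta_expression`` SD in
    cases; methylation signal genes get their beta mean shifted by
    ``delta_methylation``; mutation signal genes are mutated at
    ``mutation_rate_ratio`` times the base rate in cases (scores drawn as
    damaging PolyPhen values in [0.5, 1]).  Copy-number segments are
    label-independent; the resulting per-sample wGII is the continuous
    target.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    genes = generate_genome(config)
    gene_ids = genes.gene_ids
    n, g = config.n_samples, config.n_genes
    samples = [f"S{i:04d}" for i in range(n)]

    labels = (rng.random(n) < config.label_fraction).astype(int)
    # Guard against a degenerate draw at small n.
    if labels.sum() < 2:
        labels[:2] = 1
    if (1 - labels).sum() < 2:
        labels[-2:] = 0

    planted = {
        channel: sorted(rng.choice(gene_ids, size=config.n_signal_genes, replace=False))
        for channel in ("expression", "methylation", "mutation")
    }

    # Expression: per-gene baseline ~ N(6, 2) (log-TPM-like), unit noise.
    baseline = rng.normal(6.0, 2.0, size=g)
    expr = rng.normal(baseline[None, :], 1.0, size=(n, g))
    cols = [genes.index_of(x) for x in planted["expression"]]
    expr[:, cols] += config.delta_expression * labels[:, None]
    expr_cm = ChannelMatrix("expression", samples, gene_ids, expr)

    # Methylation: beta values around a per-gene mean, concentration 30.
    meth_mean = rng.uniform(0.1, 0.6, size=g)
    mean_matrix = np.tile(meth_mean, (n, 1))
    cols = [genes.index_of(x) for x in planted["methylation"]]
    mean_matrix[:, cols] += config.delta_methylation * labels[:, None]
    mean_matrix = np.clip(mean_matrix, 0.02, 0.98)
    kappa = 30.0
    meth = rng.beta(mean_matrix * kappa, (1 - mean_matrix) * kappa)
    meth_cm = ChannelMatrix("methylation", samples, gene_ids, meth)

    # Mutations: Bernoulli per gene; damaging PolyPhen score when mutated.
    rate = np.full((n, g), config.base_mutation_rate)
    cols = [genes.index_of(x) for x in planted["mutation"]]
    case_rate = min(config.base_mutation_rate * config.mutation_rate_ratio, 1.0)
    rate[np.ix_(labels == 1, cols)] = case_rate
    mutated = rng.random((n, g)) < rate
    records = [
        MutationRecord(samples[si], gene_ids[gi], float(rng.uniform(0.5, 1.0)))
        for si, gi in zip(*np.nonzero(mutated))
    ]
    mut_cm = summarize_mutations(records, genes, samples)

    # Copy-number segments: per chromosome, at most one aberrant interval.
    spans = _chromosome_spans(genes)
    profiles = {
        s: SampleProfile(s, ploidy=2.0, purity=float(rng.uniform(0.4, 0.9))) for s in samples
    }
    event_cns = np.array([0.0, 1.0, 3.0, 5.0, 6.0])
    event_probs = np.array([0.15, 0.3, 0.3, 0.15, 0.1])
    segments: list[Segment] = []
    for s in samples:
        for chrom, span in spans.items():
            if rng.random() >= config.segment_event_rate:
                segments.append(Segment(s, chrom, 1, span, 2.0))
                continue
            frac = rng.uniform(0.1, 0.6)
            length = max(int(span * frac), 1)
            start = int(rng.integers(1, max(span - length, 1) + 1))
            end = start + length - 1
            cn = float(rng.choice(event_cns, p=event_probs))
            if start > 1:
                segments.append(Segment(s, chrom, 1, start - 1, 2.0))
            segments.append(Segment(s, chrom, start, end, cn))
            if end < span:
                segments.append(Segment(s, chrom, end + 1, span, 2.0))
    wgii = np.array([compute_wgii(segments, profiles[s]) for s in samples])

    return SyntheticCohort(
        config=config,
        genes=genes,
        channels={"mutation": mut_cm, "expression": expr_cm, "methylation": meth_cm},
        segments=segments,
        profiles=profiles,
        labels=labels,
        wgii=wgii,
        planted_genes=planted,
    )


def recovery_score(ranked_genes: list[str], planted: list[str], k: int) -> float:
    """|top-k intersect planted| / min(k, |planted|)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not planted:
        raise ValueError("empty planted set")
    top = set(ranked_genes[:k])
    return len(top & set(planted)) / min(k, len(set(planted)))


# ---------------------------------------------------------------------------
# On-disk cohort in the interchange formats omics_ingest reads.
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write annotation (BED), omics matrices (TSV), mutations (MAF-like),
    segments (ASCAT-style), sample sheet, and the planted-genes truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bed = cohort.genes.table.copy()
    bed["start0"] = bed["start"] - 1
    paths["annotation"] = outdir / "genes.bed"
    bed[["chromosome", "start0", "end", "gene_id"]].to_csv(
        paths["annotation"], sep="\t", header=False, index=False
    )

    for name in ("expression", "methylation"):
        cm = cohort.channels[name]
        paths[name] = outdir / f"{name}.tsv"
        cm.to_frame().T.rename_axis("gene_id").to_csv(paths[name], sep="\t")

    mut = cohort.channels["mutation"]
    si, gi = np.nonzero(mut.values)
    paths["mutations"] = outdir / "mutations.tsv"
    pd.DataFrame(
        {
            "sample_id": [mut.sample_ids[i] for i in si],
            "gene_id": [mut.gene_ids[i] for i in gi],
            "polyphen": mut.values[si, gi],
        }
    ).to_csv(paths["mutations"], sep="\t", index=False)

    paths["segments"] = outdir / "segments.tsv"
    pd.DataFrame(
        {
            "sample": [s.sample_id for s in cohort.segments],
            "chr": [s.chromosome for s in cohort.segments],
            "startpos": [s.start for s in cohort.segments],
            "endpos": [s.end for s in cohort.segments],
            "total_cn": [s.total_cn for s in cohort.segments],
        }
    ).to_csv(paths["segments"], sep="\t", index=False)

    paths["sample_sheet"] = outdir / "samples.tsv"
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "ploidy": [cohort.profiles[s].ploidy for s in cohort.sample_ids],
            "purity": [cohort.profiles[s].purity for s in cohort.sample_ids],
            "label": cohort.labels,
            "wgii": cohort.wgii,
        }
    ).to_csv(paths["sample_sheet"], sep="\t", index=False)

    paths["truth"] = outdir / "planted_genes.json"
    paths["truth"].write_text(
        json.dumps({"config": asdict(cohort.config), "planted_genes": cohort.planted_genes}, indent=1)
    )
    return paths
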