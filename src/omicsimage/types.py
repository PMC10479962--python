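"""Core domain containers shared across the pipeline.

Coordinates are 1-based and inclusive throughout (gene and segment
intervals), matching the convention of ASCAT-style segment tables.  The
supported chromosomes are the human autosomes 1-22 plus X; Y and the
mitochondrial contig are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Chromosomes a gene annotation may use.
SUPPORTED_CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)

#: Fixed channel order of every multi-channel genome image.
CHANNEL_ORDER: tuple[str, ...] = (
    "mutation",
    "expression",
    "methylation",
    "cn_gain",
    "cn_loss",
)


class GeneAnnotation:
    """Ordered catalog of genes with chromosomal coordinates.

    The row order of the annotation defines the canonical gene axis of every
    :class:`ChannelMatrix` and of the image layouts.

    Parameters
    ----------
    table:
        DataFrame with columns ``gene_id``, ``chromosome``, ``start``,
        ``end``.  ``start``/``end`` are 1-based inclusive base-pair
        positions.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"gene_id", "chromosome", "start", "end"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        table = table.reset_index(drop=True).copy()
        table["chromosome"] = table["chromosome"].astype(str)
        table["gene_id"] = table["gene_id"].astype(str)
        if table["gene_id"].duplicated().any():
            dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if (table["start"] > table["end"]).any():
            raise ValueError("gene start must be <= end")
        bad = set(table["chromosome"]) - set(SUPPORTED_CHROMOSOMES)
        if bad:
            raise ValueError(f"unsupported chromosomes: {sorted(bad)}")
        self.table = table
        self._index = {g: i for i, g in enumerate(table["gene_id"])}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def index_of(self, gene_id: str) -> int:
        return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __len__(self) -> int:
        return len(self.table)

    def genes_on(self, chromosome: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == str(chromosome)]

    def chromosomes(self) -> list[str]:
        """Chromosomes present, in annotation order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.table["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneAnnotation) and self.table.equals(other.table)


@dataclass(frozen=True)
class Segment:
    """One copy-number segment of one sample (1-based inclusive interval)."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    total_cn: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.total_cn < 0:
            raise ValueError("total_cn must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleProfile:
    """Per-sample ploidy and (carried but unused) tumor purity."""

    sample_id: str
    ploidy: float
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")


@dataclass(frozen=True)
class MutationRecord:
    """A single mutation call with its PolyPhen damage score in [0, 1]."""

    sample_id: str
    gene_id: str
    polyphen: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.polyphen <= 1.0):
            raise ValueError(f"polyphen score {self.polyphen} outside [0, 1]")


@dataclass(frozen=True)
class CnThresholds:
    """Log-ratio thresholds for gene-level amplification / deletion calls.

    ``tau_amp`` defaults to log2(5/2): a segment is amplified when its total
    copy number exceeds 2.5x ploidy.  ``tau_del`` defaults to
    log2(0.5/2) = -2: deleted when total copy number falls below a quarter
    of ploidy.
    """

    tau_amp: float = float(np.log2(5 / 2))
    tau_del: float = float(np.log2(0.5 / 2))

    def __post_init__(self) -> None:
        if not self.tau_del < self.tau_amp:
            raise ValueError("tau_del must be below tau_amp")


@dataclass
class ChannelMatrix:
    """samples x genes values for a single omics source.

    ``values`` rows follow ``sample_ids``; columns follow the
    :class:`GeneAnnotation` order the matrix was built against.  ``scaled``
    marks matrices that have been min-max scaled to [0, 1].
    """

    channel_name: str
    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.channel_name not in CHANNEL_ORDER:
            raise ValueError(
                f"unknown channel {self.channel_name!r}; expected one of {CHANNEL_ORDER}"
            )
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.gene_ids)})"
            )
        if self.scaled:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError("scaled channel has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def check_segments_disjoint(segments: Iterable[Segment]) -> None:
    """Raise if any two segments of one sample on one chromosome overlap."""
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chromosome), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping segments for sample {sample} chr {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def as_sample_order(samples: Sequence[str]) -> list[str]:
    seen: dict[str, None] = {}
    for s in samples:
        if s in seen:
            raise ValueError(f"duplicate sample id {s}")
        seen[s] = None
    return list(seen)
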