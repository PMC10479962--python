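"""Gene-to-pixel layouts and the invertible table <-> image transform.

Four layouts are supported:

``square``
    Genes sorted by (chromosome rank, start) and filled row-major into a
    square grid.  In *published* mode the grid is fixed at 198x198 and the
    chromosome rank follows the Hi-C interaction ordering
    4, X, 7, 2, 5, 6, 13, ... so that chromosomes adjacent in 3-D nuclear
    space are adjacent on the image.  In *auto* mode the side is
    ceil(sqrt(n_genes)) and the interaction ordering is restricted to the
    chromosomes actually present.
``square_shuffled``
    The same grid with the gene order permuted by a seed; pixel position
    carries no information (spatial-structure control).
``chromosome_rows``
    One chromosome per row.  Published mode fixes 24 rows x 3760 columns (3760
    = the most gene-rich chromosome; unused trailing rows are padding).
``flat``
    A single 1 x W row with genes in seeded random order.

Unmapped pixels are padding: they are written as 0 in every channel and
ignored when reading values or attributions back to genes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from omicsimage.types import CHANNEL_ORDER, ChannelMatrix, GeneAnnotation

#: Chromosome ordering derived from Hi-C interaction coefficients.
HIC_CHROMOSOME_ORDER: tuple[str, ...] = (
    "4", "X", "7", "2", "5", "6", "13", "3", "8", "9", "18", "12",
    "1", "10", "11", "14", "22", "19", "17", "20", "16", "15", "21",
)

#: Fixed dimensions used in published mode.
PUBLISHED_SQUARE_SIDE = 198
PUBLISHED_CHROM_ROWS = 24
PUBLISHED_CHROM_WIDTH = 3760

LAYOUT_KINDS = ("square", "square_shuffled", "chromosome_rows", "flat")


@dataclass
class LayoutSpec:
    """Bijective gene -> pixel mapping for one image layout."""

    kind: str
    height: int
    width: int
    gene_to_pixel: dict[str, tuple[int, int]]
    chromosome_order: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in LAYOUT_KINDS:
            raise ValueError(f"unknown layout kind {self.kind!r}")
        pixels = list(self.gene_to_pixel.values())
        if len(set(pixels)) != len(pixels):
            raise ValueError("gene_to_pixel is not injective")
        for r, c in pixels:
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise ValueError(f"pixel ({r}, {c}) outside {self.height}x{self.width}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_pixel)

    def pixel_to_gene(self) -> dict[tuple[int, int], str]:
        return {pix: g for g, pix in self.gene_to_pixel.items()}

    def mask(self) -> np.ndarray:
        """Boolean H x W array, True on mapped (non-padding) pixels."""
        m = np.zeros((self.height, self.width), dtype=bool)
        for r, c in self.gene_to_pixel.values():
            m[r, c] = True
        return m

    def layout_hash(self) -> str:
        """Stable hash identifying the exact mapping (for checkpoint safety)."""
        payload = json.dumps(
            {
                "kind": self.kind,
                "height": self.height,
                "width": self.width,
                "map": sorted((g, list(p)) for g, p in self.gene_to_pixel.items()),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kind": self.kind,
                    "height": self.height,
                    "width": self.width,
                    "chromosome_order": self.chromosome_order,
                    "seed": self.seed,
                    "gene_to_pixel": {g: list(p) for g, p in self.gene_to_pixel.items()},
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LayoutSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            kind=d["kind"],
            height=d["height"],
            width=d["width"],
            gene_to_pixel={g: (int(p[0]), int(p[1])) for g, p in d["gene_to_pixel"].items()},
            chromosome_order=list(d["chromosome_order"]),
            seed=d["seed"],
        )


@dataclass
class GenomeImage:
    """samples x channels x H x W image stack plus its layout."""

    values: np.ndarray
    channel_names: list[str]
    layout: LayoutSpec
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (
            len(self.sample_ids),
            len(self.channel_names),
            self.layout.height,
            self.layout.width,
        )
        if self.values.shape != expected:
            raise ValueError(f"image shape {self.values.shape} != {expected}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape


def _ordered_genes(genes: GeneAnnotation, chromosome_order: Sequence[str]) -> list[str]:
    rank = {c: i for i, c in enumerate(chromosome_order)}
    tab = genes.table
    order = sorted(
        range(len(tab)),
        key=lambda i: (
            rank[tab["chromosome"].iat[i]],
            int(tab["start"].iat[i]),
            tab["gene_id"].iat[i],
        ),
    )
    return [tab["gene_id"].iat[i] for i in order]


def _chromosome_order_for(genes: GeneAnnotation, mode: str) -> list[str]:
    present = set(genes.table["chromosome"])
    if mode == "published":
        missing = present - set(HIC_CHROMOSOME_ORDER)
        if missing:
            raise ValueError(f"chromosomes outside the interaction ordering: {sorted(missing)}")
        return list(HIC_CHROMOSOME_ORDER)
    # auto: interaction ordering restricted to chromosomes that exist.
    return [c for c in HIC_CHROMOSOME_ORDER if c in present]


def build_layout(
    genes: GeneAnnotation,
    kind: str = "square",
    mode: str = "published",
    seed: int | None = None,
) -> LayoutSpec:
    """Construct the gene -> pixel mapping for one of the four layouts.

    ``mode='published'`` reproduces the published dimensions (198x198 square,
    24x3760 chromosome rows); ``mode='auto'`` sizes the grid to the gene
    catalog, which is what synthetic toy genomes use.  Shuffled layouts
    require a ``seed``.
    """
    if kind not in LAYOUT_KINDS:
        raise ValueError(f"unknown layout kind {kind!r}")
    if mode not in ("published", "auto"):
        raise ValueError(f"mode must be 'published' or 'auto', got {mode!r}")
    chrom_order = _chromosome_order_for(genes, mode)
    ordered = _ordered_genes(genes, chrom_order)
    n = len(ordered)

    if kind in ("square", "square_shuffled"):
        if mode == "published":
            side = PUBLISHED_SQUARE_SIDE
            if n > side * side:
                raise ValueError(f"{n} genes exceed published-mode capacity {side * side}")
            height = width = side
        else:
            side = math.ceil(math.sqrt(n))
            height = width = side
        if kind == "square_shuffled":
            if seed is None:
                raise ValueError("square_shuffled layout requires a seed")
            rng = np.random.default_rng(seed)
            ordered = [ordered[i] for i in rng.permutation(n)]
        mapping = {g: (i // width, i % width) for i, g in enumerate(ordered)}
        return LayoutSpec(kind, height, width, mapping, chrom_order, seed)

    if kind == "chromosome_rows":
        per_chrom: dict[str, list[str]] = {c: [] for c in chrom_order}
        for g in ordered:
            per_chrom[genes.table.loc[genes.index_of(g), "chromosome"]].append(g)
        max_per = max((len(v) for v in per_chrom.values()), default=0)
        if mode == "published":
            height, width = PUBLISHED_CHROM_ROWS, PUBLISHED_CHROM_WIDTH
            if max_per > width:
                raise ValueError(f"most gene-rich chromosome has {max_per} > {width} genes")
        else:
            height = len([c for c in chrom_order]) or 1
            width = max(max_per, 1)
        mapping = {}
        for row, chrom in enumerate(chrom_order):
            for col, g in enumerate(per_chrom[chrom]):
                mapping[g] = (row, col)
        return LayoutSpec(kind, height, width, mapping, chrom_order, seed)

    # flat: a single row, seeded random gene order.
    if seed is None:
        raise ValueError("flat layout requires a seed (genes are randomly ordered)")
    rng = np.random.default_rng(seed)
    ordered = [ordered[i] for i in rng.permutation(n)]
    mapping = {g: (0, i) for i, g in enumerate(ordered)}
    return LayoutSpec("flat", 1, max(n, 1), mapping, chrom_order, seed)


def image_from_table(
    channels: Sequence[ChannelMatrix],
    layout: LayoutSpec,
) -> GenomeImage:
    """Place scaled channel matrices onto the layout as a multi-channel image.

    Channels are reordered into the fixed order mutation, expression,
    methylation, cn_gain, cn_loss (restricted to those provided).  Padding
    pixels are exactly 0.
    """
    if not channels:
        raise ValueError("at least one channel required")
    for ch in channels:
        if not ch.scaled:
            raise ValueError(f"channel {ch.channel_name} is not scaled")
    first = channels[0]
    for ch in channels[1:]:
        if ch.sample_ids != first.sample_ids or ch.gene_ids != first.gene_ids:
            raise ValueError("channels disagree on sample or gene order")
    for g in first.gene_ids:
        if g not in layout.gene_to_pixel:
            raise ValueError(f"gene {g} missing from layout")

    provided = {ch.channel_name: ch for ch in channels}
    if len(provided) != len(channels):
        raise ValueError("duplicate channel names")
    names = [c for c in CHANNEL_ORDER if c in provided]

    n_samples = len(first.sample_ids)
    img = np.zeros((n_samples, len(names), layout.height, layout.width), dtype=np.float64)
    rows = np.array([layout.gene_to_pixel[g][0] for g in first.gene_ids])
    cols = np.array([layout.gene_to_pixel[g][1] for g in first.gene_ids])
    for ci, name in enumerate(names):
        img[:, ci, rows, cols] = provided[name].values
    return GenomeImage(img, names, layout, list(first.sample_ids))


def table_from_image(image: GenomeImage, gene_ids: Sequence[str] | None = None) -> list[ChannelMatrix]:
    """Exact inverse of :func:`image_from_table` on mapped pixels.

    ``gene_ids`` fixes the column order of the recovered matrices (defaults
    to the layout's genes sorted by pixel position, which matches the
    annotation order for position-ordered layouts but not for shuffled
    ones — pass the annotation order for a strict round trip).
    """
    layout = image.layout
    if gene_ids is None:
        gene_ids = [g for g, _ in sorted(layout.gene_to_pixel.items(), key=lambda kv: kv[1])]
    for g in gene_ids:
        if g not in layout.gene_to_pixel:
            raise ValueError(f"gene {g} not in layout")
    rows = np.array([layout.gene_to_pixel[g][0] for g in gene_ids])
    cols = np.array([layout.gene_to_pixel[g][1] for g in gene_ids])
    out = []
    for ci, name in enumerate(image.channel_names):
        vals = image.values[:, ci, rows, cols]
        out.append(
            ChannelMatrix(name, list(image.sample_ids), list(gene_ids), vals, scaled=True)
        )
    return out


def save_image(image: GenomeImage, path: str | Path) -> None:
    """Persist an image stack as an .npz plus a sidecar layout JSON."""
    path = Path(path)
    np.savez_compressed(
        path,
        values=image.values.astype(np.float32),
        channel_names=np.array(image.channel_names),
        sample_ids=np.array(image.sample_ids),
    )
    image.layout.to_json(path.with_suffix(".layout.json"))


def load_image(path: str | Path) -> GenomeImage:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as d:
        values = d["values"].astype(np.float64)
        channel_names = [str(c) for c in d["channel_names"]]
        sample_ids = [str(s) for s in d["sample_ids"]]
    layout = LayoutSpec.from_json(path.with_suffix(".layout.json"))
    return GenomeImage(values, channel_names, layout, sample_ids)
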