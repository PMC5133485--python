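"""Variant-set construction for the three scan designs.

Single variants, gene-based regions from a glist annotation, and
non-overlapping fixed-width (default 30 kb) windows tiling each chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import GeneAnnotation, GenotypeMatrix
from .preprocess import carrier_filter

logger = logging.getLogger(__name__)

__all__ = ["RegionSet", "gene_regions", "window_regions", "single_variant_regions"]


@dataclass
class RegionSet:
    """A named set of variant indices with genomic bounds."""

    name: str
    chromosome: str
    start: int
    end: int
    variant_indices: list[int]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")

    def __len__(self) -> int:
        return len(self.variant_indices)


def gene_regions(genes: list[GeneAnnotation], gm: GenotypeMatrix) -> list[RegionSet]:
    """One region per gene holding the variants inside its (inclusive) bounds.

    Genes containing no variants are dropped; overlapping genes may share
    variants.  Output order follows chromosome/start so it is invariant to
    the input order of the annotation.
    """
    chroms = gm.chromosomes
    pos = gm.positions
    out: list[RegionSet] = []
    n_empty = 0
    for gene in sorted(genes, key=lambda g: (str(g.chromosome), g.start, g.end, g.name)):
        mask = (chroms == str(gene.chromosome)) & (pos >= gene.start) & (pos <= gene.end)
        idx = np.where(mask)[0]
        if idx.size == 0:
            n_empty += 1
            continue
        out.append(
            RegionSet(
                name=gene.name,
                chromosome=str(gene.chromosome),
                start=gene.start,
                end=gene.end,
                variant_indices=idx.tolist(),
            )
        )
    if n_empty:
        logger.info("gene regions: %d of %d genes contain no variants", n_empty, len(genes))
    return out


def window_regions(
    gm: GenotypeMatrix, width: int = 30_000, anchor: str = "one"
) -> list[RegionSet]:
    """Tile each chromosome with non-overlapping windows of ``width`` bp.

    With ``anchor="one"`` window w covers [(w-1)*width + 1, w*width] from
    coordinate 1; with ``anchor="first-variant"`` the tiling starts at the
    chromosome's first variant position.  Only occupied windows are
    returned; every variant belongs to exactly one window.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    if anchor not in {"one", "first-variant"}:
        raise ValueError("anchor must be 'one' or 'first-variant'")
    chroms = gm.chromosomes
    pos = gm.positions
    out: list[RegionSet] = []
    for chrom in sorted(set(chroms.tolist())):
        idx = np.where(chroms == chrom)[0]
        p = pos[idx]
        origin = 1 if anchor == "one" else int(p.min())
        win = (p - origin) // width  # 0-based window ordinal
        for w in np.unique(win):
            members = idx[win == w].tolist()
            start = origin + int(w) * width
            out.append(
                RegionSet(
                    name=f"{chrom}:{start}-{start + width - 1}",
                    chromosome=chrom,
                    start=start,
                    end=start + width - 1,
                    variant_indices=members,
                )
            )
    return out


def single_variant_regions(gm: GenotypeMatrix, min_carriers: int = 4) -> list[RegionSet]:
    """One singleton region per variant passing the carrier filter."""
    out: list[RegionSet] = []
    for j, v in enumerate(gm.variants):
        if not carrier_filter(gm.dosages[:, j], min_carriers):
            continue
        out.append(
            RegionSet(
                name=v.variant_id,
                chromosome=v.chromosome,
                start=v.position,
                end=v.position,
                variant_indices=[j],
            )
        )
    return out
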