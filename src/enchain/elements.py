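"""Promoter and enhancer definition from peak calls and gene models.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Promoters are strand-aware 2-kb windows around a TSS
(1500 bp upstream, 500 bp downstream); active enhancers are 400-bp
segments centred on H3K27ac peaks that also carry H3K4me1, excluding
anything overlapping promoters, H3K27me3 peaks or blacklisted regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
ENHANCER_LENGTH = 400
DEFAULT_BIN_SIZE = 5000


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open; strand is '+', '-' or None."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # floor of midpoint; for even-length peaks this is the convention
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene model reduced to its TSS, strand and expression level."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    rpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.rpkm < 0:
            raise ValueError(f"gene {self.gene_id}: rpkm must be >= 0")


@dataclass(frozen=True)
class RegulatoryElement:
    """A promoter or enhancer element with its tissue of activity.

    Promoters carry ``gene_id`` and ``tss``; enhancers carry neither.
    """

    element_id: str
    interval: GenomicInterval
    kind: str  # "promoter" | "enhancer"
    tissue: str = ""
    gene_id: str | None = None
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("promoter", "enhancer"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "promoter" and (self.gene_id is None or self.tss is None):
            raise ValueError(f"promoter {self.element_id} needs gene_id and tss")
        if self.kind == "enhancer" and (self.gene_id is not None or self.tss is not None):
            raise ValueError(f"enhancer {self.element_id} must not carry gene fields")

    @property
    def is_promoter(self) -> bool:
        return self.kind == "promoter"

    @property
    def reference_point(self) -> int:
        """TSS for promoters, interval centre for enhancers."""
        return self.tss if self.is_promoter else self.interval.center


# ---------------------------------------------------------------------------
# interval utilities
# ---------------------------------------------------------------------------

def build_interval_trees(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    """Index intervals by chromosome for O(log n) overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlaps_any(iv: GenomicInterval, trees: Mapping[str, IntervalTree]) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


def overlap_bp(iv: GenomicInterval, trees: Mapping[str, IntervalTree]) -> int:
    """Total base pairs of iv covered by at least one indexed interval."""
    tree = trees.get(iv.chrom)
    if tree is None:
        return 0
    hits = sorted(
        (max(h.begin, iv.start), min(h.end, iv.end))
        for h in tree.overlap(iv.start, iv.end)
    )
    covered = 0
    cur_start, cur_end = None, None
    for s, e in hits:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def count_overlap_events(iv: GenomicInterval, trees: Mapping[str, IntervalTree]) -> int:
    tree = trees.get(iv.chrom)
    if tree is None:
        return 0
    return len(tree.overlap(iv.start, iv.end))


# ---------------------------------------------------------------------------
# element definition
# ---------------------------------------------------------------------------

def define_promoters(
    genes: Sequence[GeneRecord],
    chrom_sizes: Mapping[str, int],
    tissue: str = "",
) -> list[RegulatoryElement]:
    """Build one promoter element per distinct (gene_id, tss).

    The window spans 1500 bp upstream and 500 bp downstream of the TSS,
    read strand-aware, clamped to chromosome bounds.  Records on unknown
    chromosomes are rejected with a warning.
    """
    promoters: list[RegulatoryElement] = []
    seen: set[tuple[str, int]] = set()
    for gene in genes:
        size = chrom_sizes.get(gene.chrom)
        if size is None:
            logger.warning("gene %s: unknown chromosome %s, skipped", gene.gene_id, gene.chrom)
            continue
        key = (gene.gene_id, gene.tss)
        if key in seen:
            continue
        seen.add(key)
        if gene.strand == "+":
            start, end = gene.tss - PROMOTER_UPSTREAM, gene.tss + PROMOTER_DOWNSTREAM
        else:
            start, end = gene.tss - PROMOTER_DOWNSTREAM, gene.tss + PROMOTER_UPSTREAM
        start, end = max(0, start), min(size, end)
        promoters.append(
            RegulatoryElement(
                element_id=f"P:{gene.gene_id}:{gene.tss}",
                interval=GenomicInterval(gene.chrom, start, end, gene.strand),
                kind="promoter",
                tissue=tissue,
                gene_id=gene.gene_id,
                tss=gene.tss,
            )
        )
    return promoters


def define_enhancers(
    h3k27ac: Sequence[GenomicInterval],
    h3k4me1: Sequence[GenomicInterval],
    promoters: Sequence[RegulatoryElement],
    h3k27me3: Sequence[GenomicInterval] = (),
    blacklist: Sequence[GenomicInterval] = (),
    tissue: str = "",
) -> list[RegulatoryElement]:
    """Call active enhancers as 400-bp segments centred on H3K27ac peaks.

    The centred segment must overlap at least one H3K4me1 peak and must not
    overlap any promoter, H3K27me3 peak or blacklisted region.  The output
    is sorted by coordinate and independent of input peak ordering.
    """
    me1_trees = build_interval_trees(h3k4me1)
    exclusion = build_interval_trees(
        [p.interval for p in promoters] + list(h3k27me3) + list(blacklist)
    )
    enhancers: list[RegulatoryElement] = []
    seen: set[tuple[str, int]] = set()
    for peak in sorted(h3k27ac, key=lambda p: (p.chrom, p.start, p.end)):
        center = peak.center
        start = center - ENHANCER_LENGTH // 2
        if start < 0:
            start = 0
        segment = GenomicInterval(peak.chrom, start, start + ENHANCER_LENGTH)
        if not overlaps_any(segment, me1_trees):
            continue
        if overlaps_any(segment, exclusion):
            continue
        key = (segment.chrom, segment.start)
        if key in seen:  # identical centres collapse to one element
            continue
        seen.add(key)
        enhancers.append(
            RegulatoryElement(
                element_id=f"E:{segment.chrom}:{segment.start}",
                interval=segment,
                kind="enhancer",
                tissue=tissue,
            )
        )
    return enhancers


def map_elements_to_bins(
    elements: Sequence[RegulatoryElement],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> dict[str, set[int]]:
    """Map each element to the start positions of every bin it overlaps."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    mapping: dict[str, set[int]] = {}
    for el in elements:
        first = (el.interval.start // bin_size) * bin_size
        last = ((el.interval.end - 1) // bin_size) * bin_size
        mapping[el.element_id] = set(range(first, last + bin_size, bin_size))
    return mapping


def count_skipped_genes(
    enhancer: RegulatoryElement,
    target: GeneRecord,
    genes: Sequence[GeneRecord],
) -> int:
    """Number of distinct genes whose TSS lies strictly between the
    enhancer centre and the target TSS (the target itself excluded)."""
    if enhancer.interval.chrom != target.chrom:
        raise ValueError("enhancer and target gene are on different chromosomes")
    lo, hi = sorted((enhancer.interval.center, target.tss))
    skipped = {
        g.gene_id
        for g in genes
        if g.chrom == target.chrom
        and g.gene_id != target.gene_id
        and lo < g.tss < hi
    }
    return len(skipped)
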