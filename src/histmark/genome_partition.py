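"""Partition a genome into proximal promoters, exons, introns, intergenic.

The four classes follow the standard annotation-based decomposition used
for histone-mark island distributions: the proximal promoter is the
+-1 kb window around each transcript's TSS, exons are the union of
annotated exon blocks, introns are gene bodies minus exons, and
intergenic is everything not covered by a promoter or a gene body.

Classes may overlap (a promoter window typically covers the first exon);
interval classification resolves ties by precedence
promoter > exon > intron > intergenic (an alternative maximal-overlap
mode is available), so every interval gets exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Sequence, Tuple

from intervaltree import IntervalTree

from ._intervals import Span, complement_spans, merge_spans, subtract_spans
from .core import ChromSizes, GeneModel, GenomicInterval, Peak, validate_chrom_sizes


class RegionClass(str, Enum):
    PROXIMAL_PROMOTER = "proximal_promoter"
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"


#: classification precedence, highest first
PRECEDENCE: Tuple[RegionClass, ...] = (
    RegionClass.PROXIMAL_PROMOTER,
    RegionClass.EXON,
    RegionClass.INTRON,
    RegionClass.INTERGENIC,
)


class PartitionError(ValueError):
    pass


@dataclass
class GenomePartition:
    """Per-chromosome merged interval sets for each region class.

    ``promoter_registry`` maps each merged promoter interval to the gene
    models whose TSS windows contributed to it; one promoter may be
    associated with several genes.
    """

    sizes: ChromSizes
    promoter_halfwidth: int
    classes: Dict[str, Dict[RegionClass, List[Span]]]
    promoter_registry: Dict[GenomicInterval, List[GeneModel]]
    _trees: Dict[str, Dict[RegionClass, IntervalTree]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, per_class in self.classes.items():
            self._trees[chrom] = {
                cls: IntervalTree.from_tuples(spans) if spans else IntervalTree()
                for cls, spans in per_class.items()
            }

    def class_spans(self, chrom: str, cls: RegionClass) -> List[Span]:
        return self.classes[chrom][cls]

    def resolved_spans(self, chrom: str) -> Dict[RegionClass, List[Span]]:
        """Disjoint per-class spans after precedence resolution.

        Every base of the chromosome falls in exactly one resolved class.
        """
        per = self.classes[chrom]
        promoter = per[RegionClass.PROXIMAL_PROMOTER]
        exon = subtract_spans(per[RegionClass.EXON], promoter)
        intron = subtract_spans(
            subtract_spans(per[RegionClass.INTRON], promoter),
            per[RegionClass.EXON],
        )
        return {
            RegionClass.PROXIMAL_PROMOTER: promoter,
            RegionClass.EXON: exon,
            RegionClass.INTRON: intron,
            RegionClass.INTERGENIC: per[RegionClass.INTERGENIC],
        }

    def overlap_bp(self, iv: GenomicInterval, cls: RegionClass) -> int:
        trees = self._trees.get(iv.chrom)
        if trees is None:
            raise PartitionError(f"unknown chromosome {iv.chrom!r}")
        total = 0
        for hit in trees[cls].overlap(iv.start, iv.end):
            total += min(hit.end, iv.end) - max(hit.begin, iv.start)
        return total

    def promoters(self) -> List[GenomicInterval]:
        return sorted(self.promoter_registry, key=lambda iv: (iv.chrom, iv.start))


@dataclass
class DistributionReport:
    """Island counts and percentages per region class (cf. a four-slice
    genome-distribution panel)."""

    counts: Dict[RegionClass, int]
    total: int

    @property
    def percents(self) -> Dict[RegionClass, float]:
        return {cls: 100.0 * n / self.total for cls, n in self.counts.items()}

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "region_class": cls.value,
                "count": self.counts[cls],
                "percent": round(self.percents[cls], 2),
            }
            for cls in PRECEDENCE
        ]
        return pd.DataFrame(rows)

    def to_dict(self):
        return {
            "total": self.total,
            "counts": {cls.value: self.counts[cls] for cls in PRECEDENCE},
            "percents": {cls.value: self.percents[cls] for cls in PRECEDENCE},
        }


def build_partition(
    genes: Sequence[GeneModel],
    sizes: ChromSizes,
    promoter_halfwidth: int = 1000,
    strand_aware_tss: bool = True,
) -> GenomePartition:
    """Build the four-class partition from transcript models.

    Promoters are [TSS - halfwidth, TSS + halfwidth) clipped to
    chromosome bounds; same-class intervals from overlapping transcripts
    are merged. ``promoter_halfwidth=0`` yields an empty promoter class.
    """
    validate_chrom_sizes(sizes)
    if promoter_halfwidth < 0:
        raise PartitionError("promoter_halfwidth must be >= 0")

    promoter_windows: Dict[str, List[Tuple[Span, GeneModel]]] = {c: [] for c in sizes}
    exon_spans: Dict[str, List[Span]] = {c: [] for c in sizes}
    body_spans: Dict[str, List[Span]] = {c: [] for c in sizes}

    for g in genes:
        if g.chrom not in sizes:
            raise PartitionError(
                f"transcript {g.transcript_id} on unknown chromosome {g.chrom!r}"
            )
        length = sizes[g.chrom]
        if g.tx_start < 0 or g.tx_end > length:
            raise PartitionError(
                f"transcript {g.transcript_id} outside chromosome bounds "
                f"[0, {length})"
            )
        if promoter_halfwidth > 0:
            tss = g.tss(strand_aware=strand_aware_tss)
            lo = max(0, tss - promoter_halfwidth)
            hi = min(length, tss + promoter_halfwidth)
            if hi > lo:
                promoter_windows[g.chrom].append(((lo, hi), g))
        body_spans[g.chrom].append((g.tx_start, g.tx_end))
        exon_spans[g.chrom].extend((e.start, e.end) for e in g.exons)

    classes: Dict[str, Dict[RegionClass, List[Span]]] = {}
    registry: Dict[GenomicInterval, List[GeneModel]] = {}
    for chrom, length in sizes.items():
        promoters = merge_spans(s for s, _ in promoter_windows[chrom])
        exons = merge_spans(exon_spans[chrom])
        bodies = merge_spans(body_spans[chrom])
        introns = subtract_spans(bodies, exons)
        covered = merge_spans(promoters + bodies)
        intergenic = complement_spans(covered, length)
        classes[chrom] = {
            RegionClass.PROXIMAL_PROMOTER: promoters,
            RegionClass.EXON: exons,
            RegionClass.INTRON: introns,
            RegionClass.INTERGENIC: intergenic,
        }
        # map each merged promoter interval to every contributing gene
        for span in promoters:
            iv = GenomicInterval(chrom, *span)
            registry[iv] = [
                g
                for (lo, hi), g in promoter_windows[chrom]
                if lo < span[1] and hi > span[0]
            ]

    return GenomePartition(
        sizes=dict(sizes),
        promoter_halfwidth=promoter_halfwidth,
        classes=classes,
        promoter_registry=registry,
    )


def classify_interval(
    partition: GenomePartition,
    iv: GenomicInterval,
    mode: str = "precedence",
) -> RegionClass:
    """Assign one region class to an interval.

    ``precedence`` (default): the highest-precedence class with >= 1 bp
    overlap wins (promoter > exon > intron > intergenic).
    ``max_overlap``: the class covering the most bases wins, with the
    precedence order breaking ties.
    """
    if iv.chrom not in partition.classes:
        raise PartitionError(f"unknown chromosome {iv.chrom!r}")
    if mode == "precedence":
        for cls in PRECEDENCE:
            if partition.overlap_bp(iv, cls) > 0:
                return cls
        return RegionClass.INTERGENIC  # interval beyond chromosome end
    if mode == "max_overlap":
        best = RegionClass.INTERGENIC
        best_bp = -1
        for cls in PRECEDENCE:  # precedence order -> ties go to higher class
            bp = partition.overlap_bp(iv, cls)
            if bp > best_bp:
                best, best_bp = cls, bp
        return best
    raise ValueError(f"unknown classification mode {mode!r}")


def distribution_report(
    partition: GenomePartition,
    peaks: Sequence[Peak],
    mode: str = "precedence",
) -> DistributionReport:
    """Count islands per region class (each island classified once)."""
    if not peaks:
        raise PartitionError("cannot report a distribution for zero islands")
    counts = {cls: 0 for cls in PRECEDENCE}
    for p in peaks:
        counts[classify_interval(partition, p.interval, mode=mode)] += 1
    return DistributionReport(counts=counts, total=len(peaks))
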