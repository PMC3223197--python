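"""Common vs lineage-specific island classification and enrichment correlation.

Two islands are "common" when they share at least 1 bp (half-open
overlap); an island with no partner in the other set is
lineage-specific. Commonness is counted per side — one island may
partner several on the other side, which is why the two sides of a
comparison can report different common counts.

Promoter enrichment ratios (peak tag count / promoter length, tags per
bp) are the quantity correlated between lineages and between marks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import GenomicInterval, Peak, TagLibrary
from ._intervals import TagIndex, merge_spans
from .genome_partition import GenomePartition


class ComparisonError(ValueError):
    pass


@dataclass
class ComparisonResult:
    """Partition of two peak sets into common pairs and specific sets."""

    common_pairs: List[Tuple[Peak, Peak]]
    common_a: List[Peak]
    common_b: List[Peak]
    specific_a: List[Peak]
    specific_b: List[Peak]

    @property
    def n_common_a(self) -> int:
        return len(self.common_a)

    @property
    def n_common_b(self) -> int:
        return len(self.common_b)

    def to_dict(self) -> Dict[str, int]:
        return {
            "common_pairs": len(self.common_pairs),
            "common_A": len(self.common_a),
            "common_B": len(self.common_b),
            "specific_A": len(self.specific_a),
            "specific_B": len(self.specific_b),
            "total_A": len(self.common_a) + len(self.specific_a),
            "total_B": len(self.common_b) + len(self.specific_b),
        }


def compare_peak_sets(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> ComparisonResult:
    """Classify each island as common (>= 1 bp overlap partner) or specific."""
    trees: Dict[str, IntervalTree] = {}
    for j, p in enumerate(peaks_b):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, j)

    pairs: List[Tuple[Peak, Peak]] = []
    matched_b: Set[int] = set()
    common_a: List[Peak] = []
    specific_a: List[Peak] = []
    for p in peaks_a:
        hits = trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end)
        if hits:
            common_a.append(p)
            for h in sorted(hits, key=lambda h: (h.begin, h.end, h.data)):
                pairs.append((p, peaks_b[h.data]))
                matched_b.add(h.data)
        else:
            specific_a.append(p)
    common_b = [p for j, p in enumerate(peaks_b) if j in matched_b]
    specific_b = [p for j, p in enumerate(peaks_b) if j not in matched_b]
    return ComparisonResult(pairs, common_a, common_b, specific_a, specific_b)


#: cross-mark comparison (e.g. me1 vs me3 islands of one cell type) uses
#: the identical overlap contract; the per-side counts are asymmetric.
cross_mark_comparison = compare_peak_sets


@dataclass
class EnrichmentRecord:
    """Tag-density ratio of one unit (promoter/peak/gene) in two libraries."""

    unit_id: str
    interval: GenomicInterval
    ratio_a: float
    ratio_b: float
    gene_symbols: Tuple[str, ...] = ()


def _peaks_by_chrom(peaks: Sequence[Peak]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def _ratio(
    promoter: GenomicInterval,
    trees: Dict[str, IntervalTree],
    index: TagIndex,
    combine: str,
    scale: float,
) -> Tuple[float, bool]:
    hits = trees.get(promoter.chrom, IntervalTree()).overlap(
        promoter.start, promoter.end
    )
    if not hits:
        return 0.0, False
    # count tags inside the union of overlapping peaks (avoids double
    # counting if a caller ever emits overlapping islands)
    if combine == "sum":
        spans = merge_spans((h.begin, h.end) for h in hits)
        total = sum(index.count(promoter.chrom, s, e) for s, e in spans)
    elif combine == "max":
        total = max(index.count(promoter.chrom, h.begin, h.end) for h in hits)
    else:
        raise ComparisonError(f"unknown combine mode {combine!r}")
    return scale * total / promoter.length, True


def promoter_mark_table(
    partition: GenomePartition,
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    tags_a: TagLibrary,
    tags_b: TagLibrary,
    combine: str = "sum",
    cpm: bool = False,
) -> List[EnrichmentRecord]:
    """One enrichment record per promoter overlapped by >= 1 peak in
    either lineage.

    ratio_X = (tags of library X inside the promoter-overlapping peaks
    of lineage X) / promoter length in bp. A promoter with no peak in a
    lineage gets ratio 0 there; a promoter with no peak in either
    lineage is excluded. ``cpm=True`` rescales each ratio by
    1e6/total_reads of its library.
    """
    trees_a = _peaks_by_chrom(peaks_a)
    trees_b = _peaks_by_chrom(peaks_b)
    index_a = TagIndex(tags_a.tags)
    index_b = TagIndex(tags_b.tags)
    scale_a = 1e6 / tags_a.total_reads if cpm else 1.0
    scale_b = 1e6 / tags_b.total_reads if cpm else 1.0

    records: List[EnrichmentRecord] = []
    for promoter in partition.promoters():
        ra, hit_a = _ratio(promoter, trees_a, index_a, combine, scale_a)
        rb, hit_b = _ratio(promoter, trees_b, index_b, combine, scale_b)
        if not (hit_a or hit_b):
            continue
        genes = sorted(
            {
                sym
                for g in partition.promoter_registry[promoter]
                for sym in g.gene_symbols
            }
        )
        records.append(
            EnrichmentRecord(
                unit_id=str(promoter),
                interval=promoter,
                ratio_a=ra,
                ratio_b=rb,
                gene_symbols=tuple(genes),
            )
        )
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "genes": ",".join(r.gene_symbols),
                "ratio_A": r.ratio_a,
                "ratio_B": r.ratio_b,
            }
            for r in sorted(records, key=lambda r: (r.interval.chrom, r.interval.start))
        ]
    )


def marked_promoters(
    partition: GenomePartition, peaks: Sequence[Peak]
) -> List[GenomicInterval]:
    """Promoters with >= 1 bp overlap by >= 1 island (no tag-count minimum)."""
    trees = _peaks_by_chrom(peaks)
    return [
        prom
        for prom in partition.promoters()
        if trees.get(prom.chrom, IntervalTree()).overlap(prom.start, prom.end)
    ]


@dataclass
class GeneVenn:
    """Gene-level Venn partition between two lineages."""

    common_genes: Set[str]
    specific_a_genes: Set[str]
    specific_b_genes: Set[str]

    def to_dict(self) -> Dict[str, object]:
        return {
            "common": sorted(self.common_genes),
            "specific_A": sorted(self.specific_a_genes),
            "specific_B": sorted(self.specific_b_genes),
            "n_common": len(self.common_genes),
            "n_specific_A": len(self.specific_a_genes),
            "n_specific_B": len(self.specific_b_genes),
        }


def gene_venn(
    marked_promoters_a: Sequence[GenomicInterval],
    marked_promoters_b: Sequence[GenomicInterval],
    partition: GenomePartition,
) -> GeneVenn:
    """Compare the genes associated with each lineage's marked promoters.

    A promoter maps to one or more genes; a gene is counted once
    regardless of how many transcripts or promoters carry it.
    """

    def genes_of(promoters: Sequence[GenomicInterval]) -> Set[str]:
        out: Set[str] = set()
        for prom in promoters:
            for g in partition.promoter_registry[prom]:
                out.update(g.gene_symbols)
        return out

    a = genes_of(marked_promoters_a)
    b = genes_of(marked_promoters_b)
    return GeneVenn(a & b, a - b, b - a)


def enrichment_correlation(
    records: Sequence[EnrichmentRecord], method: str = "pearson"
) -> Tuple[float, int]:
    """Correlation of (ratio_A, ratio_B) across units; returns (r, n).

    Pearson on the raw ratios by default; ``spearman`` and
    ``log_pearson`` (log1p-transformed) are alternatives.
    """
    if len(records) < 3:
        raise ComparisonError("need >= 3 records for a correlation")
    x = np.array([r.ratio_a for r in records], dtype=float)
    y = np.array([r.ratio_b for r in records], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ComparisonError("zero variance on one axis; correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    elif method == "log_pearson":
        r = stats.pearsonr(np.log1p(x), np.log1p(y)).statistic
    else:
        raise ComparisonError(f"unknown correlation method {method!r}")
    return float(r), len(records)
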