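"""Synthetic genomes, planted island architectures, and tag libraries.

The generator emulates the statistical structure a two-lineage histone-
mark comparison assumes: a gene annotation on a toy genome, a set of
enrichment loci planted per mark with a chosen genomic-class mixture
(promoter-heavy for an H3K4me3-like mark, intron-heavy for an
H3K4me1-like mark), a chosen fraction of loci shared between the two
cell types, and tag libraries sampled from a piecewise-constant rate
(uniform background, ``enrichment_fold`` x background inside planted
loci). Ground-truth labels for every planted locus, marked promoter and
gene make downstream recovery measurable.

It does not model read sequences, mappability or GC bias, or duplicate
structure: tags are ideal fragment-length intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ChromSizes, GeneModel, GenomicInterval, Peak, Tag, TagLibrary
from .genome_partition import (
    GenomePartition,
    RegionClass,
    build_partition,
    classify_interval,
)
from .peak_comparison import GeneVenn, gene_venn, marked_promoters


class SimulationError(ValueError):
    pass


def _stable_code(name: str) -> int:
    """Deterministic small integer from a string (independent of hash seed)."""
    code = 0
    for ch in name:
        code = (code * 131 + ord(ch)) % (2**31 - 1)
    return code


@dataclass
class ArchitectureParams:
    """Study conditions for one mark's synthetic architecture.

    class_mixture gives the probability that a planted locus falls in
    each genomic class; share_fraction is the probability a locus is
    common to both cell types (otherwise it belongs to one cell type,
    chosen uniformly); enrichment_fold is the mean in-locus over
    background tag rate. Each locus draws its own fold from a
    mean-preserving lognormal with sigma fold_dispersion — peak heights
    vary between loci but are identical across cell types at a common
    locus, which is what makes cross-lineage enrichment ratios
    correlate for a shared mark (set 0 for uniform heights).
    library_size tags are drawn per (cell type, mark).
    placement_margin keeps each planted locus that many bases inside its
    class interval so a called island that spreads by about one
    fragment still classifies to the planted class.
    """

    mark: str = "H3K4me3"
    n_genes: int = 200
    chrom_lengths: ChromSizes = field(
        default_factory=lambda: {"chrS1": 10_000_000}
    )
    promoter_halfwidth: int = 1000
    class_mixture: Dict[RegionClass, float] = field(
        default_factory=lambda: {
            RegionClass.PROXIMAL_PROMOTER: 0.45,
            RegionClass.EXON: 0.10,
            RegionClass.INTRON: 0.20,
            RegionClass.INTERGENIC: 0.25,
        }
    )
    share_fraction: float = 0.5
    enrichment_fold: float = 20.0
    fold_dispersion: float = 0.5
    background_rate: float = 0.001
    library_size: int = 200_000
    fragment_length: int = 200
    n_peaks_per_mark: int = 300
    peak_width: int = 1000
    placement_margin: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"class mixture sums to {total}, expected 1")
        if not 0.0 <= self.share_fraction <= 1.0:
            raise SimulationError("share_fraction must be in [0, 1]")
        if self.enrichment_fold <= 1:
            raise SimulationError("enrichment_fold must exceed 1")


def me3_like(**overrides) -> ArchitectureParams:
    """Promoter-heavy, high cross-lineage share: a tri-methylation-like
    architecture (active-promoter mark, largely shared between related
    T-cell lineages)."""
    params = ArchitectureParams(
        mark="H3K4me3",
        class_mixture={
            RegionClass.PROXIMAL_PROMOTER: 0.45,
            RegionClass.EXON: 0.10,
            RegionClass.INTRON: 0.20,
            RegionClass.INTERGENIC: 0.25,
        },
        share_fraction=0.8,
    )
    return replace(params, **overrides)


def me1_like(**overrides) -> ArchitectureParams:
    """Intron/intergenic-heavy, low share: a mono-methylation-like
    architecture (enhancer mark, largely lineage-specific)."""
    params = ArchitectureParams(
        mark="H3K4me1",
        class_mixture={
            RegionClass.PROXIMAL_PROMOTER: 0.10,
            RegionClass.EXON: 0.05,
            RegionClass.INTRON: 0.55,
            RegionClass.INTERGENIC: 0.30,
        },
        share_fraction=0.3,
    )
    return replace(params, **overrides)


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(
    params: ArchitectureParams,
) -> Tuple[ChromSizes, List[GeneModel]]:
    """Place non-overlapping gene models (2-10 exons, both strands).

    Deterministic under ``params.seed``. Gene lengths are drawn from
    10-40 kb (long enough that introns can host planted loci); genes
    are separated by at least 2 x promoter_halfwidth + 2 kb so
    promoters never merge across genes.
    """
    rng = np.random.default_rng([params.seed % (2**31), _stable_code("genome")])
    sizes = dict(params.chrom_lengths)
    if params.n_genes == 0:
        return sizes, []

    chroms = sorted(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(params.n_genes, weights / weights.sum())

    min_gap = 2 * params.promoter_halfwidth + 2000
    edge = params.promoter_halfwidth + 1000
    genes: List[GeneModel] = []
    counter = 0
    for chrom, n in zip(chroms, alloc):
        if n == 0:
            continue
        length = sizes[chrom]
        gene_lens = rng.integers(10000, 40001, size=n)
        needed = int(gene_lens.sum()) + (n + 1) * min_gap + 2 * edge
        if needed > length:
            raise SimulationError(
                f"cannot pack {n} genes into {chrom} ({length} bp); "
                f"need >= {needed} bp"
            )
        slack = length - needed
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = edge
        for i in range(n):
            pos += min_gap + int(extra[i])
            start = pos
            end = start + int(gene_lens[i])
            pos = end
            counter += 1
            genes.append(
                _make_gene(rng, chrom, start, end, f"G{counter:04d}")
            )
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return sizes, genes


def _make_gene(
    rng: np.random.Generator, chrom: str, start: int, end: int, symbol: str
) -> GeneModel:
    L = end - start
    n_exons = int(rng.integers(2, 7))
    n_seg = 2 * n_exons - 1  # exon, intron, exon, ...
    min_seg = 50
    extra = rng.multinomial(L - n_seg * min_seg, np.full(n_seg, 1.0 / n_seg))
    seg_lens = extra + min_seg
    bounds = start + np.concatenate([[0], np.cumsum(seg_lens)])
    exons = tuple(
        GenomicInterval(chrom, int(bounds[2 * i]), int(bounds[2 * i + 1]))
        for i in range(n_exons)
    )
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(
        transcript_id=f"T{symbol[1:]}",
        gene_symbols=(symbol,),
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        exons=exons,
    )


# ---------------------------------------------------------------------------
# architecture planting


@dataclass(frozen=True)
class PlantedPeak:
    interval: GenomicInterval
    region_class: RegionClass
    label: str  # "common" | "specific_A" | "specific_B"
    fold: float = 20.0  # this locus's enrichment over background


@dataclass
class PlantedTruth:
    """Ground truth of one mark's planted architecture."""

    mark: str
    peaks: List[PlantedPeak]
    partition: GenomePartition

    def peaks_for_cell(self, cell: str) -> List[PlantedPeak]:
        want = {"common", f"specific_{cell}"}
        return sorted(
            (p for p in self.peaks if p.label in want),
            key=lambda p: (p.interval.chrom, p.interval.start),
        )

    def intervals_for_cell(self, cell: str) -> List[GenomicInterval]:
        """Planted loci present in cell 'A' or 'B'."""
        return [p.interval for p in self.peaks_for_cell(cell)]

    def as_peaks(self, cell: str) -> List[Peak]:
        return [Peak(interval=iv) for iv in self.intervals_for_cell(cell)]

    @property
    def realized_share(self) -> float:
        if not self.peaks:
            return 0.0
        return sum(p.label == "common" for p in self.peaks) / len(self.peaks)

    @property
    def realized_mixture(self) -> Dict[RegionClass, float]:
        n = len(self.peaks)
        return {
            cls: sum(p.region_class is cls for p in self.peaks) / n
            for cls in RegionClass
        }

    def marked_promoters_for_cell(self, cell: str) -> List[GenomicInterval]:
        return marked_promoters(self.partition, self.as_peaks(cell))

    def expected_gene_venn(self) -> GeneVenn:
        return gene_venn(
            self.marked_promoters_for_cell("A"),
            self.marked_promoters_for_cell("B"),
            self.partition,
        )


def plant_architecture(
    genome: Tuple[ChromSizes, List[GeneModel]],
    params: ArchitectureParams,
) -> PlantedTruth:
    """Draw planted enrichment loci per the class mixture and share fraction.

    Each locus sits entirely inside one precedence-resolved class
    interval, at least ``placement_margin`` bp from its edges, and at
    least 1 kb from every other planted locus of the same mark, so
    planted class labels survive peak calling and islands never merge.
    """
    sizes, genes = genome
    rng = np.random.default_rng(
        [params.seed % (2**31), _stable_code("plant"), _stable_code(params.mark)]
    )
    partition = build_partition(genes, sizes, params.promoter_halfwidth)

    # eligible resolved spans per class
    eligible: Dict[RegionClass, List[Tuple[str, int, int]]] = {
        cls: [] for cls in RegionClass
    }
    need = params.peak_width + 2 * params.placement_margin
    for chrom in sorted(sizes):
        for cls, spans in partition.resolved_spans(chrom).items():
            eligible[cls].extend(
                (chrom, s, e) for s, e in spans if e - s >= need
            )

    # stratified quotas: realized class proportions and share fraction
    # match the parameters exactly (up to rounding), so recovery error
    # measures the pipeline, not multinomial sampling noise
    class_order = list(RegionClass)
    quotas = _largest_remainder(
        [params.class_mixture.get(c, 0.0) for c in class_order],
        params.n_peaks_per_mark,
    )
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in sizes}
    min_sep = 1000

    planted: List[Tuple[GenomicInterval, RegionClass]] = []
    for cls, quota in zip(class_order, quotas):
        spans = eligible[cls]
        if quota > 0 and not spans:
            raise SimulationError(f"no {cls.value} interval can host a locus")
        for _ in range(quota):
            w = np.array([e - s - need + 1 for _, s, e in spans], dtype=float)
            interval = None
            for _attempt in range(500):
                k = int(rng.choice(len(spans), p=w / w.sum()))
                chrom, s, e = spans[k]
                start = int(
                    rng.integers(s + params.placement_margin,
                                 e - params.placement_margin - params.peak_width + 1)
                )
                end = start + params.peak_width
                if all(
                    start - min_sep >= pe or end + min_sep <= ps
                    for ps, pe in placed[chrom]
                ):
                    interval = GenomicInterval(chrom, start, end)
                    break
            if interval is None:
                raise SimulationError(
                    f"cannot place a {cls.value} locus: class space exhausted"
                )
            placed[chrom].append((interval.start, interval.end))
            planted.append((interval, cls))

    n = len(planted)
    n_common = int(round(params.share_fraction * n))
    n_specific = n - n_common
    labels = (
        ["common"] * n_common
        + ["specific_A"] * (n_specific - n_specific // 2)
        + ["specific_B"] * (n_specific // 2)
    )
    rng.shuffle(labels)
    # per-locus enrichment: mean-preserving lognormal around the mean fold
    sigma = params.fold_dispersion
    if sigma > 0:
        folds = params.enrichment_fold * np.exp(
            sigma * rng.standard_normal(n) - sigma**2 / 2
        )
    else:
        folds = np.full(n, params.enrichment_fold)
    folds = np.maximum(folds, 2.0)  # every locus stays detectable
    peaks = [
        PlantedPeak(interval, cls, label, float(fold))
        for (interval, cls), label, fold in zip(planted, labels, folds)
    ]
    return PlantedTruth(mark=params.mark, peaks=peaks, partition=partition)


def _largest_remainder(probs: Sequence[float], total: int) -> List[int]:
    raw = [p * total for p in probs]
    counts = [int(x) for x in raw]
    short = total - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# tag generation


def generate_tags(
    truth: PlantedTruth, params: ArchitectureParams, cell: str
) -> TagLibrary:
    """Sample one cell type's tag library from the planted architecture.

    The sampling rate is background_rate outside planted loci and
    fold x background_rate inside locus i (each locus carries its own
    fold); fragment-length tags are centred on rate-weighted positions
    until library_size is reached. Deterministic under (seed, cell, mark).
    """
    if params.library_size <= 0:
        raise SimulationError("library_size must be positive")
    if cell not in ("A", "B"):
        raise SimulationError(f"cell must be 'A' or 'B', got {cell!r}")
    rng = np.random.default_rng(
        [params.seed % (2**31), _stable_code("tags"),
         _stable_code(params.mark), _stable_code(cell)]
    )
    sizes = truth.partition.sizes
    loci = truth.peaks_for_cell(cell)

    # piecewise-constant rate segments over the whole genome
    seg_chrom: List[str] = []
    seg_start: List[int] = []
    seg_end: List[int] = []
    seg_rate: List[float] = []
    by_chrom: Dict[str, List[PlantedPeak]] = {c: [] for c in sizes}
    for p in loci:
        by_chrom[p.interval.chrom].append(p)
    for chrom in sorted(sizes):
        pos = 0
        for p in sorted(by_chrom[chrom], key=lambda p: p.interval.start):
            iv = p.interval
            if iv.start > pos:
                seg_chrom.append(chrom)
                seg_start.append(pos)
                seg_end.append(iv.start)
                seg_rate.append(params.background_rate)
            seg_chrom.append(chrom)
            seg_start.append(iv.start)
            seg_end.append(iv.end)
            seg_rate.append(params.background_rate * p.fold)
            pos = iv.end
        if pos < sizes[chrom]:
            seg_chrom.append(chrom)
            seg_start.append(pos)
            seg_end.append(sizes[chrom])
            seg_rate.append(params.background_rate)

    starts = np.asarray(seg_start, dtype=np.int64)
    ends = np.asarray(seg_end, dtype=np.int64)
    weights = np.asarray(seg_rate) * (ends - starts)
    probs = weights / weights.sum()

    idx = rng.choice(len(starts), size=params.library_size, p=probs)
    offsets = rng.random(params.library_size) * (ends[idx] - starts[idx])
    mids = starts[idx] + offsets.astype(np.int64)
    strands = rng.random(params.library_size) < 0.5

    half = params.fragment_length // 2
    tags: List[Tag] = []
    for i in range(params.library_size):
        chrom = seg_chrom[idx[i]]
        limit = sizes[chrom]
        s = max(0, int(mids[i]) - half)
        e = min(limit, s + params.fragment_length)
        s = max(0, e - params.fragment_length)
        tags.append(Tag(chrom, s, e, "+" if strands[i] else "-"))
    return TagLibrary(tags=tags, mark=params.mark, cell_type=cell)


def simulate_mark(
    params: ArchitectureParams,
    genome: Optional[Tuple[ChromSizes, List[GeneModel]]] = None,
) -> Tuple[Tuple[ChromSizes, List[GeneModel]], PlantedTruth, TagLibrary, TagLibrary]:
    """Genome (generated unless given), planted truth, and both cell
    types' tag libraries for one mark."""
    if genome is None:
        genome = generate_genome(params)
    truth = plant_architecture(genome, params)
    tags_a = generate_tags(truth, params, "A")
    tags_b = generate_tags(truth, params, "B")
    return genome, truth, tags_a, tags_b
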