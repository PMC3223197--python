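"""Core coordinate types shared by every stage of the pipeline.

All coordinates are 0-based half-open (BED convention) internally.
Browser-style region strings such as ``ChrX:49001620-49002192`` are
1-based inclusive and are converted exactly once, at the parse boundary
(:func:`parse_region`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

#: chromosome name -> length in bp
ChromSizes = Dict[str, int]


class CoordinateError(ValueError):
    """Raised for malformed or out-of-bounds genomic coordinates."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CoordinateError("chrom must be non-empty")
        if self.start < 0:
            raise CoordinateError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise CoordinateError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.end > other.start
            and other.end > self.start
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


_REGION_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*([\d,]+)\s*[-–]\s*([\d,]+)\s*$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a browser-style ``chrom:A-B`` region string.

    The string is interpreted as 1-based inclusive (the convention of
    genome-browser coordinate displays) and converted to the internal
    0-based half-open form ``[A-1, B)``. Thousands separators and an
    en-dash are tolerated.
    """
    m = _REGION_RE.match(text)
    if m is None:
        raise CoordinateError(f"cannot parse region string {text!r}")
    chrom = m.group(1)
    a = int(m.group(2).replace(",", ""))
    b = int(m.group(3).replace(",", ""))
    if a < 1 or b < a:
        raise CoordinateError(f"bad 1-based inclusive range {a}-{b}")
    return GenomicInterval(chrom, a - 1, b)


@dataclass(frozen=True)
class Tag:
    """A single mapped sequencing read, with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise CoordinateError(
                f"bad tag interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class TagLibrary:
    """A library of uniquely mapped tags for one (cell type, mark) pair.

    ``total_reads`` is the normalisation denominator used by the metagene
    tag-density formula and, optionally, by CPM scaling of enrichment
    ratios.
    """

    tags: List[Tag]
    mark: str = ""
    cell_type: str = ""

    @property
    def total_reads(self) -> int:
        return len(self.tags)

    def chromosomes(self) -> List[str]:
        return sorted({t.chrom for t in self.tags})


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: body span, strand, exon blocks, gene symbol(s).

    ``tx_start``/``tx_end`` follow annotation-table semantics: both are
    0-based half-open chromosome coordinates with ``tx_start < tx_end``
    regardless of strand. The biological transcription start site is
    strand dependent (see :meth:`tss`).
    """

    transcript_id: str
    gene_symbols: Tuple[str, ...]
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise CoordinateError(
                f"{self.transcript_id}: txEnd must exceed txStart"
            )
        prev_end = self.tx_start - 1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise CoordinateError(
                    f"{self.transcript_id}: exon chromosome mismatch"
                )
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise CoordinateError(
                    f"{self.transcript_id}: exon {ex} outside transcript span"
                )
            if ex.start <= prev_end:
                raise CoordinateError(
                    f"{self.transcript_id}: exons not sorted/disjoint at {ex}"
                )
            prev_end = ex.end

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)

    def tss(self, strand_aware: bool = True) -> int:
        """Transcription start site as a single base position.

        Strand-aware (default): txStart for + transcripts, txEnd-1 (the
        last covered base, i.e. the biological 5' end) for - transcripts.
        With ``strand_aware=False`` txStart is returned for both strands,
        reproducing a strand-ignorant reading of annotation tables.
        """
        if strand_aware and self.strand == "-":
            return self.tx_end - 1
        return self.tx_start


@dataclass
class Peak:
    """An enrichment island: the unit of every downstream comparison."""

    interval: GenomicInterval
    tag_count: int = 0
    summit: Optional[int] = None
    score: Optional[float] = None
    name: str = ""

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


def sort_peaks(peaks: Sequence[Peak]) -> List[Peak]:
    return sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))


def validate_chrom_sizes(sizes: ChromSizes) -> None:
    for chrom, length in sizes.items():
        if length <= 0:
            raise CoordinateError(f"chromosome {chrom} has non-positive length")
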