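"""Readers and writers for the plain-text genomic formats the pipeline uses.

Supported formats: refFlat and BED12 for gene annotation, BED3/BED6 for
mapped tags, BED5 for enrichment islands (score column = tag count),
two-column chrom.sizes, and TSV/JSON reports. Internal coordinates are
0-based half-open throughout; refFlat and BED are already in that
convention so no shifting happens here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Iterable, List, Sequence, Union

import pandas as pd

from .core import (
    ChromSizes,
    CoordinateError,
    GeneModel,
    GenomicInterval,
    Peak,
    Tag,
    TagLibrary,
    sort_peaks,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed input file; message names the file and 1-based line."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


# ---------------------------------------------------------------------------
# gene annotation


def _gene_from_refflat(path: PathLike, lineno: int, f: List[str]) -> GeneModel:
    if len(f) < 11:
        raise ParseError(path, lineno, f"refFlat needs 11 columns, got {len(f)}")
    try:
        tx_start, tx_end = int(f[4]), int(f[5])
        exon_count = int(f[8])
        exon_starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
        exon_ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
    except ValueError as exc:
        raise ParseError(path, lineno, f"bad numeric field: {exc}") from None
    if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
        raise ParseError(
            path, lineno,
            f"exonCount={exon_count} but {len(exon_starts)} starts / "
            f"{len(exon_ends)} ends",
        )
    chrom = f[2]
    try:
        exons = tuple(
            GenomicInterval(chrom, s, e) for s, e in zip(exon_starts, exon_ends)
        )
        return GeneModel(
            transcript_id=f[1],
            gene_symbols=tuple(sym for sym in f[0].split(",") if sym),
            chrom=chrom,
            strand=f[3],
            tx_start=tx_start,
            tx_end=tx_end,
            exons=exons,
        )
    except CoordinateError as exc:
        raise ParseError(path, lineno, str(exc)) from None


def _gene_from_bed12(path: PathLike, lineno: int, f: List[str]) -> GeneModel:
    if len(f) < 12:
        raise ParseError(path, lineno, f"BED12 needs 12 columns, got {len(f)}")
    try:
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        block_count = int(f[9])
        block_sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
        block_starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
    except ValueError as exc:
        raise ParseError(path, lineno, f"bad numeric field: {exc}") from None
    if len(block_sizes) != block_count or len(block_starts) != block_count:
        raise ParseError(path, lineno, "blockCount does not match block lists")
    try:
        exons = tuple(
            GenomicInterval(chrom, start + bs, start + bs + sz)
            for bs, sz in zip(block_starts, block_sizes)
        )
        return GeneModel(
            transcript_id=name,
            gene_symbols=(name,),
            chrom=chrom,
            strand=strand,
            tx_start=start,
            tx_end=end,
            exons=exons,
        )
    except CoordinateError as exc:
        raise ParseError(path, lineno, str(exc)) from None


def read_gene_annotation(path: PathLike, dialect: str = "refFlat") -> List[GeneModel]:
    """Read transcript models from a refFlat or BED12 table.

    One GeneModel per row; exon blocks are reconstructed; a refFlat
    geneName column holding comma-separated symbols yields multiple
    gene_symbols on one transcript.
    """
    if dialect not in ("refFlat", "bed12"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    parse = _gene_from_refflat if dialect == "refFlat" else _gene_from_bed12
    genes = [parse(path, lineno, f) for lineno, f in _data_lines(path)]
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.tx_end, g.transcript_id))
    return genes


def write_gene_annotation(
    genes: Sequence[GeneModel], path: PathLike, dialect: str = "refFlat"
) -> None:
    if dialect != "refFlat":
        raise ValueError("only refFlat output is supported")
    rows = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.transcript_id)):
        starts = ",".join(str(e.start) for e in g.exons) + ","
        ends = ",".join(str(e.end) for e in g.exons) + ","
        rows.append(
            "\t".join(
                [
                    ",".join(g.gene_symbols),
                    g.transcript_id,
                    g.chrom,
                    g.strand,
                    str(g.tx_start),
                    str(g.tx_end),
                    str(g.tx_start),
                    str(g.tx_end),
                    str(len(g.exons)),
                    starts,
                    ends,
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# tags and peaks


def read_tags(
    path: PathLike, mark: str = "", cell_type: str = "", collapse_duplicates: bool = False
) -> TagLibrary:
    """Read mapped tags from BED3+ (strand from column 6 if present).

    Duplicate tags are kept by default; ``collapse_duplicates=True``
    keeps one tag per identical (chrom, start, end, strand).
    """
    tags: List[Tag] = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise ParseError(path, lineno, "BED needs at least 3 columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad coordinate: {exc}") from None
        strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "+"
        try:
            tags.append(Tag(f[0], start, end, strand))
        except CoordinateError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    if collapse_duplicates:
        seen = set()
        unique = []
        for t in tags:
            key = (t.chrom, t.start, t.end, t.strand)
            if key not in seen:
                seen.add(key)
                unique.append(t)
        tags = unique
    return TagLibrary(tags=tags, mark=mark, cell_type=cell_type)


def write_tags(library: TagLibrary, path: PathLike) -> None:
    with open(path, "w") as fh:
        for t in sorted(library.tags, key=lambda t: (t.chrom, t.start, t.end, t.strand)):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t.\t0\t{t.strand}\n")


def read_peaks(path: PathLike) -> List[Peak]:
    """Read islands from BED3+; column 5 (if present) is the tag count."""
    peaks: List[Peak] = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise ParseError(path, lineno, "BED needs at least 3 columns")
        try:
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
        except (ValueError, CoordinateError) as exc:
            raise ParseError(path, lineno, str(exc)) from None
        name = f[3] if len(f) >= 4 else ""
        try:
            count = int(float(f[4])) if len(f) >= 5 else 0
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad score column: {exc}") from None
        peaks.append(Peak(interval=iv, tag_count=count, name=name))
    return sort_peaks(peaks)


def write_peaks(peaks: Sequence[Peak], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(sort_peaks(peaks)):
            name = p.name or f"peak_{i + 1}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.tag_count}\n")


# ---------------------------------------------------------------------------
# chrom sizes


def read_chrom_sizes(path: PathLike) -> ChromSizes:
    sizes: ChromSizes = {}
    for lineno, f in _data_lines(path):
        if len(f) < 2:
            raise ParseError(path, lineno, "chrom.sizes needs 2 columns")
        try:
            length = int(f[1])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad length: {exc}") from None
        if length <= 0:
            raise ParseError(path, lineno, f"non-positive length {length}")
        sizes[f[0]] = length
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# reports


def write_report(report: Any, path: PathLike, format: str = "tsv") -> None:
    """Write any report object with a ``to_frame``/``to_dict`` method.

    TSV output goes through the object's ``to_frame()`` (deterministic
    column and row order); JSON through ``to_dict()`` with sorted keys,
    so identical reports produce byte-identical files.
    """
    if format == "tsv":
        frame = report.to_frame() if hasattr(report, "to_frame") else pd.DataFrame(report)
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
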