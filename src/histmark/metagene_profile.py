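"""Aggregate tag-density profile over flanks and length-scaled gene body.

For each gene, the 5 kb upstream flank, the gene body, and the 5 kb
downstream flank are each divided into 40 windows (fixed 125 bp windows
in the flanks, equal fractions of the body). Tag counts are summed over
all genes per window position and normalised by

    density = reads in window / (library total reads x window bases)

so the 120 bin values are tag densities in reads per (read x bp),
comparable across libraries of different depth. Profiles are oriented
5' -> 3': for minus-strand genes the bins are flipped so bin 0 is
always the distal 5' end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from ._intervals import TagIndex
from .core import GeneModel, TagLibrary


class ProfileError(ValueError):
    pass


@dataclass
class MetageneProfile:
    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_genes: int
    library_total: int

    @property
    def densities(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])

    def to_frame(self):
        import pandas as pd

        rows = []
        for region, values in (
            ("upstream", self.upstream),
            ("body", self.body),
            ("downstream", self.downstream),
        ):
            for i, d in enumerate(values):
                rows.append({"region": region, "bin": i, "density": d})
        return pd.DataFrame(rows)


def _gene_windows(
    gene: GeneModel, flank: int, n_bins: int
) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int]], List[Tuple[int, int]]]:
    """Window coordinate lists (upstream, body, downstream), 5'->3' order.

    Flank windows are fixed-width (flank/n_bins); body windows have
    boundaries at round(i*L/n_bins), covering the body without gaps.
    Windows are clipped at 0 (a clipped-away window has zero length).
    """
    bw = flank // n_bins
    L = gene.tx_end - gene.tx_start
    body_bounds = [gene.tx_start + round(i * L / n_bins) for i in range(n_bins + 1)]
    body = [(body_bounds[i], body_bounds[i + 1]) for i in range(n_bins)]

    left = [
        (max(0, gene.tx_start - flank + i * bw), max(0, gene.tx_start - flank + (i + 1) * bw))
        for i in range(n_bins)
    ]
    right = [
        (gene.tx_end + i * bw, gene.tx_end + (i + 1) * bw) for i in range(n_bins)
    ]
    if gene.strand == "+":
        return left, body, right
    # minus strand: upstream is to the right, and bin order flips
    upstream = right[::-1]
    downstream = left[::-1]
    return upstream, body[::-1], downstream


def metagene_profile(
    genes: Sequence[GeneModel],
    tags: TagLibrary,
    flank: int = 5000,
    n_bins: int = 40,
    orient_by_strand: bool = True,
    assignment: str = "overlap",
) -> MetageneProfile:
    """Aggregate tag-density profile across a gene set.

    ``assignment='overlap'`` counts a tag in every window its interval
    overlaps; ``'five_prime'`` assigns each tag once, to the window
    containing its 5' end. Genes shorter than n_bins bp are skipped
    with a warning (their body windows would be under 1 bp).
    """
    if not genes:
        raise ProfileError("empty gene list")
    if tags.total_reads == 0:
        raise ProfileError("empty tag library")
    if flank % n_bins != 0:
        raise ProfileError("flank must be divisible by n_bins")
    if assignment not in ("overlap", "five_prime"):
        raise ProfileError(f"unknown assignment mode {assignment!r}")

    index = TagIndex(tags.tags)
    if assignment == "five_prime":
        five_prime = [
            (t.chrom, t.start if t.strand == "+" else t.end - 1) for t in tags.tags
        ]
        fp_pos = {}
        for chrom, pos in five_prime:
            fp_pos.setdefault(chrom, []).append(pos)
        fp_sorted = {c: np.sort(np.asarray(v)) for c, v in fp_pos.items()}

        def count(chrom: str, s: int, e: int) -> int:
            arr = fp_sorted.get(chrom)
            if arr is None:
                return 0
            return int(np.searchsorted(arr, e) - np.searchsorted(arr, s))

    else:
        count = index.count

    tag_sums = np.zeros(3 * n_bins)
    base_sums = np.zeros(3 * n_bins)
    n_used = 0
    for gene in genes:
        if gene.tx_end - gene.tx_start < n_bins:
            warnings.warn(
                f"skipping {gene.transcript_id}: body shorter than {n_bins} bp"
            )
            continue
        n_used += 1
        regions = _gene_windows(
            gene, flank, n_bins
        ) if orient_by_strand else _gene_windows(
            GeneModel(
                gene.transcript_id,
                gene.gene_symbols,
                gene.chrom,
                "+",
                gene.tx_start,
                gene.tx_end,
                gene.exons,
            ),
            flank,
            n_bins,
        )
        for r, windows in enumerate(regions):
            for i, (s, e) in enumerate(windows):
                if e <= s:
                    continue
                k = r * n_bins + i
                tag_sums[k] += count(gene.chrom, s, e)
                base_sums[k] += e - s

    if n_used == 0:
        raise ProfileError("no gene long enough to profile")

    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(
            base_sums > 0, tag_sums / (tags.total_reads * base_sums), 0.0
        )
    return MetageneProfile(
        upstream=dens[:n_bins],
        body=dens[n_bins : 2 * n_bins],
        downstream=dens[2 * n_bins :],
        n_genes=n_used,
        library_total=tags.total_reads,
    )
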