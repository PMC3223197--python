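"""Sliding-window local-Poisson enrichment-island caller.

A deliberately simple detector in the spirit of model-based ChIP-seq
peak callers: tags are extended to the expected chromatin fragment
length, counted in overlapping fixed-width windows, and each window is
tested against a Poisson null whose rate is the maximum of the
genome-wide expectation and several local expectations (which absorbs
local background fluctuation). Significant windows are merged into
islands. There is no fragment-shift model and no control library; if
externally called peaks are available they can be fed to the downstream
stages directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from ._intervals import TagIndex, merge_spans
from .core import ChromSizes, GenomicInterval, Peak, TagLibrary, validate_chrom_sizes


class PeakCallingError(ValueError):
    pass


@dataclass
class PeakCallerParams:
    """Tuning knobs of the island caller.

    window/step control resolution; p_threshold is the raw Poisson
    upper-tail cutoff per window (no multiple-testing correction, as in
    classic caller defaults); merge_gap joins nearby significant
    windows; min_length drops fragmented calls; local_lambda_windows are
    the spans over which local background rates are estimated;
    fragment_length is the size each tag is extended to from its 5' end
    (sequenced chromatin fragments are a few hundred bp).
    """

    window: int = 200
    step: int = 50
    p_threshold: float = 1e-5
    merge_gap: int = 200
    min_length: int = 200
    local_lambda_windows: Sequence[int] = (1000, 5000, 10000)
    fragment_length: int = 200

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise PeakCallingError("step must not exceed window")
        if any(span <= self.window for span in self.local_lambda_windows):
            raise PeakCallingError("local lambda spans must exceed the window")
        if not (0 < self.p_threshold < 1):
            raise PeakCallingError("p_threshold must be in (0, 1)")


def poisson_tail(count: int, lam: float) -> float:
    """Upper-tail probability P(X >= count) for X ~ Poisson(lam)."""
    if lam <= 0:
        raise PeakCallingError(f"lambda must be positive, got {lam}")
    if count < 0:
        raise PeakCallingError("count must be non-negative")
    if count == 0:
        return 1.0
    # sf(count-1) = P(X > count-1) = P(X >= count); scipy computes this
    # via the regularised gamma function, stable for large counts.
    return float(stats.poisson.sf(count - 1, lam))


def extend_tags(tags: TagLibrary, fragment_length: int) -> List[GenomicInterval]:
    """Extend each tag to fragment_length from its 5' end (strand-aware)."""
    out = []
    for t in tags.tags:
        if t.strand == "+":
            out.append(GenomicInterval(t.chrom, t.start, t.start + fragment_length))
        else:
            out.append(
                GenomicInterval(t.chrom, max(0, t.end - fragment_length), t.end)
            )
    return out


def call_peaks(
    tags: TagLibrary,
    sizes: ChromSizes,
    params: PeakCallerParams | None = None,
) -> List[Peak]:
    """Call enrichment islands from a tag library.

    Windows of ``params.window`` bp, stepped by ``params.step`` from
    position 0 of each chromosome, are scored by the count of extended-
    fragment midpoints they contain against Poisson(lambda_max), where
    lambda_max is the largest of the genome-wide and local expected
    counts. Windows with upper-tail probability below ``p_threshold``
    are merged (gap <= merge_gap) into islands; islands shorter than
    ``min_length`` are dropped. Each island's tag_count is the number of
    original tags overlapping it; its summit is the centre of its
    highest-count window; its score is -log10 of its best window p.
    """
    params = params or PeakCallerParams()
    validate_chrom_sizes(sizes)
    if tags.total_reads == 0:
        raise PeakCallingError("cannot call peaks on an empty tag library")
    unknown = set(t.chrom for t in tags.tags) - set(sizes)
    if unknown:
        raise PeakCallingError(f"tags on chromosomes missing from sizes: {unknown}")

    fragments = extend_tags(tags, params.fragment_length)
    mids: Dict[str, np.ndarray] = {}
    for chrom in sizes:
        pos = [(f.start + f.end) // 2 for f in fragments if f.chrom == chrom]
        mids[chrom] = np.sort(np.asarray(pos, dtype=np.int64))

    tag_index = TagIndex(tags.tags)
    peaks: List[Peak] = []
    for chrom in sorted(sizes):
        peaks.extend(
            _call_chromosome(chrom, sizes[chrom], mids[chrom], tag_index, params)
        )
    return peaks


def _window_counts(
    mids: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    return np.searchsorted(mids, ends, side="left") - np.searchsorted(
        mids, starts, side="left"
    )


def _call_chromosome(
    chrom: str,
    length: int,
    mids: np.ndarray,
    tag_index: TagIndex,
    params: PeakCallerParams,
) -> List[Peak]:
    if len(mids) == 0:
        return []
    w, step = params.window, params.step
    # background rate is per chromosome, so calling a multi-chromosome
    # library equals calling each chromosome separately
    lam_genome = len(mids) * w / length
    starts = np.arange(0, max(1, length - w + 1), step, dtype=np.int64)
    ends = starts + w
    counts = _window_counts(mids, starts, ends)

    # pass 1: mask provisionally enriched windows at a lenient threshold,
    # so the local background estimate is not contaminated by the very
    # enrichment being tested (a treatment-only caller has no control
    # library to estimate local lambda from)
    mask_p = max(params.p_threshold, 1e-3)
    provisional = stats.poisson.sf(counts - 1, lam_genome) < mask_p
    mask_spans = merge_spans(
        (int(starts[i]), int(min(ends[i], length)))
        for i in np.flatnonzero(provisional)
    )
    mask_starts = np.array([s for s, _ in mask_spans], dtype=np.int64)
    mask_ends = np.array([e for _, e in mask_spans], dtype=np.int64)
    mask_cum = np.concatenate([[0], np.cumsum(mask_ends - mask_starts)])

    def masked_bp_below(x: np.ndarray) -> np.ndarray:
        """Total masked bases in [0, x)."""
        k = np.searchsorted(mask_starts, x, side="right")
        total = mask_cum[k]
        km = np.maximum(k - 1, 0)
        overshoot = np.clip(mask_ends[km] - x, 0, mask_ends[km] - mask_starts[km])
        return total - np.where(k > 0, overshoot, 0)

    keep = np.ones(len(mids), dtype=bool)
    if len(mask_starts):
        k = np.searchsorted(mask_starts, mids, side="right")
        inside = (k > 0) & (mids < mask_ends[np.maximum(k - 1, 0)])
        keep = ~inside
    bg_mids = mids[keep]

    # pass 2: local lambda per span from the masked (background-only) tags
    lam = np.full(len(starts), lam_genome)
    centers = starts + w // 2
    for span in params.local_lambda_windows:
        lo = np.clip(centers - span // 2, 0, length)
        hi = np.clip(centers + span // 2, 0, length)
        bg_counts = _window_counts(bg_mids, lo, hi)
        if len(mask_starts):
            masked_len = masked_bp_below(hi) - masked_bp_below(lo)
        else:
            masked_len = np.zeros(len(lo), dtype=np.int64)
        unmasked = (hi - lo) - masked_len
        local = np.where(unmasked >= w, bg_counts * w / np.maximum(unmasked, 1),
                         lam_genome)
        lam = np.maximum(lam, local)

    pvals = stats.poisson.sf(counts - 1, lam)
    pvals = np.where(counts == 0, 1.0, pvals)
    sig = pvals < params.p_threshold
    if not sig.any():
        return []

    sig_idx = np.flatnonzero(sig)
    spans = merge_spans(
        (int(starts[i]), int(min(ends[i], length))) for i in sig_idx
    )
    # merge islands separated by <= merge_gap
    merged: List[List[int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] <= params.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    peaks: List[Peak] = []
    for s, e in merged:
        if e - s < params.min_length:
            continue
        inside = (starts >= s) & (ends <= e) & sig
        if not inside.any():
            inside = (starts >= s) & (starts < e)
        best = np.flatnonzero(inside)[np.argmax(counts[inside])]
        p_best = float(pvals[best])
        score = 1000.0 if p_best == 0 else -math.log10(p_best)
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, s, e),
                tag_count=tag_index.count(chrom, s, e),
                summit=int(starts[best] + w // 2),
                score=score,
            )
        )
    for i, p in enumerate(peaks):
        p.name = f"{chrom}_island_{i + 1}"
    return peaks
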