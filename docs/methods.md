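# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open (`[start, end)`, the BED
convention). Genome-browser region strings (`ChrX:A-B`) are 1-based
inclusive and converted exactly once at the parse boundary to
`[A-1, B)`. Gene annotation is read from refFlat (primary dialect; it
carries txStart/txEnd/exonStarts/exonEnds directly) or BED12. Tags are
BED3/BED6 (strand defaults to `+`), islands BED5 with the score column
holding the tag count. Chromosome names are matched as exact strings.
Duplicate tags are kept by default; collapsing is an option, since
whether duplicates should be removed before counting is a
protocol-level choice the analysis does not impose.

## Genome partition

From a transcript set, four region classes are built per chromosome:

- proximal promoter: `[TSS − h, TSS + h)` per transcript, default
  h = 1000 bp, clipped to chromosome bounds. The TSS is strand-aware by
  default (txStart for `+`, txEnd − 1 for `−` transcripts); a
  strand-ignorant literal-txStart mode exists for reproducing
  annotation-table semantics.
- exon: union of exon blocks; intron: gene bodies minus exons;
  intergenic: complement of promoters ∪ gene bodies.

Same-class intervals from overlapping transcripts are merged, and a
merged promoter keeps the list of all contributing genes (one promoter
may serve several genes). Classes can overlap each other; classifying
an interval resolves ties by precedence promoter > exon > intron >
intergenic with a ≥1 bp overlap rule. The precedence order is a design
choice — the promoter-first reading is the one consistent with treating
promoter overlap as the defining property of a promoter island — and a
maximal-overlap mode is available behind a flag. `resolved_spans` gives
the disjoint per-base version of the partition (used by the simulator
and by exhaustiveness tests). A promoter halfwidth of 0 is allowed and
produces an empty promoter class.

## Island caller

A deliberately simple treatment-only detector, not a re-implementation
of any published caller: no fragment-shift model, no control library,
no multiple-testing correction (raw per-window p threshold, default
1e-5). Tags are extended to the expected chromatin fragment length
(default 200 bp, matching sonicated fragments of a few hundred bp) from
their 5′ ends; fragment midpoints are counted in 200 bp windows stepped
by 50 bp from position 0 of each chromosome.

Each window count is tested against a Poisson null with
λ_max = max(λ_chrom, λ_local over 1 kb/5 kb/10 kb spans). The local
rates are estimated in two passes: windows provisionally enriched
against the chromosome-wide rate at a lenient threshold
(max(p, 1e-3)) are masked, and local λ per span is computed from the
remaining background midpoints over the unmasked span length (falling
back to λ_chrom when almost the whole span is masked). The masking is
essential: estimated naively from the treatment, a local λ inside a
uniformly enriched kilobase equals the window's own rate and the test
has no power. λ_chrom is per chromosome (reads on chromosome × window /
chromosome length), which also makes calling a multi-chromosome library
exactly equal to calling each chromosome separately.

Significant windows are merged (gap ≤ 200 bp), islands shorter than
200 bp are dropped, each island's tag count is the number of original
tags overlapping it, the summit is the centre of its highest-count
window, and the score is −log10 of its best window p-value. Island
counts are monotone in the p threshold for isolated loci; when two loci
sit close together a looser threshold can merge them, so total enriched
bases — which are strictly monotone — are the better dial to reason
about.

## Island comparison and promoter association

Two islands are common when they share ≥ 1 bp under half-open
semantics; specific otherwise. Commonness is per side: an island is
common if it has ≥ 1 partner, and one island may partner several on the
other side, so the two directions of a comparison report different
common totals. The same contract serves the cross-mark comparison
(me1 vs me3 islands of one cell type), which is where the per-side
asymmetry becomes visible.

A promoter is "marked" when ≥ 1 island overlaps it by ≥ 1 bp (no
minimum tag count). The enrichment ratio of a marked promoter in a
lineage is the number of that lineage's tags falling inside the
promoter-overlapping islands (summed over the union of those islands;
a max-single-peak mode exists) divided by the promoter length, in
tags/bp. Ratios can optionally be scaled to counts per million library
reads; default off, since the ratio is already length-normalised and
the correlation is scale-invariant under per-library scaling. The
cross-lineage correlation is Pearson on the raw ratios (the scatter of
interest is linear in the ratios); Spearman and log1p-Pearson are
available. Correlation requires ≥ 3 records and non-zero variance on
both axes. Gene-level Venn partitions compare the union of gene symbols
behind each lineage's marked promoters; a gene counts once regardless
of transcript multiplicity.

## Metagene profile

Per gene: 40 fixed 125 bp windows over the 5 kb upstream flank, 40
equal-fraction windows over the body (boundaries at round(i·L/40), so
bodies of any length ≥ 40 bp are covered without gaps), 40 windows over
the 5 kb downstream flank. Genes shorter than 40 bp are skipped with a
warning. Bins are oriented 5′→3′ (minus-strand genes are flipped;
a literal-coordinate mode exists). A tag is counted in every window its
interval overlaps (a 5′-end single-assignment mode exists). Counts are
aggregated over all genes first and then normalised once:

    density(bin) = Σ_genes tags in window / (library reads × Σ_genes window bases)

This summed-then-normalised form follows the single-ratio definition of
tag density; per-gene averaging would weight genes equally regardless
of length and is not the default. Overlapping genes are profiled
independently, so a tag may contribute to more than one gene.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

- **Genome**: by default one 10 Mb chromosome carrying 200
  non-overlapping genes, lengths 10–40 kb with 2–6 exons (long genes so
  introns can host kilobase loci), both strands, separated by ≥ 2 kb +
  two promoter halfwidths so promoters never merge across genes.
- **Architecture**: 300 loci of 1 kb per mark, each placed wholly
  inside one precedence-resolved class interval with a 300 bp margin
  (so a called island that spreads by about one fragment length still
  classifies to the planted class) and ≥ 1 kb from any other locus of
  the same mark (so islands never merge). Class quotas and the
  common/specific labels are assigned by largest-remainder quota rather
  than i.i.d. draws: the realized class mixture and share fraction
  equal the parameters up to rounding, so recovery error measures the
  pipeline rather than multinomial sampling noise.
- **Presets**: *me3-like* (promoter-heavy mixture 45/10/20/25% over
  promoter/exon/intron/intergenic, share 0.8) motivated by the
  observation that roughly a third to a half of tri-methylation islands
  fall in proximal promoters and that the mark is largely shared
  between related lineages; *me1-like* (10/5/55/30%, share 0.3)
  motivated by mono-methylation concentrating in introns and being
  largely lineage-specific. The presets are regime anchors, not claims
  of reproducing real-data values.
- **Tags**: fragment-length intervals centred on positions drawn from a
  piecewise-constant rate — background everywhere, fold × background
  inside each locus. Each locus draws its own fold from a
  mean-preserving lognormal (mean 20×, σ = 0.5, floored at 2×), shared
  between cell types at common loci; without this between-locus height
  variation, enrichment ratios would carry only independent Poisson
  noise and cross-lineage correlation would be near zero even for a
  fully shared mark. Every random stream derives deterministically from
  (seed, purpose, mark, cell).

What the generator does **not** model: read sequences, mappability and
GC bias, duplicate structure, fragment-size variance, inter-replicate
variation, and broad/weak enrichment domains. Passing tests therefore
show the pipeline's logic is correct under idealised sampling, not that
the caller's sensitivity matches real libraries.

## Pipeline

`run_pipeline` validates all inputs before any computation, then per
mark: calls (or loads) islands per cell type, writes the class
distribution, metagene profile, common/specific BEDs and JSON summary,
promoter enrichment table with correlation, and gene Venn; with two
marks it adds the per-cell cross-mark comparison. Reports are sorted
deterministically and identical (config, seed) reruns are
byte-identical; timings go only to stderr and `pipeline.log`.

## Problem sizes and defaults

Default study conditions (200 genes on 10 Mb, 200 000 tags per library,
300 loci per mark, 20× mean fold) were chosen so planted loci carry
~250 tags (comfortably above the ~10-tag detection floor at this
background) while a full two-mark, two-lineage analysis completes in
seconds. The acceptance script runs exactly these conditions.

## Known limitations

- The caller targets punctate-to-kilobase islands; broad domains
  (tens of kb) would be fragmented by the local-lambda masking.
- Enrichment ratios are compared only between two lineages; no
  count-based differential-binding statistics are provided.
- The gene Venn treats gene symbols as identifiers; annotation
  versions with inconsistent symbols will fragment genes.
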