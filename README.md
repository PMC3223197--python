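# histmark

Comparative ChIP-seq analysis of histone H3K4 methylation marks between
two cell lineages — for example regulatory T cells (Treg) versus
activated conventional T cells (aTconv), profiled for H3K4me1 (an
enhancer-associated mark) and H3K4me3 (an active-promoter mark).

`histmark` is aimed at epigenomics analysts who have per-lineage
libraries of uniquely mapped tags (BED) or externally called peaks and
want the standard downstream comparisons:

- **Genome partition** — divide the genome into four classes from a gene
  annotation: proximal promoters (±1 kb around each transcription start
  site), exons, introns, and intergenic sequence; classify each
  enrichment island into one class (precedence promoter > exon >
  intron > intergenic) and report the island distribution.
- **Island calling** — a sliding-window local-Poisson caller: tags are
  extended to the chromatin fragment length, counted in 200 bp windows
  stepped by 50 bp, and each window count *k* is tested against
  P(X ≥ k), X ~ Poisson(λ_max) with
  λ_max = max(λ_genome, λ_1k, λ_5k, λ_10k), the local rates estimated
  from enrichment-masked background. Externally called peaks can be
  supplied instead (`--skip-calling`).
- **Common vs lineage-specific islands** — two islands are *common* if
  they overlap by at least 1 bp (half-open coordinates); an island with
  no partner in the other lineage is *lineage-specific*. Commonness is
  counted per side, so the two sides of a comparison may report
  different common totals (one island can partner several).
- **Promoter/gene association** — per marked promoter, the enrichment
  ratio (tags in the promoter-overlapping peaks ÷ promoter length, in
  tags/bp) in each lineage; Pearson correlation of the two ratios over
  promoters; gene-level Venn partition (common / A-specific /
  B-specific genes).
- **Metagene profile** — aggregate tag density over 5 kb upstream, the
  length-scaled gene body, and 5 kb downstream (40 windows per region,
  125 bp flank windows), normalised as
  density = reads in window / (library total reads × window bases).
- **Synthetic data** — genomes, annotations, planted island
  architectures with per-class placement mixtures and a cross-lineage
  share fraction, and tag libraries with known ground truth, so every
  stage is testable end to end.

## Worked example

Simulate a promoter-heavy ("me3-like") mark for two lineages, call
islands in each, and compare:

```sh
histmark simulate --preset me3-like --seed 1 --n-genes 60 \
    --library-size 40000 --n-peaks 100 --outdir sim
histmark call --tags sim/tags_H3K4me3_A.bed --sizes sim/genome.chrom.sizes --out peaks_A.bed
histmark call --tags sim/tags_H3K4me3_B.bed --sizes sim/genome.chrom.sizes --out peaks_B.bed
histmark compare --peaks-a peaks_A.bed --peaks-b peaks_B.bed --out-prefix cmp
histmark classify --peaks peaks_A.bed --annotation sim/genes.refFlat \
    --sizes sim/genome.chrom.sizes --out classes.tsv
```

The `compare` step prints the common/specific partition:

```json
{"common_pairs": 70, "common_A": 70, "common_B": 70,
 "specific_A": 12, "specific_B": 15, "total_A": 82, "total_B": 85}
```

70 of the 82 lineage-A islands overlap a lineage-B island; the implied
common fraction 70/(82+85−70) ≈ 0.72 estimates the preset's planted
share of 0.8 at this small scale. `classes.tsv.summary.tsv` holds the
genomic-class distribution of the called islands:

```text
region_class       count  percent
proximal_promoter  38     46.34
exon               9      10.98
intron             13     15.85
intergenic         22     26.83
```

— promoter-concentrated, as planted (45% promoter mixture). The full
pipeline (`histmark run`) chains every stage, adds metagene profiles,
promoter enrichment correlation, gene Venn partitions and a cross-mark
comparison, and writes a manifest plus `summary.json`.

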