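"""Synthetic genome/architecture/tag generator: determinism and structure."""

import numpy as np
import pytest
from scipy import stats

from histmark.core import GenomicInterval
from histmark.genome_partition import RegionClass, classify_interval
from histmark.io_formats import read_gene_annotation, write_gene_annotation
from histmark.synthetic_data import (
    ArchitectureParams,
    SimulationError,
    generate_genome,
    generate_tags,
    me1_like,
    me3_like,
    plant_architecture,
)


class TestGenerateGenome:
    def test_deterministic_and_disjoint(self):
        params = ArchitectureParams(seed=1, n_genes=50,
                                    chrom_lengths={"chrS1": 3_000_000})
        sizes, genes = generate_genome(params)
        sizes2, genes2 = generate_genome(params)
        assert genes == genes2
        assert len(genes) == 50
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.tx_start)
            for g1, g2 in zip(gs, gs[1:]):
                assert g1.tx_end < g2.tx_start
        assert {g.strand for g in genes} == {"+", "-"}
        assert all(2 <= len(g.exons) <= 10 for g in genes)

    def test_zero_genes(self):
        params = ArchitectureParams(seed=1, n_genes=0)
        _, genes = generate_genome(params)
        assert genes == []

    def test_infeasible_packing_rejected(self):
        params = ArchitectureParams(seed=1, n_genes=50,
                                    chrom_lengths={"chrS1": 100_000})
        with pytest.raises(SimulationError):
            generate_genome(params)

    def test_round_trip_through_annotation_file(self, tmp_path):
        params = ArchitectureParams(seed=2, n_genes=20,
                                    chrom_lengths={"chrS1": 2_000_000})
        _, genes = generate_genome(params)
        path = tmp_path / "genes.refFlat"
        write_gene_annotation(genes, path)
        assert read_gene_annotation(path) == genes


class TestPlantArchitecture:
    def _genome(self, seed=3):
        params = me3_like(seed=seed, n_genes=40, n_peaks_per_mark=60,
                          chrom_lengths={"chrS1": 3_000_000})
        return params, generate_genome(params)

    def test_share_fraction_extremes(self):
        params, genome = self._genome()
        all_common = plant_architecture(
            genome, me3_like(seed=3, n_genes=40, n_peaks_per_mark=60,
                             chrom_lengths={"chrS1": 3_000_000},
                             share_fraction=1.0)
        )
        assert all(p.label == "common" for p in all_common.peaks)
        none_common = plant_architecture(
            genome, me3_like(seed=3, n_genes=40, n_peaks_per_mark=60,
                             chrom_lengths={"chrS1": 3_000_000},
                             share_fraction=0.0)
        )
        assert not any(p.label == "common" for p in none_common.peaks)

    def test_pure_promoter_mixture_verified_by_classifier(self):
        params, genome = self._genome()
        pure = me3_like(
            seed=3, n_genes=40, n_peaks_per_mark=30,
            chrom_lengths={"chrS1": 3_000_000},
            class_mixture={RegionClass.PROXIMAL_PROMOTER: 1.0},
        )
        truth = plant_architecture(genome, pure)
        assert len(truth.peaks) == 30
        for p in truth.peaks:
            assert (
                classify_interval(truth.partition, p.interval)
                is RegionClass.PROXIMAL_PROMOTER
            )

    def test_realized_mixture_matches_parameters(self):
        params, genome = self._genome()
        truth = plant_architecture(genome, params)
        for cls, prob in params.class_mixture.items():
            assert abs(truth.realized_mixture[cls] - prob) <= 1.5 / len(truth.peaks)

    def test_loci_within_bounds_and_separated(self):
        params, genome = self._genome()
        sizes, _ = genome
        truth = plant_architecture(genome, params)
        ivs = sorted((p.interval for p in truth.peaks),
                     key=lambda iv: iv.start)
        for iv in ivs:
            assert 0 <= iv.start < iv.end <= sizes[iv.chrom]
        for a, b in zip(ivs, ivs[1:]):
            assert b.start - a.end >= 1000


class TestGenerateTags:
    def test_deterministic_per_seed_and_cell(self):
        params = me3_like(seed=4, n_genes=30, n_peaks_per_mark=40,
                          library_size=5000,
                          chrom_lengths={"chrS1": 2_000_000})
        genome = generate_genome(params)
        truth = plant_architecture(genome, params)
        a1 = generate_tags(truth, params, "A")
        a2 = generate_tags(truth, params, "A")
        b = generate_tags(truth, params, "B")
        assert a1.tags == a2.tags
        assert a1.tags != b.tags
        assert a1.total_reads == 5000
        assert all(t.end - t.start == params.fragment_length for t in a1.tags
                   if t.start > 0)

    def test_extreme_fold_concentrates_tags_in_loci(self):
        params = me3_like(seed=5, n_genes=30, n_peaks_per_mark=40,
                          library_size=4000, enrichment_fold=1e6,
                          chrom_lengths={"chrS1": 2_000_000})
        genome = generate_genome(params)
        truth = plant_architecture(genome, params)
        lib = generate_tags(truth, params, "A")
        loci = truth.intervals_for_cell("A")
        inside = sum(
            any(t.chrom == iv.chrom and (t.start + t.end) // 2 in
                range(iv.start, iv.end) for iv in loci)
            for t in lib.tags
        )
        assert inside / lib.total_reads > 0.999

    def test_background_counts_poisson_distributed(self):
        """With no planted loci, per-window midpoint counts pass a
        chi-square goodness-of-fit test against the Poisson law."""
        params = me3_like(seed=6, n_genes=0, n_peaks_per_mark=0,
                          library_size=20_000,
                          chrom_lengths={"chrS1": 2_000_000})
        genome = generate_genome(params)
        truth = plant_architecture(genome, params)
        lib = generate_tags(truth, params, "A")
        mids = np.sort([(t.start + t.end) // 2 for t in lib.tags])
        counts = np.histogram(mids, bins=np.arange(0, 2_000_001, 1000))[0]
        lam = counts.mean()
        kmax = 25
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        expected = stats.poisson.pmf(np.arange(kmax), lam) * len(counts)
        expected = np.append(expected, len(counts) - expected.sum())
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 2)
        assert pval > 0.01

    def test_invalid_library_size_rejected(self):
        params = me3_like(seed=7, n_genes=10, n_peaks_per_mark=5,
                          chrom_lengths={"chrS1": 1_000_000})
        genome = generate_genome(params)
        truth = plant_architecture(genome, params)
        import dataclasses
        bad = dataclasses.replace(params, library_size=0)
        with pytest.raises(SimulationError):
            generate_tags(truth, bad, "A")


class TestPresets:
    def test_preset_mixtures_and_shares(self):
        me3, me1 = me3_like(), me1_like()
        assert me3.class_mixture[RegionClass.PROXIMAL_PROMOTER] > 0.4
        assert me1.class_mixture[RegionClass.INTRON] > 0.5
        assert me3.share_fraction > me1.share_fraction

    def test_invalid_params_rejected(self):
        with pytest.raises(SimulationError):
            ArchitectureParams(share_fraction=1.5)
        with pytest.raises(SimulationError):
            ArchitectureParams(enrichment_fold=0.5)
        with pytest.raises(SimulationError):
            ArchitectureParams(
                class_mixture={RegionClass.EXON: 0.5, RegionClass.INTRON: 0.2}
            )
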