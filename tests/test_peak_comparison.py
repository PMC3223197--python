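"""Common/specific island partition, promoter ratios, Venn, correlation."""

import numpy as np
import pytest

from histmark.core import GenomicInterval, Peak, Tag, TagLibrary
from histmark.genome_partition import build_partition
from histmark.peak_comparison import (
    ComparisonError,
    EnrichmentRecord,
    compare_peak_sets,
    cross_mark_comparison,
    enrichment_correlation,
    gene_venn,
    marked_promoters,
    promoter_mark_table,
)
from tests.conftest import make_gene


def peak(chrom, start, end, count=0):
    return Peak(GenomicInterval(chrom, start, end), tag_count=count)


def brute_force_compare(peaks_a, peaks_b):
    """O(n^2) all-pairs oracle for the common/specific partition."""
    pairs = set()
    for i, a in enumerate(peaks_a):
        for j, b in enumerate(peaks_b):
            if a.interval.overlaps(b.interval):
                pairs.add((i, j))
    common_a = {i for i, _ in pairs}
    common_b = {j for _, j in pairs}
    return pairs, common_a, common_b


def random_peaks(rng, n, chroms=("c1", "c2"), span=10_000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        out.append(peak(str(rng.choice(chroms)), s, s + int(rng.integers(50, 800))))
    return out


class TestComparePeakSets:
    def test_one_bp_overlap_is_common(self):
        res = compare_peak_sets([peak("c", 100, 200)], [peak("c", 199, 300)])
        assert len(res.common_pairs) == 1
        assert not res.specific_a and not res.specific_b

    def test_adjacency_is_specific(self):
        res = compare_peak_sets([peak("c", 100, 200)], [peak("c", 200, 300)])
        assert not res.common_pairs
        assert len(res.specific_a) == len(res.specific_b) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, 50)
        b = random_peaks(rng, 50)
        res = compare_peak_sets(a, b)
        pairs, common_a, common_b = brute_force_compare(a, b)
        got_pairs = {
            (a.index(pa), b.index(pb)) for pa, pb in res.common_pairs
        }
        assert got_pairs == pairs
        assert len(res.common_a) == len(common_a)
        assert len(res.common_b) == len(common_b)

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry_and_conservation(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_peaks(rng, 40), random_peaks(rng, 30)
        fwd = compare_peak_sets(a, b)
        rev = compare_peak_sets(b, a)
        fwd_pairs = {(str(x.interval), str(y.interval)) for x, y in fwd.common_pairs}
        rev_pairs = {(str(y.interval), str(x.interval)) for x, y in rev.common_pairs}
        assert fwd_pairs == rev_pairs
        assert len(fwd.common_a) + len(fwd.specific_a) == len(a)
        assert len(fwd.common_b) + len(fwd.specific_b) == len(b)

    def test_cross_mark_per_side_counting(self):
        """One me1 region spanning two me3 regions counts once on the me1
        side and twice on the me3 side — common counts are per side."""
        me1 = [peak("c", 1000, 3000)]
        me3 = [peak("c", 1200, 1600), peak("c", 2500, 2900)]
        res = cross_mark_comparison(me1, me3)
        assert len(res.common_a) == 1
        assert len(res.common_b) == 2
        assert len(res.common_pairs) == 2
        disjoint = cross_mark_comparison(me1, [peak("c", 5000, 5100)])
        assert not disjoint.common_a and not disjoint.common_b


@pytest.fixture
def promoter_fixture():
    """Five genes; planted peaks overlap some promoters in each lineage."""
    sizes = {"chrP": 200_000}
    genes = [
        make_gene(f"tx{i}", "chrP", "+", 20_000 * (i + 1), 20_000 * (i + 1) + 8000,
                  symbols=(f"G{i}",))
        for i in range(5)
    ]
    part = build_partition(genes, sizes, promoter_halfwidth=1000)
    return sizes, genes, part


def uniform_tags_in(chrom, start, end, n):
    # n point-like tags evenly placed inside [start, end)
    step = (end - start) / n
    return [Tag(chrom, int(start + i * step), int(start + i * step) + 1)
            for i in range(n)]


class TestPromoterMarkTable:
    def test_hand_computed_ratios(self, promoter_fixture):
        sizes, genes, part = promoter_fixture
        # promoter of tx0 is [19000, 21000); peak covers it exactly
        pk_a = [peak("chrP", 19_000, 21_000)]
        pk_b = [peak("chrP", 19_000, 21_000), peak("chrP", 39_000, 41_000)]
        tags_a = TagLibrary(tags=uniform_tags_in("chrP", 19_000, 21_000, 400))
        tags_b = TagLibrary(
            tags=uniform_tags_in("chrP", 19_000, 21_000, 100)
            + uniform_tags_in("chrP", 39_000, 41_000, 300)
        )
        records = promoter_mark_table(part, pk_a, pk_b, tags_a, tags_b)
        by_gene = {r.gene_symbols: r for r in records}
        r0 = by_gene[("G0",)]
        assert r0.ratio_a == pytest.approx(400 / 2000)  # 0.2 tags/bp
        assert r0.ratio_b == pytest.approx(100 / 2000)
        r1 = by_gene[("G1",)]
        assert r1.ratio_a == 0.0  # no lineage-A peak on this promoter
        assert r1.ratio_b == pytest.approx(300 / 2000)
        # promoters with no peak in either lineage are excluded
        assert len(records) == 2

    def test_multiple_peaks_summed(self, promoter_fixture):
        sizes, genes, part = promoter_fixture
        pk = [peak("chrP", 19_000, 19_800), peak("chrP", 20_200, 21_000)]
        tags = TagLibrary(
            tags=uniform_tags_in("chrP", 19_000, 19_800, 120)
            + uniform_tags_in("chrP", 20_200, 21_000, 80)
        )
        empty_peaks = []
        records = promoter_mark_table(part, pk, empty_peaks, tags, tags)
        assert records[0].ratio_a == pytest.approx(200 / 2000)
        records_max = promoter_mark_table(
            part, pk, empty_peaks, tags, tags, combine="max"
        )
        assert records_max[0].ratio_a == pytest.approx(120 / 2000)


class TestGeneVenn:
    def test_set_algebra(self, promoter_fixture):
        sizes, genes, part = promoter_fixture
        proms = part.promoters()
        # promoters sorted by start: G0..G4
        venn = gene_venn(proms[:3], proms[2:3], part)
        assert venn.common_genes == {"G2"}
        assert venn.specific_a_genes == {"G0", "G1"}
        assert venn.specific_b_genes == set()

    def test_identical_and_disjoint_sets(self, promoter_fixture):
        sizes, genes, part = promoter_fixture
        proms = part.promoters()
        same = gene_venn(proms, proms, part)
        assert same.common_genes == {f"G{i}" for i in range(5)}
        assert not same.specific_a_genes and not same.specific_b_genes
        disjoint = gene_venn(proms[:2], proms[3:], part)
        assert disjoint.common_genes == set()

    def test_marked_promoters_one_bp_rule(self, promoter_fixture):
        sizes, genes, part = promoter_fixture
        # [20999, 21200) touches the first promoter by exactly 1 bp
        assert len(marked_promoters(part, [peak("chrP", 20_999, 21_200)])) == 1
        assert len(marked_promoters(part, [peak("chrP", 21_000, 21_200)])) == 0


def records_from(x, y):
    return [
        EnrichmentRecord(str(i), GenomicInterval("c", i * 10 + 1, i * 10 + 5),
                         float(a), float(b))
        for i, (a, b) in enumerate(zip(x, y))
    ]


class TestEnrichmentCorrelation:
    def test_perfect_linear(self):
        x = np.arange(1.0, 11.0)
        r, n = enrichment_correlation(records_from(x, 2 * x))
        assert r == pytest.approx(1.0)
        assert n == 10
        r_neg, _ = enrichment_correlation(records_from(x, 30 - x))
        assert r_neg == pytest.approx(-1.0)

    def test_planted_correlation_recovered(self):
        """Bivariate ratios with rho = 0.8 at n=100: r within +-0.1."""
        rng = np.random.default_rng(12)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([5.0, 5.0], cov, size=100)
        r, n = enrichment_correlation(records_from(xy[:, 0], xy[:, 1]))
        assert abs(r - 0.8) <= 0.1
        assert n == 100

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ComparisonError):
            enrichment_correlation(records_from([1, 2], [2, 4]))
        with pytest.raises(ComparisonError):
            enrichment_correlation(records_from([1, 1, 1], [2, 4, 6]))

    def test_alternative_methods(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        y = x**3  # monotone but nonlinear
        r_s, _ = enrichment_correlation(records_from(x, y), method="spearman")
        assert r_s == pytest.approx(1.0)
        r_log, _ = enrichment_correlation(records_from(x, y), method="log_pearson")
        r_raw, _ = enrichment_correlation(records_from(x, y))
        assert r_log > r_raw - 1e-9
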