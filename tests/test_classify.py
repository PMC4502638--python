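import numpy as np
import pytest
from collections import Counter

from tucall import (
    AlignedRead,
    Category,
    EnhancerPair,
    GeneModel,
    TranscriptionUnit,
    cell_type_specificity,
    classify_units,
    detect_enhancer_pairs,
    metagene,
)


def unit(start, end, strand="+", chrom="chr1"):
    return TranscriptionUnit(chrom, start, end, strand)


def gene(symbol, start, end, strand="+", chrom="chr1"):
    return GeneModel(symbol, chrom, strand, start, end)


CODING = [gene("MRNA", 100_000, 130_000)]
LNCRNA = [gene("LNC", 200_000, 220_000)]
NCRNA = [gene("MIR", 300_000, 300_100)]
REPEATS = [gene("ALU", 400_000, 410_000)]

ARCHETYPES = {
    Category.PROTEIN_CODING: unit(99_000, 110_000),
    Category.NONCODING_RNA: unit(299_950, 300_050, "-"),
    Category.LNCRNA: unit(200_000, 210_000),
    Category.DIVERGENT: unit(98_500, 100_500, "-"),
    Category.ANTISENSE: unit(110_000, 125_000, "-"),
    Category.REPEAT: unit(400_000, 408_000),
    Category.OTHER_GENIC_SENSE: unit(125_000, 155_000),
    Category.OTHER_GENIC_ANTISENSE: unit(125_000, 155_000, "-"),
    Category.INTERGENIC: unit(700_000, 705_000),
}
ENHANCER_PAIR = (unit(599_500, 601_500), unit(598_500, 600_500, "-"))


class TestClassifyUnits:
    def classify(self, units):
        return classify_units(units, CODING, NCRNA, LNCRNA, REPEATS)

    def test_each_archetype_gets_its_category(self):
        units = list(ARCHETYPES.values()) + list(ENHANCER_PAIR)
        out = self.classify(units)
        got = {(c.unit.chrom, c.unit.start, c.unit.end, c.unit.strand): c.category
               for c in out}
        for cat, u in ARCHETYPES.items():
            assert got[(u.chrom, u.start, u.end, u.strand)] == cat, cat
        for u in ENHANCER_PAIR:
            assert got[(u.chrom, u.start, u.end, u.strand)] == Category.ENHANCER
        assert {c.category for c in out} == set(Category)

    def test_coding_overlap_just_above_threshold(self):
        # 25% of the unit over the coding gene, same strand
        out = self.classify([unit(97_500, 107_500)])
        assert out[0].category == Category.PROTEIN_CODING

    def test_unit_overlapping_nothing_is_intergenic(self):
        out = self.classify([unit(900_000, 905_000)])
        assert out[0].category == Category.INTERGENIC

    def test_divergent_requires_promoter_overlap_and_size_ratio(self):
        # 2-kb unit with 15% over the promoter of a 10-kb opposite mRNA
        coding = [gene("P", 50_000, 60_000)]
        u = unit(49_200, 51_200, "-")  # promoter ±500 of TSS 50,000
        out = classify_units([u], coding, (), (), ())
        assert out[0].category == Category.DIVERGENT
        # same geometry but the unit is over half the primary's size
        coding2 = [gene("P", 50_000, 53_000)]
        out2 = classify_units([u], coding2, (), (), ())
        assert out2[0].category != Category.DIVERGENT

    def test_partition_sums_to_input_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            units = [
                unit(s, s + l, "+-"[rng.integers(2)])
                for s, l in zip(
                    rng.integers(0, 800_000, 15), rng.integers(100, 40_000, 15)
                )
            ]
            out = self.classify(units)
            assert len(out) == len(units)
            assert sum(Counter(c.category for c in out).values()) == len(units)

    def test_classification_order_independent(self):
        units = list(ARCHETYPES.values()) + list(ENHANCER_PAIR)
        a = {(c.unit.start, c.unit.strand): c.category for c in self.classify(units)}
        b = {(c.unit.start, c.unit.strand): c.category
             for c in self.classify(units[::-1])}
        assert a == b


class TestDetectEnhancerPairs:
    GENES = [gene("G", 900_000, 950_000)]

    def test_overlapping_short_distal_pair_detected(self):
        pairs = detect_enhancer_pairs(
            [unit(0, 2000), unit(1500, 3500, "-")], self.GENES
        )
        assert len(pairs) == 1
        assert pairs[0].center == 1750

    def test_nonoverlapping_units_do_not_pair(self):
        assert detect_enhancer_pairs(
            [unit(0, 2000), unit(7000, 9000, "-")], self.GENES
        ) == []

    def test_pair_near_gene_tss_rejected(self):
        pairs = detect_enhancer_pairs(
            [unit(895_000, 897_500), unit(894_000, 896_500, "-")], self.GENES
        )
        assert pairs == []

    def test_long_unit_rejected(self):
        pairs = detect_enhancer_pairs(
            [unit(0, 12_000), unit(1500, 3500, "-")], self.GENES
        )
        assert pairs == []

    def test_each_unit_joins_at_most_one_pair(self):
        plus = unit(0, 2000)
        pairs = detect_enhancer_pairs(
            [plus, unit(1000, 3000, "-"), unit(1500, 3600, "-")], self.GENES
        )
        assert len(pairs) == 1  # best-overlap partner wins, plus is used up

    def test_pairing_symmetric_under_strand_swap(self):
        units = [unit(0, 2000), unit(1500, 3500, "-")]
        flipped = [
            TranscriptionUnit(u.chrom, u.start, u.end, "-" if u.strand == "+" else "+")
            for u in units
        ]
        a = detect_enhancer_pairs(units, self.GENES)
        b = detect_enhancer_pairs(flipped, self.GENES)
        assert len(a) == len(b) == 1
        assert (a[0].plus_unit.start, a[0].plus_unit.end) == (
            b[0].minus_unit.start, b[0].minus_unit.end
        )

    def test_planted_pairs_recovered_from_truth_units(self, small_truth):
        _, truth, _ = small_truth
        pairs = detect_enhancer_pairs(truth.truth_units, truth.genes)
        assert len(pairs) == len(truth.enhancer_pairs)
        got = sorted(p.center for p in pairs)
        want = sorted(p.center for p in truth.enhancer_pairs)
        np.testing.assert_allclose(got, want, atol=1)


class TestCellTypeSpecificity:
    def pair(self, start, end, chrom="chr1"):
        mid = (start + end) // 2
        return EnhancerPair(
            unit(start, mid + 200, "+", chrom), unit(mid - 200, end, "-", chrom), mid
        )

    def test_identical_pairs_in_two_cells_are_shared(self):
        p = self.pair(1000, 4000)
        out = cell_type_specificity({"A": [p], "B": [p]})
        assert all(not r.specific for r in out)
        assert all(r.cell_types_active == frozenset("AB") for r in out)

    def test_low_overlap_pairs_are_specific(self):
        a = self.pair(0, 10_000)
        b = self.pair(9_500, 19_500)  # 5% of each pair's length
        out = cell_type_specificity({"A": [a], "B": [b]})
        assert all(r.specific for r in out)

    def test_pair_in_one_cell_only_is_specific(self):
        out = cell_type_specificity({"A": [self.pair(0, 3000)], "B": []})
        assert len(out) == 1 and out[0].specific
        assert out[0].cell_types_active == frozenset("A")

    def test_single_cell_type_rejected(self):
        with pytest.raises(ValueError):
            cell_type_specificity({"A": []})


class TestMetagene:
    def reads(self, *positions, strand="+", chrom="chr1"):
        return [AlignedRead(chrom, p, p + 30, strand) for p in positions]

    def test_single_center_counts_land_in_expected_bin(self):
        reads = self.reads(10_050, 10_060, 10_070)
        res = metagene(reads, [("chr1", 10_000)], half_window=400, bin_size=100)
        profile = res.profiles["+"]
        assert profile.sum() == 3
        assert profile[4] == 3  # bin [center, center+100)

    def test_no_centers_rejected(self):
        with pytest.raises(ValueError):
            metagene([], [], half_window=400, bin_size=100)

    def test_misaligned_bin_rejected(self):
        with pytest.raises(ValueError):
            metagene([], [("chr1", 5000)], half_window=450, bin_size=100)

    def test_mean_of_identical_layouts_equals_single_profile(self):
        reads = self.reads(10_050, 10_120) + self.reads(50_050, 50_120)
        one = metagene(reads, [("chr1", 10_000)], 400, 100)
        both = metagene(reads, [("chr1", 10_000), ("chr1", 50_000)], 400, 100)
        np.testing.assert_allclose(both.profiles["+"], one.profiles["+"])

    def test_edge_center_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="edge"):
            res = metagene(
                self.reads(500), [("chr1", 100), ("chr1", 10_000)], 400, 100
            )
        assert len(res.centers_used) == 1
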