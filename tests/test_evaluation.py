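import numpy as np
import pytest

from tucall import (
    ConsensusAnnotation,
    TranscriptionUnit,
    annotation_errors,
    genome_coverage,
    match_units,
    transcript_density,
    tua,
    tua_closed_form,
)


def ann(symbol, start, end, strand="+", chrom="chr1"):
    return ConsensusAnnotation(symbol, chrom, strand, start, end)


def unit(start, end, strand="+", chrom="chr1"):
    return TranscriptionUnit(chrom, start, end, strand, id=f"{start}-{end}{strand}")


class TestMatchUnits:
    def test_exact_cover_gives_full_overlap_pair(self):
        m = match_units([unit(0, 1000)], [ann("A", 0, 1000)])
        u, ov = m.pairs["A"]
        assert ov == 1000 and (u.start, u.end) == (0, 1000)
        assert not m.unmatched_annotations and not m.unmatched_units

    def test_best_overlap_wins(self):
        u60, u30 = unit(0, 600), unit(650, 950)
        m = match_units([u60, u30], [ann("A", 0, 1000)])
        assert m.pairs["A"][0] == u60
        assert m.unmatched_units == [u30]

    def test_strand_respected(self):
        m = match_units([unit(0, 1000, "-")], [ann("A", 0, 1000, "+")])
        assert m.unmatched_annotations == ["A"]

    def test_overlap_tie_broken_to_five_prime_unit(self):
        a, b = unit(100, 200), unit(300, 400)
        m = match_units([b, a], [ann("A", 150, 350)])  # both overlap 50 bp
        assert m.pairs["A"][0] == a


class TestAnnotationErrors:
    def test_merged_error_counted_per_spanning_unit(self):
        rep = annotation_errors(
            [unit(0, 2000)], [ann("A", 0, 800), ann("B", 1200, 2000)]
        )
        assert (rep.n_merged, rep.n_dissociated) == (1, 0)
        assert rep.rate == pytest.approx(0.5)

    def test_dissociated_error_counted_per_fragmented_annotation(self):
        rep = annotation_errors([unit(0, 300), unit(500, 900)], [ann("A", 0, 1000)])
        assert (rep.n_merged, rep.n_dissociated) == (0, 1)

    def test_perfect_one_to_one_calls_have_zero_rate(self):
        anns = [ann(f"G{i}", i * 2000, i * 2000 + 1000) for i in range(10)]
        units = [unit(i * 2000, i * 2000 + 1000) for i in range(10)]
        rep = annotation_errors(units, anns)
        assert rep.rate == 0.0 and rep.n_eval == 10

    def test_overlapping_annotation_input_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            annotation_errors([], [ann("A", 0, 100), ann("B", 50, 200)])

    def test_counting_invariant_under_unit_reordering(self):
        anns = [ann("A", 0, 800), ann("B", 1200, 2000)]
        units = [unit(0, 2000), unit(2500, 2600), unit(100, 150)]
        a = annotation_errors(units, anns)
        b = annotation_errors(units[::-1], anns)
        assert a == b


class TestTua:
    def test_exact_gene_body_call_scores_one(self):
        res = tua([unit(1000, 2000)], [ann("A", 1000, 2000)])
        assert res.tp_hat == pytest.approx(1.0)
        assert res.fp5_hat == pytest.approx(0.0)
        assert res.tua == pytest.approx(1.0)

    def test_no_calls_score_zero(self):
        res = tua([], [ann("A", 1000, 2000)])
        assert res.tua == 0.0 and res.fn_hat == 1.0

    def test_full_gene_plus_full_upstream_scores_half(self):
        res = tua([unit(0, 2000)], [ann("A", 1000, 2000)])
        assert res.tp_hat == pytest.approx(1.0)
        assert res.fp5_hat == pytest.approx(1.0)
        assert res.tua == pytest.approx(0.5)

    def test_minus_strand_upstream_is_rightward(self):
        # '-' gene [1000,2000): upstream region is [2000,3000)
        res = tua([unit(1000, 3000, "-")], [ann("A", 1000, 2000, "-")])
        assert res.fp5_hat == pytest.approx(1.0)
        assert res.tua == pytest.approx(0.5)

    def test_downstream_coverage_reported_but_excluded(self):
        res = tua([unit(1000, 3000)], [ann("A", 1000, 2000)])
        assert res.post_tts_hat == pytest.approx(1.0)
        assert res.tua == pytest.approx(1.0)  # run-through does not hurt TUA

    def test_closed_form_identity_and_constraint(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp = rng.uniform(0, 1)
            fp5 = rng.uniform(0, 1)
            fp5c = min(fp5, tp)
            tn5 = tp - fp5c
            fn = 1 - tp
            direct = (tp + tn5) / (tp + fn + fp5c + tn5) if tp + fn + fp5c + tn5 else 0.0
            assert tua_closed_form(tp, fp5) == pytest.approx(direct, abs=1e-12)

    def test_monotone_in_tp_and_fp5(self):
        grid = np.linspace(0.01, 1.0, 25)
        for fp5 in (0.0, 0.2, 0.6):
            vals = [tua_closed_form(tp, fp5) for tp in grid]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        for tp in (0.3, 0.7, 1.0):
            vals = [tua_closed_form(tp, f) for f in grid]
            assert all(a + 1e-12 >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_upstream_fraction_rejected(self):
        with pytest.raises(ValueError):
            tua([unit(0, 10)], [ann("A", 0, 10)], upstream_fraction=0.0)


class TestTranscriptDensity:
    def test_perfect_calls_fill_body_bins_only(self):
        anns = [ann("A", 10_000, 20_000), ann("B", 40_000, 50_000, "-")]
        units = [unit(10_000, 20_000), unit(40_000, 50_000, "-")]
        d = transcript_density(units, anns, n_bins=30)
        np.testing.assert_allclose(d[10:20], 1.0)
        np.testing.assert_allclose(d[:10], 0.0)
        np.testing.assert_allclose(d[20:], 0.0)

    def test_no_calls_all_zero(self):
        d = transcript_density([], [ann("A", 0, 1000)], n_bins=9)
        np.testing.assert_allclose(d, 0.0)

    def test_half_called_gives_half_density(self):
        anns = [ann("A", 10_000, 20_000), ann("B", 40_000, 50_000)]
        d = transcript_density([unit(10_000, 20_000)], anns, n_bins=6)
        np.testing.assert_allclose(d[2:4], 0.5)

    def test_bad_bin_count_rejected(self):
        with pytest.raises(ValueError):
            transcript_density([], [ann("A", 0, 10)], n_bins=10)


class TestGenomeCoverage:
    LEN = {"chr1": 10_000}

    def test_exact_calls_cover_genic_only(self):
        anns = [ann("A", 1000, 2000)]
        units = [unit(1000, 2000)]
        genic, inter = genome_coverage(units, anns, self.LEN)
        assert genic == pytest.approx(1.0)
        assert inter == 0.0

    def test_no_units_covers_nothing(self):
        assert genome_coverage([], [ann("A", 0, 500)], self.LEN) == (0.0, 0.0)

    def test_small_unit_inside_long_gene(self):
        anns = [ann("A", 0, 1000)]  # 10 windows of 100 bp
        genic, _ = genome_coverage([unit(300, 400)], anns, self.LEN)
        assert genic == pytest.approx(1 / 10)
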