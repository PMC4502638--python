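import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from tucall import (
    HmmModel,
    NONTRANSCRIBED,
    TRANSCRIBED,
    StatePath,
    WindowedCounts,
    baum_welch_train,
    emission_logdensity,
    forward_backward,
    path_to_units,
    viterbi,
)
from tucall.hmm import _train, path_log_joint, simulate_hmm

from conftest import brute_force_loglike

MODEL = HmmModel(k_t=2.0, theta_t=5.0, sigma2=10.0, lt_prob_b=4.0, n_trans=0.02)


class TestEmission:
    def test_background_exponential_closed_form(self):
        # sigma2 = 1 makes the background Exp(1): log f(1) = -1
        m = replace(MODEL, sigma2=1.0)
        assert emission_logdensity(1.0, NONTRANSCRIBED, m) == pytest.approx(-1.0)

    def test_transcribed_gamma_closed_form(self):
        m = replace(MODEL, k_t=1.0, theta_t=2.0)
        expected = math.log(0.5 * math.exp(-1.0))
        assert emission_logdensity(2.0, TRANSCRIBED, m) == pytest.approx(expected)

    @pytest.mark.parametrize("state", [NONTRANSCRIBED, TRANSCRIBED])
    def test_density_normalizes(self, state):
        val, _ = quad(lambda x: math.exp(emission_logdensity(x, state, MODEL)), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_emission_rejected(self):
        with pytest.raises(ValueError):
            emission_logdensity(0.0, TRANSCRIBED, MODEL)

    def test_background_mean_is_pinned_at_one(self):
        for s2 in (1.0, 5.0, 30.0, 50.0):
            val, _ = quad(
                lambda x: x * math.exp(
                    emission_logdensity(x, NONTRANSCRIBED, replace(MODEL, sigma2=s2))
                ),
                0, np.inf,
            )
            assert val == pytest.approx(1.0, abs=1e-6)


class TestForwardBackward:
    def test_loglike_matches_brute_force_path_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.poisson(3.0, size=10)
            wc = WindowedCounts("c", "+", 50, counts)
            post, ll = forward_backward(wc, MODEL)
            _, _, ll_bf = brute_force_loglike(counts, MODEL)
            assert ll == pytest.approx(ll_bf, rel=1e-8)
            assert np.all((post >= 0) & (post <= 1))

    def test_all_zero_counts_stay_background(self):
        wc = WindowedCounts("c", "+", 50, np.zeros(50, dtype=int))
        post, _ = forward_backward(wc, MODEL)
        assert np.all(post < 0.5)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            forward_backward(np.array([]), MODEL)

    def test_genome_scale_no_underflow(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.05, size=200_000)
        wc = WindowedCounts("c", "+", 50, counts)
        post, ll = forward_backward(wc, replace(MODEL, lt_prob_b=350.0))
        assert math.isfinite(ll)
        assert np.all(np.isfinite(post))


class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            counts = rng.poisson(2.5, size=12)
            wc = WindowedCounts("c", "+", 50, counts)
            sp = viterbi(wc, MODEL)
            paths, lp, _ = brute_force_loglike(counts, MODEL)
            best = lp.max()
            assert sp.log_joint == pytest.approx(best, rel=1e-8)
            optima = paths[lp >= best - 1e-9]
            assert any(np.array_equal(sp.states, p) for p in optima)
            if len(optima) == 1:
                np.testing.assert_array_equal(sp.states, optima[0])

    def test_log_joint_matches_direct_path_evaluation(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, size=30)
        wc = WindowedCounts("c", "-", 50, counts)
        sp = viterbi(wc, MODEL)
        assert sp.log_joint == pytest.approx(path_log_joint(wc, sp.states, MODEL))

    def test_all_zero_counts_decode_nontranscribed(self):
        wc = WindowedCounts("c", "+", 50, np.zeros(40, dtype=int))
        assert not viterbi(wc, MODEL).states.any()

    def test_high_block_called_as_single_run(self):
        counts = np.zeros(60, dtype=int)
        counts[20:40] = 12
        wc = WindowedCounts("c", "+", 50, counts)
        sp = viterbi(wc, MODEL)
        units = path_to_units(sp, wc)
        assert len(units) == 1
        assert (units[0].start, units[0].end) == (20 * 50, 40 * 50)

    def test_minus_strand_is_mirror_of_plus(self):
        """Decoding is 5'->3'; a minus-strand vector decodes like its
        reversed plus-strand twin, mapped back to genomic order."""
        rng = np.random.default_rng(9)
        counts = rng.poisson(2.0, size=40)
        minus = viterbi(WindowedCounts("c", "-", 50, counts), MODEL)
        plus_rev = viterbi(WindowedCounts("c", "+", 50, counts[::-1]), MODEL)
        np.testing.assert_array_equal(minus.states, plus_rev.states[::-1])


class TestPathToUnits:
    WC = WindowedCounts("chr1", "+", 50, np.zeros(7, dtype=int))

    def test_single_run_maps_to_window_scaled_interval(self):
        sp = StatePath(np.array([0, 0, 1, 1, 1, 0, 0]), 0.0)
        units = path_to_units(sp, self.WC)
        assert [(u.start, u.end) for u in units] == [(100, 250)]
        assert units[0].strand == "+"

    def test_all_background_yields_no_units(self):
        assert path_to_units(StatePath(np.zeros(7), 0.0), self.WC) == []

    def test_runs_split_by_single_gap(self):
        sp = StatePath(np.array([1, 1, 0, 1, 1, 0, 0]), 0.0)
        units = path_to_units(sp, self.WC)
        assert [(u.start, u.end) for u in units] == [(0, 100), (150, 250)]

    def test_final_unit_clipped_to_chrom_length(self):
        wc = WindowedCounts("chr1", "+", 50, np.zeros(3, dtype=int), chrom_length=130)
        units = path_to_units(StatePath(np.array([0, 1, 1]), 0.0), wc)
        assert units[0].end == 130

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            path_to_units(StatePath(np.zeros(3), 0.0), self.WC)


class TestBaumWelch:
    def test_max_iter_zero_returns_init_unchanged(self):
        wc = WindowedCounts("c", "+", 50, np.arange(10))
        assert baum_welch_train(wc, MODEL, max_iter=0) is MODEL

    def test_tuning_parameters_bit_identical_after_training(self):
        rng = np.random.default_rng(5)
        vals, _ = simulate_hmm(MODEL, 5000, rng)
        fit = baum_welch_train(vals, replace(MODEL, pseudocount=0.0), max_iter=25)
        assert fit.sigma2 == MODEL.sigma2
        assert fit.lt_prob_b == MODEL.lt_prob_b
        assert fit.pseudocount == 0.0

    def test_loglike_monotone_over_many_iterations(self):
        rng = np.random.default_rng(6)
        vals, _ = simulate_hmm(MODEL, 20_000, rng)
        _, hist, _, _ = _train(
            vals, replace(MODEL, pseudocount=0.0, k_t=1.0, theta_t=2.0),
            max_iter=50, tol=0.0,
        )
        assert np.all(np.diff(hist) > -1e-6)

    def test_parameter_recovery_from_simulated_data(self):
        true = HmmModel(2.0, 5.0, sigma2=10.0, lt_prob_b=3.0, n_trans=0.01,
                        pseudocount=0.0)
        rng = np.random.default_rng(0)
        vals, _ = simulate_hmm(true, 100_000, rng)
        fit = baum_welch_train(
            vals, replace(true, k_t=1.0, theta_t=3.0, n_trans=0.003), max_iter=100
        )
        assert fit.k_t * fit.theta_t == pytest.approx(10.0, rel=0.10)
        assert fit.n_trans == pytest.approx(0.01, rel=0.20)

    def test_degenerate_constant_data_warns_not_crashes(self):
        vals = np.full(2000, 5.0)
        with pytest.warns(UserWarning):
            fit = baum_welch_train(vals, replace(MODEL, pseudocount=0.0), max_iter=20)
        assert math.isfinite(fit.k_t)


def test_stronger_length_penalty_never_shortens_median_unit(small_counts):
    """The T->N penalty acts as a length control: larger -LtProbB values
    can only lengthen called units on a fixed counts vector."""
    wc = small_counts[("chrSim", "+")]
    base = baum_welch_train(wc, HmmModel(2.0, 5.0, sigma2=30.0, lt_prob_b=275.0),
                            max_iter=15)
    medians = []
    for lt in (50.0, 162.5, 275.0, 387.5, 500.0):
        units = path_to_units(viterbi(wc, replace(base, lt_prob_b=lt)), wc)
        medians.append(np.median([len(u) for u in units]))
    assert all(a <= b for a, b in zip(medians, medians[1:]))
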