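import numpy as np
import pytest

from tucall import ConsensusAnnotation, GenomeSpec, bin_reads, simulate_genome, simulate_reads


def brute_force_loglike(values, model):
    """Path-sum log-likelihood by exhaustive enumeration (<= ~14 windows)."""
    from itertools import product

    from scipy.special import logsumexp

    from tucall.hmm import _emission_matrix

    logem = _emission_matrix(np.asarray(values, float) + model.pseudocount, model)
    loga = model.log_transition_matrix()
    logpi = model.log_initial()
    n = len(values)
    paths = np.array(list(product((0, 1), repeat=n)))
    lp = logpi[paths[:, 0]] + logem[np.arange(n), paths].sum(axis=1)
    if n > 1:
        lp = lp + loga[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    return paths, lp, float(logsumexp(lp))


@pytest.fixture(scope="session")
def small_truth():
    """2-Mb human-preset simulated genome shared across tests."""
    spec = GenomeSpec(chrom_lengths={"chrSim": 2_000_000}, seed=7, n_enhancers=4)
    truth = simulate_genome(spec)
    reads = simulate_reads(truth)
    return spec, truth, reads


@pytest.fixture(scope="session")
def small_counts(small_truth):
    spec, truth, reads = small_truth
    return bin_reads(reads, spec.window_size, spec.chrom_lengths)


@pytest.fixture(scope="session")
def truth_consensus(small_truth):
    _, truth, _ = small_truth
    return [
        ConsensusAnnotation(g.symbol, g.chrom, g.strand, g.start, g.end)
        for g in truth.genes
    ]
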