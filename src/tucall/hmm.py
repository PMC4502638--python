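"""Two-state hidden Markov model for nascent-transcription read counts.

The model segments each chromosome strand into TRANSCRIBED and
NONTRANSCRIBED stretches from read counts in fixed windows. Emissions are
gamma densities evaluated at ``count + pseudocount``: the non-transcribed
state uses the constrained gamma Γ(shape=σ², scale=1/σ²), whose mean is
exactly 1 (matching the near-zero background of run-on data after a unit
pseudocount), and the transcribed state uses an unconstrained Γ(k_T, θ_T).
Two transition parameters are held out for tuning: the probability of
leaving the transcribed state, parameterised on the natural-log scale as
``P(T→N) = exp(-lt_prob_b)`` (a length penalty on called units), and σ².
The remaining parameters (k_T, θ_T and N = P(N→T)) are learned by
Baum-Welch EM; decoding uses Viterbi.

All recursions run in log space so that transition penalties like
``exp(-350)`` and genome-scale products never underflow. Each strand is
scanned 5'→3' (minus-strand windows are reversed before decoding and the
state path mapped back), because the asymmetric transition structure
encodes 3'-end behaviour.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln, polygamma, psi

from .core import TranscriptionUnit, WindowedCounts

logger = logging.getLogger(__name__)

NONTRANSCRIBED = 0
TRANSCRIBED = 1

#: Floor on log-densities / log-probabilities; avoids -inf propagation.
LOG_FLOOR = -1e12

#: Cap on the gamma shape when EM data are degenerate (zero spread).
_SHAPE_CAP = 1e6


@dataclass(frozen=True)
class HmmModel:
    """Full parameter set of the two-state gamma HMM.

    Parameters
    ----------
    k_t, theta_t
        Shape and scale of the transcribed-state gamma (both > 0).
    sigma2
        Background tuning parameter σ² > 0; the non-transcribed state emits
        Γ(shape=σ², scale=1/σ²), whose mean is pinned at 1.
    lt_prob_b
        Positive number v with log P(TRANSCRIBED→NONTRANSCRIBED) = -v
        (natural log). Larger values penalise leaving the transcribed
        state, lengthening called units.
    n_trans
        N = P(NONTRANSCRIBED→TRANSCRIBED), in (0, 1).
    pseudocount
        Added to every window count before emission evaluation (default 1),
        keeping emissions strictly positive.
    """

    k_t: float
    theta_t: float
    sigma2: float = 30.0
    lt_prob_b: float = 350.0
    n_trans: float = 1e-3
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.k_t <= 0 or self.theta_t <= 0:
            raise ValueError("transcribed gamma parameters must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.lt_prob_b <= 0:
            raise ValueError("lt_prob_b must be positive")
        if not 0.0 < self.n_trans < 1.0:
            raise ValueError("n_trans must lie in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    def log_transition_matrix(self) -> np.ndarray:
        """2x2 log transition matrix, rows = from-state."""
        log_tn = -self.lt_prob_b
        # log(1 - e^-v): underflows gracefully to 0.0 for large v
        log_tt = math.log1p(-math.exp(log_tn)) if log_tn > -745 else 0.0
        loga = np.array(
            [
                [math.log1p(-self.n_trans), math.log(self.n_trans)],
                [log_tn, log_tt],
            ]
        )
        return np.maximum(loga, LOG_FLOOR)

    def log_initial(self) -> np.ndarray:
        """Sequences start non-transcribed: chromosome ends lie outside genes."""
        return np.array([0.0, LOG_FLOOR])


@dataclass
class StatePath:
    """Decoded state sequence (genomic window order) with its log joint."""

    states: np.ndarray
    log_joint: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.states)


def emission_logdensity(x, state: int, model: HmmModel):
    """Log gamma density of emission value(s) ``x`` under one state.

    ``x`` must be strictly positive (guaranteed upstream by the
    pseudocount); the density is Γ(σ², 1/σ²) for NONTRANSCRIBED and
    Γ(k_T, θ_T) for TRANSCRIBED.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("emission values must be strictly positive")
    if state == NONTRANSCRIBED:
        shape, scale = model.sigma2, 1.0 / model.sigma2
    elif state == TRANSCRIBED:
        shape, scale = model.k_t, model.theta_t
    else:
        raise ValueError(f"unknown state {state}")
    out = _gamma_logpdf(x, shape, scale)
    return out if out.ndim else float(out)


def _gamma_logpdf(x: np.ndarray, shape: float, scale: float) -> np.ndarray:
    logx = np.log(x)
    out = (shape - 1.0) * logx - x / scale - gammaln(shape) - shape * math.log(scale)
    return np.maximum(out, LOG_FLOOR)


def _emission_matrix(values: np.ndarray, model: HmmModel) -> np.ndarray:
    """(n, 2) log-density matrix; evaluated once per unique value."""
    uniq, inv = np.unique(values, return_inverse=True)
    le = np.empty((len(uniq), 2))
    le[:, NONTRANSCRIBED] = _gamma_logpdf(uniq, model.sigma2, 1.0 / model.sigma2)
    le[:, TRANSCRIBED] = _gamma_logpdf(uniq, model.k_t, model.theta_t)
    le = np.maximum(np.nan_to_num(le, neginf=LOG_FLOOR), LOG_FLOOR)
    return le[inv]


def _values_5to3(counts: WindowedCounts | np.ndarray, model: HmmModel) -> np.ndarray:
    """Emission values in scan (5'→3') order: count + pseudocount."""
    if isinstance(counts, WindowedCounts):
        vals = np.asarray(counts.counts, dtype=float) + model.pseudocount
        if counts.strand == "-":
            vals = vals[::-1]
        return np.ascontiguousarray(vals)
    return np.asarray(counts, dtype=float) + model.pseudocount


# ---------------------------------------------------------------------------
# numba kernels (2-state, log space)


@njit(cache=True)
def _forward_kernel(logem, loga, logpi):
    n = logem.shape[0]
    alpha = np.empty((n, 2))
    for j in range(2):
        alpha[0, j] = logpi[j] + logem[0, j]
    for t in range(1, n):
        for j in range(2):
            a = alpha[t - 1, 0] + loga[0, j]
            b = alpha[t - 1, 1] + loga[1, j]
            m = a if a > b else b
            alpha[t, j] = m + math.log(math.exp(a - m) + math.exp(b - m)) + logem[t, j]
    la, lb = alpha[n - 1, 0], alpha[n - 1, 1]
    m = la if la > lb else lb
    ll = m + math.log(math.exp(la - m) + math.exp(lb - m))
    return alpha, ll


@njit(cache=True)
def _backward_kernel(logem, loga):
    n = logem.shape[0]
    beta = np.empty((n, 2))
    beta[n - 1, 0] = 0.0
    beta[n - 1, 1] = 0.0
    for t in range(n - 2, -1, -1):
        for i in range(2):
            a = loga[i, 0] + logem[t + 1, 0] + beta[t + 1, 0]
            b = loga[i, 1] + logem[t + 1, 1] + beta[t + 1, 1]
            m = a if a > b else b
            beta[t, i] = m + math.log(math.exp(a - m) + math.exp(b - m))
    return beta


@njit(cache=True)
def _estep_kernel(logem, loga, logpi, x, logx):
    """One-pass E-step sufficient statistics for a single sequence.

    Returns (ll, sum_gamma_T, sum_gamma_T_x, sum_gamma_T_logx,
    sum_xi_NT, sum_gamma_N_head).
    """
    n = logem.shape[0]
    alpha, ll = _forward_kernel(logem, loga, logpi)
    beta = _backward_kernel(logem, loga)
    sg_t = 0.0
    sg_t_x = 0.0
    sg_t_lx = 0.0
    s_xi_nt = 0.0
    sg_n_head = 0.0
    for t in range(n):
        g1 = math.exp(alpha[t, 1] + beta[t, 1] - ll)
        sg_t += g1
        sg_t_x += g1 * x[t]
        sg_t_lx += g1 * logx[t]
        if t < n - 1:
            sg_n_head += math.exp(alpha[t, 0] + beta[t, 0] - ll)
            s_xi_nt += math.exp(
                alpha[t, 0] + loga[0, 1] + logem[t + 1, 1] + beta[t + 1, 1] - ll
            )
    return ll, sg_t, sg_t_x, sg_t_lx, s_xi_nt, sg_n_head


@njit(cache=True)
def _viterbi_kernel(logem, loga, logpi):
    """Max-probability path; ties prefer NONTRANSCRIBED (state 0)."""
    n = logem.shape[0]
    delta = np.empty((n, 2))
    psi_bt = np.empty((n, 2), dtype=np.int8)
    for j in range(2):
        delta[0, j] = logpi[j] + logem[0, j]
        psi_bt[0, j] = 0
    for t in range(1, n):
        for j in range(2):
            c0 = delta[t - 1, 0] + loga[0, j]
            c1 = delta[t - 1, 1] + loga[1, j]
            if c0 >= c1:
                delta[t, j] = c0 + logem[t, j]
                psi_bt[t, j] = 0
            else:
                delta[t, j] = c1 + logem[t, j]
                psi_bt[t, j] = 1
    states = np.empty(n, dtype=np.int8)
    states[n - 1] = 0 if delta[n - 1, 0] >= delta[n - 1, 1] else 1
    for t in range(n - 2, -1, -1):
        states[t] = psi_bt[t + 1, states[t + 1]]
    return states, delta[n - 1, states[n - 1]]


# ---------------------------------------------------------------------------
# public operations


def forward_backward(
    counts: WindowedCounts | np.ndarray, model: HmmModel
) -> tuple[np.ndarray, float]:
    """Posterior P(TRANSCRIBED) per window and the total log-likelihood.

    Posteriors are returned in genomic window order regardless of strand.
    """
    values = _values_5to3(counts, model)
    if len(values) == 0:
        raise ValueError("counts must be non-empty")
    logem = _emission_matrix(values, model)
    loga = model.log_transition_matrix()
    logpi = model.log_initial()
    alpha, ll = _forward_kernel(logem, loga, logpi)
    beta = _backward_kernel(logem, loga)
    post = np.exp(alpha[:, TRANSCRIBED] + beta[:, TRANSCRIBED] - ll)
    post = np.clip(post, 0.0, 1.0)
    if isinstance(counts, WindowedCounts) and counts.strand == "-":
        post = post[::-1]
    return post, float(ll)


def viterbi(counts: WindowedCounts | np.ndarray, model: HmmModel) -> StatePath:
    """Maximum-probability state path (genomic order); ties fall to
    NONTRANSCRIBED for deterministic, conservative calls."""
    values = _values_5to3(counts, model)
    if len(values) == 0:
        raise ValueError("counts must be non-empty")
    logem = _emission_matrix(values, model)
    states, log_joint = _viterbi_kernel(
        logem, model.log_transition_matrix(), model.log_initial()
    )
    if isinstance(counts, WindowedCounts) and counts.strand == "-":
        states = states[::-1]
    return StatePath(states, float(log_joint))


def path_log_joint(counts: WindowedCounts | np.ndarray, states: np.ndarray, model: HmmModel) -> float:
    """Direct log P(path, observations); same scan orientation as decoding."""
    values = _values_5to3(counts, model)
    states = np.asarray(states, dtype=np.int64)
    if isinstance(counts, WindowedCounts) and counts.strand == "-":
        states = states[::-1]
    logem = _emission_matrix(values, model)
    loga = model.log_transition_matrix()
    logpi = model.log_initial()
    total = logpi[states[0]] + logem[0, states[0]]
    for t in range(1, len(states)):
        total += loga[states[t - 1], states[t]] + logem[t, states[t]]
    return float(total)


def _weighted_gamma_mle(
    wsum: float, wmean: float, wlogmean: float, fallback: tuple[float, float]
) -> tuple[float, float]:
    """Gamma (shape, scale) maximising the posterior-weighted likelihood.

    Solves ``log k - digamma(k) = log(wmean) - wlogmean`` by Newton steps
    from the standard closed-form approximation.
    """
    if wsum <= 0 or wmean <= 0:
        return fallback
    s = math.log(wmean) - wlogmean
    if not math.isfinite(s) or s <= 1e-12:
        warnings.warn("degenerate transcribed emissions (zero spread); shape capped")
        k = _SHAPE_CAP
        return k, wmean / k
    k = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        f = math.log(k) - psi(k) - s
        fp = 1.0 / k - polygamma(1, k)
        step = f / fp
        k_new = k - step
        while k_new <= 0:
            step *= 0.5
            k_new = k - step
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    k = min(k, _SHAPE_CAP)
    return k, wmean / k


def _as_sequences(
    counts: WindowedCounts | np.ndarray | Sequence, model: HmmModel
) -> list[np.ndarray]:
    if isinstance(counts, (WindowedCounts, np.ndarray)):
        counts = [counts]
    return [_values_5to3(c, model) for c in counts]


def _train(
    counts,
    model_init: HmmModel,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[HmmModel, list[float], bool, int]:
    """Constrained Baum-Welch: updates k_T, θ_T and N only.

    σ², lt_prob_b and the pseudocount are the held-out tuning parameters
    and are returned untouched. Returns (model, loglike history,
    converged flag, iterations run).
    """
    seqs = _as_sequences(counts, model_init)
    if not seqs or any(len(s) == 0 for s in seqs):
        raise ValueError("counts must be non-empty")
    model = model_init
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        loga = model.log_transition_matrix()
        logpi = model.log_initial()
        ll_total = 0.0
        sg_t = sg_t_x = sg_t_lx = s_xi_nt = sg_n_head = 0.0
        for values in seqs:
            logem = _emission_matrix(values, model)
            ll, a, b, c, d, e = _estep_kernel(
                logem, loga, logpi, values, np.log(values)
            )
            ll_total += ll
            sg_t += a
            sg_t_x += b
            sg_t_lx += c
            s_xi_nt += d
            sg_n_head += e
        if not math.isfinite(ll_total) or any(
            not math.isfinite(v) for v in (sg_t, sg_t_x, sg_t_lx, s_xi_nt, sg_n_head)
        ):
            raise FloatingPointError(f"NaN/inf in EM statistics at iteration {it}")
        history.append(ll_total)
        logger.info("EM iteration %d: log-likelihood %.6f", it, ll_total)
        if len(history) > 1 and history[-1] - history[-2] < tol:
            converged = True
            break
        # M-step
        if sg_t > 0:
            wmean = sg_t_x / sg_t
            wlogmean = sg_t_lx / sg_t
            k_t, theta_t = _weighted_gamma_mle(
                sg_t, wmean, wlogmean, (model.k_t, model.theta_t)
            )
        else:
            warnings.warn("no posterior mass on the transcribed state")
            k_t, theta_t = model.k_t, model.theta_t
        if sg_n_head > 0:
            n_trans = min(max(s_xi_nt / sg_n_head, 1e-10), 1.0 - 1e-10)
        else:
            n_trans = model.n_trans
        model = replace(model, k_t=k_t, theta_t=theta_t, n_trans=n_trans)
    return model, history, converged, it


def baum_welch_train(
    counts,
    model_init: HmmModel,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> HmmModel:
    """Train k_T, θ_T and N by EM; the tuning parameters stay fixed.

    ``counts`` may be one WindowedCounts, a raw count vector, or a sequence
    of either (statistics pool across sequences). ``max_iter=0`` returns
    ``model_init`` unchanged.
    """
    if max_iter == 0:
        return model_init
    model, _, _, _ = _train(counts, model_init, max_iter=max_iter, tol=tol)
    return model


def initial_model(
    counts,
    sigma2: float = 30.0,
    lt_prob_b: float = 350.0,
    pseudocount: float = 1.0,
    n_trans: float = 1e-3,
) -> HmmModel:
    """Moment-based EM starting point.

    k_T, θ_T come from the moments of emission values above their 75th
    percentile (a crude stand-in for transcribed windows); N starts at the
    scale of one gene-sized run per thousand windows.
    """
    ref = HmmModel(1.0, 1.0, sigma2, lt_prob_b, n_trans, pseudocount)
    seqs = _as_sequences(counts, ref)
    values = np.concatenate(seqs)
    hi = values[values > np.percentile(values, 75)]
    if len(hi) < 2 or np.var(hi) <= 0:
        k_t, theta_t = 2.0, max(float(np.mean(values)), pseudocount + 0.5)
    else:
        m, v = float(np.mean(hi)), float(np.var(hi))
        k_t = max(m * m / v, 1e-3)
        theta_t = v / m
    return HmmModel(k_t, theta_t, sigma2, lt_prob_b, n_trans, pseudocount)


def path_to_units(path: StatePath, counts: WindowedCounts) -> list[TranscriptionUnit]:
    """Maximal TRANSCRIBED runs → stranded intervals in bp.

    Boundaries are run boundaries × window size; the final unit is clipped
    to the chromosome length. Units are reported in genomic orientation.
    """
    states = np.asarray(path.states, dtype=np.int8)
    if len(states) != len(counts):
        raise ValueError("state path and counts lengths differ")
    padded = np.concatenate(([0], states, [0]))
    d = np.diff(padded)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    w = counts.window_size
    units = []
    for s, e in zip(run_starts, run_ends):
        start = int(s) * w
        end = min(int(e) * w, counts.chrom_length)
        units.append(
            TranscriptionUnit(
                counts.chrom,
                start,
                end,
                counts.strand,
                id=f"{counts.chrom}:{start}-{end}:{counts.strand}",
            )
        )
    return units


def simulate_hmm(
    model: HmmModel, n_windows: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (emission values, states) directly from the model.

    Used for parameter-recovery checks: states follow the Markov chain
    (started non-transcribed), emissions the state's gamma. The returned
    values already live on the emission scale (no pseudocount is added
    back), so train with ``pseudocount=0``.
    """
    p_tn = math.exp(-model.lt_prob_b)
    states = np.empty(n_windows, dtype=np.int8)
    state = NONTRANSCRIBED
    for t in range(n_windows):
        states[t] = state
        if state == NONTRANSCRIBED:
            state = TRANSCRIBED if rng.random() < model.n_trans else NONTRANSCRIBED
        else:
            state = NONTRANSCRIBED if rng.random() < p_tn else TRANSCRIBED
    values = np.where(
        states == TRANSCRIBED,
        rng.gamma(model.k_t, model.theta_t, size=n_windows),
        rng.gamma(model.sigma2, 1.0 / model.sigma2, size=n_windows),
    )
    return values, states
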