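"""Model/results interface for transcription-unit calling.

:class:`TranscriptionHMM` holds the windowed counts and the held-out
tuning parameters; :meth:`TranscriptionHMM.fit` runs constrained
Baum-Welch and returns a :class:`TranscriptionHMMResults` carrying the
trained parameters, the likelihood trace and decoding methods.

Example
-------
>>> model = TranscriptionHMM.from_reads(reads, chrom_lengths)
>>> res = model.fit()
>>> units = res.decode()
>>> print(res.summary())
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import hmm
from .core import AlignedRead, TranscriptionUnit, WindowedCounts
from .io import bin_reads, read_bed, read_chrom_sizes


class TranscriptionHMM:
    """Two-state gamma HMM over strand-specific windowed read counts.

    Parameters
    ----------
    counts
        Mapping of (chrom, strand) to :class:`WindowedCounts`, or any
        iterable of WindowedCounts.
    sigma2
        Background tuning parameter (UTS); shape of the constrained
        non-transcribed gamma Γ(σ², 1/σ²). Typical mammalian range 5-50.
    lt_prob_b
        Length-penalty tuning parameter: -log P(T→N). Typical mammalian
        range 50-500; gene-dense genomes need larger values.
    pseudocount
        Added to every window count before emission evaluation.
    """

    def __init__(
        self,
        counts: Mapping[tuple[str, str], WindowedCounts] | Iterable[WindowedCounts],
        sigma2: float = 30.0,
        lt_prob_b: float = 350.0,
        pseudocount: float = 1.0,
    ) -> None:
        if isinstance(counts, Mapping):
            items = list(counts.values())
        else:
            items = list(counts)
        if not items:
            raise ValueError("no counts provided")
        # deterministic processing order, independent of input ordering
        items.sort(key=lambda wc: (wc.chrom, wc.strand))
        self.counts: dict[tuple[str, str], WindowedCounts] = {
            (wc.chrom, wc.strand): wc for wc in items
        }
        self.sigma2 = float(sigma2)
        self.lt_prob_b = float(lt_prob_b)
        self.pseudocount = float(pseudocount)
        self.window_size = items[0].window_size

    @classmethod
    def from_reads(
        cls,
        reads: Iterable[AlignedRead],
        chrom_lengths: dict[str, int],
        window_size: int = 50,
        **kwargs,
    ) -> "TranscriptionHMM":
        return cls(bin_reads(reads, window_size, chrom_lengths), **kwargs)

    @classmethod
    def from_bed(
        cls,
        reads_path: str | Path,
        chrom_sizes_path: str | Path,
        window_size: int = 50,
        **kwargs,
    ) -> "TranscriptionHMM":
        return cls.from_reads(
            read_bed(reads_path), read_chrom_sizes(chrom_sizes_path), window_size, **kwargs
        )

    def start_params(self, n_trans: float = 1e-3) -> hmm.HmmModel:
        """Moment-based EM initialisation over all sequences."""
        return hmm.initial_model(
            list(self.counts.values()),
            sigma2=self.sigma2,
            lt_prob_b=self.lt_prob_b,
            pseudocount=self.pseudocount,
            n_trans=n_trans,
        )

    def loglike(self, params: hmm.HmmModel) -> float:
        """Total log-likelihood of the data under ``params``."""
        return float(
            sum(hmm.forward_backward(wc, params)[1] for wc in self.counts.values())
        )

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-4,
        start_params: hmm.HmmModel | None = None,
    ) -> "TranscriptionHMMResults":
        """Constrained Baum-Welch EM; σ² and lt_prob_b stay fixed."""
        start = start_params if start_params is not None else self.start_params()
        if max_iter == 0:
            return TranscriptionHMMResults(self, start, [], False, 0)
        params, history, converged, n_iter = hmm._train(
            list(self.counts.values()), start, max_iter=max_iter, tol=tol
        )
        return TranscriptionHMMResults(self, params, history, converged, n_iter)


class TranscriptionHMMResults:
    """Fit results: trained parameters, likelihood trace, decoding."""

    def __init__(
        self,
        model: TranscriptionHMM,
        params: hmm.HmmModel,
        loglike_history: Sequence[float],
        converged: bool,
        n_iter: int,
    ) -> None:
        self.model = model
        self.params = params
        self.loglike_history = list(loglike_history)
        self.converged = converged
        self.n_iter = n_iter

    @property
    def llf(self) -> float:
        """Final training log-likelihood (NaN when EM was not run)."""
        return self.loglike_history[-1] if self.loglike_history else float("nan")

    def decode(self) -> list[TranscriptionUnit]:
        """Viterbi-call transcription units on every chromosome strand."""
        units: list[TranscriptionUnit] = []
        for wc in self.model.counts.values():
            path = hmm.viterbi(wc, self.params)
            units.extend(hmm.path_to_units(path, wc))
        return units

    def posterior(self) -> dict[tuple[str, str], np.ndarray]:
        """Per-window posterior P(TRANSCRIBED), keyed by (chrom, strand)."""
        return {
            key: hmm.forward_backward(wc, self.params)[0]
            for key, wc in self.model.counts.items()
        }

    def summary(self) -> str:
        p = self.params
        units = self.decode()
        lengths = np.array([len(u) for u in units]) if units else np.array([0])
        lines = [
            "Transcription-unit HMM results",
            "=" * 46,
            f"{'sequences (chrom,strand)':<32}{len(self.model.counts):>14}",
            f"{'windows total':<32}{sum(len(wc) for wc in self.model.counts.values()):>14}",
            f"{'window size (bp)':<32}{self.model.window_size:>14}",
            "-" * 46,
            f"{'k_T (transcribed shape)':<32}{p.k_t:>14.4f}",
            f"{'theta_T (transcribed scale)':<32}{p.theta_t:>14.4f}",
            f"{'transcribed mean k_T*theta_T':<32}{p.k_t * p.theta_t:>14.4f}",
            f"{'sigma2 (UTS, fixed)':<32}{p.sigma2:>14.4f}",
            f"{'-LtProbB (fixed)':<32}{p.lt_prob_b:>14.4f}",
            f"{'N = P(nontranscribed->transcr.)':<32}{p.n_trans:>14.6g}",
            f"{'pseudocount':<32}{p.pseudocount:>14.4f}",
            "-" * 46,
            f"{'EM iterations':<32}{self.n_iter:>14}",
            f"{'converged':<32}{str(self.converged):>14}",
            f"{'log-likelihood':<32}{self.llf:>14.2f}",
            f"{'called units':<32}{len(units):>14}",
            f"{'median unit length (bp)':<32}{int(np.median(lengths)):>14}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save_params(self, path: str | Path) -> None:
        """Plain-text key=value parameter dump for reproducibility."""
        p = self.params
        with open(path, "w") as fh:
            for key, val in [
                ("k_t", p.k_t),
                ("theta_t", p.theta_t),
                ("sigma2", p.sigma2),
                ("lt_prob_b", p.lt_prob_b),
                ("n_trans", p.n_trans),
                ("pseudocount", p.pseudocount),
                ("loglike", self.llf),
                ("n_iter", self.n_iter),
                ("converged", int(self.converged)),
            ]:
                fh.write(f"{key}={float(val)}\n")

    def plot_posterior(self, chrom: str, strand: str, ax=None):
        """Posterior transcription probability along one chromosome strand."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        wc = self.model.counts[(chrom, strand)]
        post = hmm.forward_backward(wc, self.params)[0]
        x = np.arange(len(post)) * wc.window_size / 1e6
        ax.fill_between(x, post, step="mid", alpha=0.6)
        ax.set_xlabel(f"{chrom} position (Mb)")
        ax.set_ylabel("P(transcribed)")
        ax.set_title(f"{chrom} ({strand})")
        return ax
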