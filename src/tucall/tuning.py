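"""Grid search over the two held-out HMM parameters and model selection.

Every (lt_prob_b, σ²) pair is trained, decoded and scored against the
expressed annotation set. The selection mirrors the published procedure:
models are first filtered to those whose median unit length lies within
the interquartile range of median lengths across the grid, then to those
calling between 1.25× and 1.5× as many units as there are consensus
annotations, and the minimum-overall-error-rate survivor wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import ConsensusAnnotation, TranscriptionUnit, WindowedCounts
from .evaluation import ErrorReport, annotation_errors
from .hmm import HmmModel
from .model import TranscriptionHMM

logger = logging.getLogger(__name__)

#: Mammalian default grids (10 steps each spanning the standard ranges).
DEFAULT_LT_GRID = tuple(np.linspace(50, 500, 10))
DEFAULT_UTS_GRID = tuple(np.linspace(5, 50, 10))
#: Gene-dense (non-mammalian) preset: stronger length penalties are needed
#: to keep densely packed genes from merging.
NONMAMMALIAN_LT_GRID = tuple(np.linspace(100, 2000, 10))


@dataclass
class GridResult:
    lt_prob_b: float
    sigma2: float
    model: HmmModel | None
    report: ErrorReport | None
    units: list[TranscriptionUnit] | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None and self.report is not None


def grid_search(
    counts,
    lt_values: Sequence[float] = DEFAULT_LT_GRID,
    uts_values: Sequence[float] = DEFAULT_UTS_GRID,
    expressed_annotations: Sequence[ConsensusAnnotation] = (),
    pseudocount: float = 1.0,
    max_iter: int = 30,
    tol: float = 1e-3,
    keep_units: bool = False,
) -> list[GridResult]:
    """Train/decode/score one model per (lt, σ²) grid point.

    Per-point failures are recorded on the result rather than raised, so a
    degenerate corner never voids the grid. Results are ordered by the
    (lt, σ²) grid regardless of traversal concerns.
    """
    if len(lt_values) == 0 or len(uts_values) == 0:
        raise ValueError("grids must be non-empty")
    results: list[GridResult] = []
    for lt in lt_values:
        for uts in uts_values:
            try:
                thmm = TranscriptionHMM(
                    counts, sigma2=uts, lt_prob_b=lt, pseudocount=pseudocount
                )
                res = thmm.fit(max_iter=max_iter, tol=tol)
                units = res.decode()
                report = annotation_errors(units, expressed_annotations)
                results.append(
                    GridResult(lt, uts, res.params, report,
                               units if keep_units else None)
                )
                logger.info(
                    "grid lt=%g uts=%g: %d units, rate %.4f",
                    lt, uts, report.n_units, report.rate,
                )
            except Exception as exc:  # degenerate grid point
                warnings.warn(f"grid point lt={lt}, uts={uts} failed: {exc}")
                results.append(GridResult(lt, uts, None, None, error=str(exc)))
    return results


def select_optimal(
    results: Sequence[GridResult],
    n_consensus: int,
    apply_filters: bool = True,
) -> GridResult:
    """Pick the best grid model by the published filter-then-minimise rule.

    Step 1 keeps models whose median unit length falls within the IQR of
    median lengths across the grid; step 2 keeps models calling strictly
    between 1.25× and 1.5× ``n_consensus`` units; step 3 returns the
    minimum-error-rate survivor (ties: smaller lt_prob_b, then smaller
    σ²). A filter that would empty the pool is skipped with a warning.
    """
    pool = [r for r in results if r.ok]
    if not pool:
        raise ValueError("no successful grid results to select from")
    if apply_filters and len(pool) > 1:
        medians = np.array([r.report.median_unit_length for r in pool])
        q1, q3 = np.percentile(medians, [25, 75])
        step1 = [r for r in pool if q1 <= r.report.median_unit_length <= q3]
        if step1:
            pool = step1
        else:
            warnings.warn("median-length IQR filter emptied the pool; skipped")
        step2 = [
            r for r in pool
            if 1.25 * n_consensus < r.report.n_units < 1.5 * n_consensus
        ]
        if step2:
            pool = step2
        else:
            warnings.warn("transcript-count filter emptied the pool; skipped")
    return min(pool, key=lambda r: (r.report.rate, r.lt_prob_b, r.sigma2))


def grid_table(results: Sequence[GridResult]):
    """One row per grid point with all error-report fields (DataFrame)."""
    import pandas as pd

    rows = []
    for r in results:
        row = {"lt_prob_b": r.lt_prob_b, "sigma2": r.sigma2, "error": r.error}
        if r.ok:
            row.update(
                n_merged=r.report.n_merged,
                n_dissociated=r.report.n_dissociated,
                n_eval=r.report.n_eval,
                rate=r.report.rate,
                n_units=r.report.n_units,
                median_unit_length=r.report.median_unit_length,
            )
            if r.model is not None:
                row.update(k_t=r.model.k_t, theta_t=r.model.theta_t,
                           n_trans=r.model.n_trans)
        rows.append(row)
    return pd.DataFrame(rows)
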