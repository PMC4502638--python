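"""Scoring called transcription units against consensus annotations.

Two error types are counted: a *merged annotation error* is one called
unit spanning two or more expressed annotations on its strand; a
*dissociated annotation error* is one annotation fragmented across two or
more called units. Boundary fidelity is summarised by the transcription
unit accuracy

    TUA = (TP̂ + 5'TN̂) / (TP̂ + FN̂ + 5'FP̂ + 5'TN̂)

where TP̂ is the mean fraction of the (length-scaled) gene body covered by
each annotation's best-matching unit, FN̂ = 1 − TP̂, and the upstream
quantities satisfy the constraint 5'FP̂ + 5'TN̂ = TP̂, giving the closed
form TUA = (2·TP̂ − 5'FP̂) / (1 + TP̂). Coverage downstream of the TTS is
reported (PostTTŜ) but excluded from TUA, since polymerase normally runs
past the polyadenylation site.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import ConsensusAnnotation, TranscriptionUnit, overlap_bp


@dataclass
class MatchMap:
    """Best-overlap assignment of one called unit per annotation.

    A unit may serve several annotations (the merged case); each
    annotation maps to at most one unit.
    """

    pairs: dict[str, tuple[TranscriptionUnit, int]]
    unmatched_annotations: list[str]
    unmatched_units: list[TranscriptionUnit]


@dataclass(frozen=True)
class ErrorReport:
    n_merged: int
    n_dissociated: int
    n_eval: int
    rate: float
    n_units: int
    median_unit_length: float


@dataclass(frozen=True)
class TuaResult:
    tp_hat: float
    fp5_hat: float
    tn5_hat: float
    fn_hat: float
    post_tts_hat: float
    tua: float


def _grouped(items, key):
    groups = defaultdict(list)
    for it in items:
        groups[key(it)].append(it)
    return groups


def _overlap_join(
    anns: Sequence[ConsensusAnnotation], units: Sequence[TranscriptionUnit]
):
    """Yield (ann, unit, overlap_bp) for same-(chrom,strand) overlaps."""
    unit_groups = _grouped(units, lambda u: (u.chrom, u.strand))
    for key, group_units in unit_groups.items():
        group_units.sort(key=lambda u: (u.start, u.end))
    ann_groups = _grouped(anns, lambda a: (a.chrom, a.strand))
    for key, group_anns in ann_groups.items():
        group_units = unit_groups.get(key, [])
        group_anns.sort(key=lambda a: (a.start, a.end))
        starts = np.array([u.start for u in group_units], dtype=np.int64)
        ends = np.array([u.end for u in group_units], dtype=np.int64)
        for ann in group_anns:
            hit = np.flatnonzero((starts < ann.end) & (ends > ann.start))
            for i in hit:
                u = group_units[i]
                yield ann, u, overlap_bp(ann.start, ann.end, u.start, u.end)


def match_units(
    units: Sequence[TranscriptionUnit], annotations: Sequence[ConsensusAnnotation]
) -> MatchMap:
    """One-to-one annotation→unit map: maximal same-strand overlap wins.

    Ties go to the 5'-most unit (smallest start on '+', largest end on
    '-'); an overlap of at least 1 bp on the same strand is required.
    """
    best: dict[str, tuple[TranscriptionUnit, int]] = {}
    matched_units: set[tuple] = set()
    for ann, u, ov in _overlap_join(annotations, units):
        cur = best.get(ann.symbol)
        if cur is None or ov > cur[1] or (ov == cur[1] and _more_5prime(u, cur[0])):
            best[ann.symbol] = (u, ov)
    for u, _ in best.values():
        matched_units.add((u.chrom, u.start, u.end, u.strand))
    unmatched_annotations = [a.symbol for a in annotations if a.symbol not in best]
    unmatched_units = [
        u for u in units if (u.chrom, u.start, u.end, u.strand) not in matched_units
    ]
    return MatchMap(best, unmatched_annotations, unmatched_units)


def _more_5prime(a: TranscriptionUnit, b: TranscriptionUnit) -> bool:
    if a.strand == "+":
        return a.start < b.start
    return a.end > b.end


def _check_nonoverlapping(annotations: Sequence[ConsensusAnnotation]) -> None:
    for (chrom, strand), group in _grouped(
        annotations, lambda a: (a.chrom, a.strand)
    ).items():
        group.sort(key=lambda a: a.start)
        for prev, nxt in zip(group, group[1:]):
            if prev.end > nxt.start:
                raise ValueError(
                    f"annotations {prev.symbol} and {nxt.symbol} overlap on "
                    f"{chrom}{strand}; consensus input required"
                )


def annotation_errors(
    units: Sequence[TranscriptionUnit],
    expressed_annotations: Sequence[ConsensusAnnotation],
) -> ErrorReport:
    """Merged/dissociated error counts against expressed annotations.

    A unit overlapping exactly one annotation, and an annotation covered
    by exactly one unit, contribute to neither error. The rate divides the
    summed errors by the number of expressed annotations evaluated.
    """
    _check_nonoverlapping(expressed_annotations)
    per_unit: dict[tuple, int] = defaultdict(int)
    per_ann: dict[str, int] = defaultdict(int)
    for ann, u, _ in _overlap_join(expressed_annotations, units):
        per_unit[(u.chrom, u.start, u.end, u.strand)] += 1
        per_ann[ann.symbol] += 1
    n_merged = sum(1 for n in per_unit.values() if n >= 2)
    n_dissociated = sum(1 for n in per_ann.values() if n >= 2)
    n_eval = len(expressed_annotations)
    lengths = np.array([len(u) for u in units]) if units else np.array([0.0])
    return ErrorReport(
        n_merged=n_merged,
        n_dissociated=n_dissociated,
        n_eval=n_eval,
        rate=(n_merged + n_dissociated) / n_eval if n_eval else 0.0,
        n_units=len(units),
        median_unit_length=float(np.median(lengths)),
    )


def _flank(ann: ConsensusAnnotation, fraction: float, side: str) -> tuple[int, int]:
    """Upstream/downstream evaluation region, scaled to the gene length."""
    span = max(int(round(fraction * len(ann))), 1)
    upstream = side == "up"
    if (ann.strand == "+") == upstream:
        return max(ann.start - span, 0), ann.start
    return ann.end, ann.end + span


def tua(
    units: Sequence[TranscriptionUnit],
    expressed_annotations: Sequence[ConsensusAnnotation],
    upstream_fraction: float = 1.0,
) -> TuaResult:
    """Transcription unit accuracy of calls against expressed annotations.

    Per annotation, its best-matching unit's covered fraction of the gene
    body (TP̂ contribution) and of the upstream evaluation region of width
    ``upstream_fraction × gene length`` (5'FP̂ contribution) are averaged
    over annotations; the aggregate 5'FP̂ is capped at TP̂ so that the
    constraint 5'FP̂ + 5'TN̂ = TP̂ holds, and TUA follows in closed form.
    """
    if upstream_fraction <= 0:
        raise ValueError("upstream_fraction must be positive")
    if not expressed_annotations:
        raise ValueError("no annotations to evaluate")
    matches = match_units(units, expressed_annotations)
    tp_sum = fp5_sum = post_sum = 0.0
    for ann in expressed_annotations:
        hit = matches.pairs.get(ann.symbol)
        if hit is None:
            continue
        u, _ = hit
        tp_sum += overlap_bp(ann.start, ann.end, u.start, u.end) / len(ann)
        us, ue = _flank(ann, upstream_fraction, "up")
        if ue > us:
            fp5_sum += overlap_bp(us, ue, u.start, u.end) / (ue - us)
        ds, de = _flank(ann, upstream_fraction, "down")
        if de > ds:
            post_sum += overlap_bp(ds, de, u.start, u.end) / (de - ds)
    n = len(expressed_annotations)
    tp_hat = tp_sum / n
    fp5_hat = min(fp5_sum / n, tp_hat)
    tn5_hat = tp_hat - fp5_hat
    fn_hat = 1.0 - tp_hat
    denom = tp_hat + fn_hat + fp5_hat + tn5_hat
    tua_val = (tp_hat + tn5_hat) / denom if denom > 0 else 0.0
    return TuaResult(tp_hat, fp5_hat, tn5_hat, fn_hat, post_sum / n, tua_val)


def tua_closed_form(tp_hat: float, fp5_hat: float) -> float:
    """TUA from the aggregate areas under the 5' constraint:
    (2·TP̂ − 5'FP̂) / (1 + TP̂)."""
    fp5_hat = min(fp5_hat, tp_hat)
    return (2.0 * tp_hat - fp5_hat) / (1.0 + tp_hat) if tp_hat > 0 or fp5_hat > 0 else 0.0


def transcript_density(
    units: Sequence[TranscriptionUnit],
    annotations: Sequence[ConsensusAnnotation],
    n_bins: int = 30,
) -> np.ndarray:
    """Fraction of annotations whose matched unit covers each scaled bin.

    ``n_bins`` (a multiple of 3, >= 3) is split equally across the scaled
    upstream, gene-body and downstream regions, ordered 5'→3' in
    transcript orientation; a bin is covered when the matched unit spans
    its genomic midpoint.
    """
    if n_bins < 3 or n_bins % 3:
        raise ValueError("n_bins must be a positive multiple of 3")
    if not annotations:
        raise ValueError("no annotations")
    per_region = n_bins // 3
    matches = match_units(units, annotations)
    covered = np.zeros(n_bins)
    for ann in annotations:
        hit = matches.pairs.get(ann.symbol)
        if hit is None:
            continue
        u, _ = hit
        length = len(ann)
        # region starts in transcript orientation: upstream, body, downstream
        if ann.strand == "+":
            origins = [ann.start - length, ann.start, ann.end]
            step = length / per_region
        else:
            origins = [ann.end + length, ann.end, ann.start]
            step = -length / per_region
        for region, origin in enumerate(origins):
            for b in range(per_region):
                mid = origin + (b + 0.5) * step
                if u.start <= mid < u.end:
                    covered[region * per_region + b] += 1
    return covered / len(annotations)


def genome_coverage(
    units: Sequence[TranscriptionUnit],
    annotations: Sequence[ConsensusAnnotation],
    chrom_lengths: dict[str, int],
    window: int = 100,
) -> tuple[float, float]:
    """Fraction of genic and intergenic fixed windows covered by calls.

    Windows are classified per strand: a window is genic on a strand when
    it intersects any expressed annotation there, and covered when it
    intersects any called unit on that strand. Returns
    (genic fraction covered, intergenic fraction covered) pooled over all
    chromosome strands.
    """
    genic_total = genic_cov = inter_total = inter_cov = 0
    ann_groups = _grouped(annotations, lambda a: (a.chrom, a.strand))
    unit_groups = _grouped(units, lambda u: (u.chrom, u.strand))
    for chrom, length in chrom_lengths.items():
        n_win = -(-length // window)
        for strand in ("+", "-"):
            genic = np.zeros(n_win, dtype=bool)
            cov = np.zeros(n_win, dtype=bool)
            for a in ann_groups.get((chrom, strand), []):
                genic[a.start // window : -(-a.end // window)] = True
            for u in unit_groups.get((chrom, strand), []):
                cov[u.start // window : -(-u.end // window)] = True
            genic_total += int(genic.sum())
            genic_cov += int((genic & cov).sum())
            inter_total += int((~genic).sum())
            inter_cov += int((~genic & cov).sum())
    return (
        genic_cov / genic_total if genic_total else 0.0,
        inter_cov / inter_total if inter_total else 0.0,
    )
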