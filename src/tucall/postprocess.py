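"""Annotation-guided boundary repair of called transcription units.

Two complementary repairs: units that merge several genes are broken at
the midpoint between each adjacent annotation pair, and units that
fragment a single gene are combined into one unit spanning the
fragments. Applying break-then-combine to truth-equal calls is the
identity.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from .core import ConsensusAnnotation, TranscriptionUnit, overlap_bp
from .evaluation import _check_nonoverlapping, _grouped, _overlap_join


def break_on_annotations(
    units: Sequence[TranscriptionUnit],
    annotations: Sequence[ConsensusAnnotation],
    window_size: int = 50,
) -> list[TranscriptionUnit]:
    """Split every unit overlapping >= 2 same-strand annotations.

    Cut points are the midpoints of the gaps between adjacent overlapped
    annotations; fragments shorter than one window are dropped.
    """
    _check_nonoverlapping(annotations)
    overlapped: dict[tuple, list[ConsensusAnnotation]] = defaultdict(list)
    for ann, u, _ in _overlap_join(annotations, units):
        overlapped[(u.chrom, u.start, u.end, u.strand)].append(ann)
    out: list[TranscriptionUnit] = []
    for u in units:
        anns = overlapped.get((u.chrom, u.start, u.end, u.strand), [])
        if len(anns) < 2:
            out.append(u)
            continue
        anns = sorted(anns, key=lambda a: a.start)
        cuts = [
            (prev.end + nxt.start) // 2 for prev, nxt in zip(anns, anns[1:])
        ]
        bounds = [u.start] + [c for c in cuts if u.start < c < u.end] + [u.end]
        for s, e in zip(bounds, bounds[1:]):
            if e - s >= window_size:
                out.append(
                    TranscriptionUnit(u.chrom, s, e, u.strand, id=f"{u.chrom}:{s}-{e}:{u.strand}")
                )
    return out


def combine_on_annotations(
    units: Sequence[TranscriptionUnit],
    annotations: Sequence[ConsensusAnnotation],
    window_size: int = 50,
) -> list[TranscriptionUnit]:
    """Merge all units whose best match is the same annotation.

    Only units lying within the annotation's span (± one window) are
    merged, into one unit from min(start) to max(end); units matched to no
    annotation pass through untouched.
    """
    _check_nonoverlapping(annotations)
    # best annotation per unit, by overlap bp (ties: 5'-most annotation)
    best: dict[tuple, tuple[int, ConsensusAnnotation]] = {}
    for ann, u, ov in _overlap_join(annotations, units):
        key = (u.chrom, u.start, u.end, u.strand)
        cur = best.get(key)
        if cur is None or ov > cur[0]:
            best[key] = (ov, ann)
    merged_groups: dict[str, list[TranscriptionUnit]] = defaultdict(list)
    out: list[TranscriptionUnit] = []
    for u in units:
        key = (u.chrom, u.start, u.end, u.strand)
        hit = best.get(key)
        if hit is None:
            out.append(u)
            continue
        _, ann = hit
        if u.start >= ann.start - window_size and u.end <= ann.end + window_size:
            merged_groups[ann.symbol].append(u)
        else:
            out.append(u)
    for symbol, group in merged_groups.items():
        if len(group) == 1:
            out.append(group[0])
        else:
            s = min(u.start for u in group)
            e = max(u.end for u in group)
            chrom, strand = group[0].chrom, group[0].strand
            out.append(
                TranscriptionUnit(chrom, s, e, strand, id=f"{chrom}:{s}-{e}:{strand}")
            )
    out.sort(key=lambda u: (u.chrom, u.strand, u.start, u.end))
    return out


def polish(
    units: Sequence[TranscriptionUnit],
    annotations: Sequence[ConsensusAnnotation],
    window_size: int = 50,
    do_break: bool = True,
    do_combine: bool = True,
) -> list[TranscriptionUnit]:
    """Break merged units, then combine fragmented ones."""
    result = list(units)
    if do_break:
        result = break_on_annotations(result, annotations, window_size)
    if do_combine:
        result = combine_on_annotations(result, annotations, window_size)
    return result
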