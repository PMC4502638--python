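"""Functional classification of transcription units.

Each refined unit is assigned exactly one of ten classes by an ordered
rule cascade (first match wins): protein-coding, non-coding RNA, lncRNA,
enhancer, divergent, antisense, repeat, other genic (sense), other genic
(antisense), intergenic. Enhancer transcript pairs — short, bidirectional,
partially overlapping, far from annotated gene ends — are detected first
and their members short-circuit the cascade at the enhancer rule.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .annotations import ReadIndex
from .core import AlignedRead, TranscriptionUnit, overlap_bp


class Category(str, Enum):
    PROTEIN_CODING = "protein_coding"
    NONCODING_RNA = "noncoding_rna"
    LNCRNA = "lncrna"
    ENHANCER = "enhancer"
    DIVERGENT = "divergent"
    ANTISENSE = "antisense"
    REPEAT = "repeat"
    OTHER_GENIC_SENSE = "other_genic_sense"
    OTHER_GENIC_ANTISENSE = "other_genic_antisense"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class ClassifiedUnit:
    unit: TranscriptionUnit
    category: Category
    evidence_id: str = ""
    overlap_fraction: float = 0.0


@dataclass(frozen=True)
class EnhancerPair:
    """Short bidirectional overlapping intergenic transcript pair."""

    plus_unit: TranscriptionUnit
    minus_unit: TranscriptionUnit
    center: int
    cell_types_active: frozenset = frozenset()

    @property
    def chrom(self) -> str:
        return self.plus_unit.chrom

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(self.plus_unit.start, self.minus_unit.start),
            max(self.plus_unit.end, self.minus_unit.end),
        )


def _iv(obj) -> tuple[str, str | None, int, int, str]:
    """(chrom, strand, start, end, label) from annotation-like objects."""
    strand = getattr(obj, "strand", None)
    label = getattr(obj, "symbol", "") or getattr(obj, "id", "")
    return obj.chrom, strand, obj.start, obj.end, label


class _IntervalSet:
    """Per-(chrom[,strand]) interval lookup over small annotation sets."""

    def __init__(self, items: Iterable, stranded: bool = True) -> None:
        self.stranded = stranded
        self._by_key: dict = defaultdict(list)
        for obj in items:
            chrom, strand, start, end, label = _iv(obj)
            key = (chrom, strand) if stranded else chrom
            self._by_key[key].append((start, end, label, obj))
        for v in self._by_key.values():
            v.sort()

    def overlapping(self, chrom: str, start: int, end: int, strand: str | None = None):
        key = (chrom, strand) if self.stranded else chrom
        for s, e, label, obj in self._by_key.get(key, []):
            if s >= end:
                break
            if e > start:
                yield s, e, label, obj

    def max_fraction(self, u: TranscriptionUnit, strand: str) -> tuple[float, str]:
        """Largest per-interval overlap as a fraction of the unit length."""
        best, best_label = 0.0, ""
        for s, e, label, _ in self.overlapping(u.chrom, u.start, u.end, strand):
            frac = overlap_bp(u.start, u.end, s, e) / len(u)
            if frac > best:
                best, best_label = frac, label
        return best, best_label

    def union_fraction(self, u: TranscriptionUnit, strand: str | None = None) -> float:
        """Fraction of the unit covered by the union of the intervals."""
        segs = sorted(
            (max(s, u.start), min(e, u.end))
            for s, e, _, _ in self.overlapping(u.chrom, u.start, u.end, strand)
        )
        covered, cur_s, cur_e = 0, None, None
        for s, e in segs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        return covered / len(u)


def detect_enhancer_pairs(
    units: Sequence[TranscriptionUnit],
    annotations: Sequence,
    max_len: int = 10_000,
    min_distance: int = 10_000,
) -> list[EnhancerPair]:
    """Pair opposite-strand overlapping short units far from gene ends.

    Both members must be shorter than ``max_len`` and have their TSS more
    than ``min_distance`` bp from every annotated TSS and TTS. Pairing is
    greedy by overlap width (ties: leftmost); each unit joins at most one
    pair. The pair center is the midpoint of the overlap.
    """
    ends_by_chrom: dict[str, np.ndarray] = {}
    buckets: dict[str, list[int]] = defaultdict(list)
    for a in annotations:
        chrom, strand, start, end, _ = _iv(a)
        buckets[chrom].extend((start, end))
    ends_by_chrom = {c: np.sort(np.asarray(v)) for c, v in buckets.items()}

    def far_from_genes(u: TranscriptionUnit) -> bool:
        pts = ends_by_chrom.get(u.chrom)
        if pts is None or len(pts) == 0:
            return True
        i = np.searchsorted(pts, u.tss)
        for j in (i - 1, i):
            if 0 <= j < len(pts) and abs(int(pts[j]) - u.tss) <= min_distance:
                return False
        return True

    cands = [u for u in units if len(u) < max_len and far_from_genes(u)]
    plus = defaultdict(list)
    minus = defaultdict(list)
    for u in cands:
        (plus if u.strand == "+" else minus)[u.chrom].append(u)

    edges = []
    for chrom, pu_list in plus.items():
        for pu in pu_list:
            for mu in minus.get(chrom, []):
                ov = overlap_bp(pu.start, pu.end, mu.start, mu.end)
                if ov > 0:
                    edges.append((ov, min(pu.start, mu.start), pu, mu))
    edges.sort(key=lambda t: (-t[0], t[1]))
    used: set[tuple] = set()
    pairs: list[EnhancerPair] = []
    for ov, _, pu, mu in edges:
        kp = (pu.chrom, pu.start, pu.end, pu.strand)
        km = (mu.chrom, mu.start, mu.end, mu.strand)
        if kp in used or km in used:
            continue
        used.update((kp, km))
        center = (max(pu.start, mu.start) + min(pu.end, mu.end)) // 2
        pairs.append(EnhancerPair(pu, mu, center))
    pairs.sort(key=lambda p: (p.chrom, p.span))
    return pairs


def classify_units(
    units: Sequence[TranscriptionUnit],
    coding: Sequence = (),
    ncrna: Sequence = (),
    lncrna: Sequence = (),
    repeats: Sequence = (),
    enhancer_pairs: Sequence[EnhancerPair] | None = None,
    enhancer_max_len: int = 10_000,
    enhancer_min_distance: int = 10_000,
) -> list[ClassifiedUnit]:
    """Assign each unit to exactly one functional class.

    Rules, applied in order with first match winning:

    1. protein-coding: > 20 % of the unit overlaps a coding gene (sense);
    2. non-coding RNA: any overlap with an annotated small ncRNA;
    3. lncRNA: > 20 % of the unit overlaps a lncRNA gene (sense);
    4. enhancer: member of a detected bidirectional pair;
    5. divergent: > 10 % of the unit overlaps the ±500 bp promoter of an
       opposite-strand primary transcript > 1 kb, and the unit is < 50 %
       of the primary's size;
    6. antisense: > 20 % of the unit overlaps, and that overlap covers
       > 20 % of, an opposite-strand coding or lncRNA gene;
    7. repeat: > 50 % of the unit lies in repeat-masked regions;
    8-9. other genic sense/antisense: residual overlap of any gene
       annotation with < 20 % matching;
    10. intergenic: none of the above.
    """
    coding_set = _IntervalSet(coding)
    ncrna_set = _IntervalSet(ncrna, stranded=False)
    lncrna_set = _IntervalSet(lncrna)
    repeat_set = _IntervalSet(repeats, stranded=False)
    primary = list(coding) + list(lncrna)
    primary_set = _IntervalSet(primary)
    genic_set = _IntervalSet(list(coding) + list(lncrna) + list(ncrna))
    if enhancer_pairs is None:
        enhancer_pairs = detect_enhancer_pairs(
            units, primary, enhancer_max_len, enhancer_min_distance
        )
    enhancer_members = set()
    for p in enhancer_pairs:
        for u in (p.plus_unit, p.minus_unit):
            enhancer_members.add((u.chrom, u.start, u.end, u.strand))

    out: list[ClassifiedUnit] = []
    for u in units:
        other = "-" if u.strand == "+" else "+"
        frac, label = coding_set.max_fraction(u, u.strand)
        if frac > 0.20:
            out.append(ClassifiedUnit(u, Category.PROTEIN_CODING, label, frac))
            continue
        nc = next(iter(ncrna_set.overlapping(u.chrom, u.start, u.end)), None)
        if nc is not None:
            ov = overlap_bp(u.start, u.end, nc[0], nc[1]) / len(u)
            out.append(ClassifiedUnit(u, Category.NONCODING_RNA, nc[2], ov))
            continue
        frac, label = lncrna_set.max_fraction(u, u.strand)
        if frac > 0.20:
            out.append(ClassifiedUnit(u, Category.LNCRNA, label, frac))
            continue
        if (u.chrom, u.start, u.end, u.strand) in enhancer_members:
            out.append(ClassifiedUnit(u, Category.ENHANCER))
            continue
        div = _divergent_evidence(u, primary_set, other)
        if div is not None:
            out.append(ClassifiedUnit(u, Category.DIVERGENT, div[0], div[1]))
            continue
        anti = _antisense_evidence(u, coding_set, lncrna_set, other)
        if anti is not None:
            out.append(ClassifiedUnit(u, Category.ANTISENSE, anti[0], anti[1]))
            continue
        rep_frac = repeat_set.union_fraction(u)
        if rep_frac > 0.50:
            out.append(ClassifiedUnit(u, Category.REPEAT, "", rep_frac))
            continue
        sense_frac, sense_label = genic_set.max_fraction(u, u.strand)
        if sense_frac > 0:
            out.append(
                ClassifiedUnit(u, Category.OTHER_GENIC_SENSE, sense_label, sense_frac)
            )
            continue
        anti_frac, anti_label = genic_set.max_fraction(u, other)
        if anti_frac > 0:
            out.append(
                ClassifiedUnit(u, Category.OTHER_GENIC_ANTISENSE, anti_label, anti_frac)
            )
            continue
        out.append(ClassifiedUnit(u, Category.INTERGENIC))
    return out


def _divergent_evidence(u, primary_set: _IntervalSet, other: str):
    for s, e, label, obj in primary_set.overlapping(
        u.chrom, u.start - 500, u.end + 500, other
    ):
        if e - s <= 1000 or len(u) >= 0.5 * (e - s):
            continue
        strand = getattr(obj, "strand", other)
        tss = s if strand == "+" else e
        frac = overlap_bp(u.start, u.end, tss - 500, tss + 500) / len(u)
        if frac > 0.10:
            return label, frac
    return None


def _antisense_evidence(u, coding_set, lncrna_set, other: str):
    for iset in (coding_set, lncrna_set):
        for s, e, label, _ in iset.overlapping(u.chrom, u.start, u.end, other):
            ov = overlap_bp(u.start, u.end, s, e)
            if ov / len(u) > 0.20 and ov / (e - s) > 0.20:
                return label, ov / len(u)
    return None


@dataclass(frozen=True)
class PairSpecificity:
    cell_type: str
    pair: EnhancerPair
    specific: bool
    cell_types_active: frozenset


def cell_type_specificity(
    pairs_by_cell: Mapping[str, Sequence[EnhancerPair]],
    min_overlap_fraction: float = 0.20,
) -> list[PairSpecificity]:
    """Label enhancer pairs as cell-type-specific or shared.

    A pair is shared when some pair from another cell type overlaps its
    merged span by at least ``min_overlap_fraction`` of the query pair's
    length; specific otherwise. The active cell set of each pair is the
    union of cells over its connected component of the sharing graph.
    """
    if len(pairs_by_cell) < 2:
        raise ValueError("at least two cell types are required")
    nodes = [
        (cell, i, p)
        for cell, pairs in pairs_by_cell.items()
        for i, p in enumerate(pairs)
    ]
    g = nx.Graph()
    g.add_nodes_from((cell, i) for cell, i, _ in nodes)
    shared: set[tuple] = set()
    for cell_a, i, p in nodes:
        ps, pe = p.span
        for cell_b, j, q in nodes:
            if cell_b == cell_a or q.chrom != p.chrom:
                continue
            ov = overlap_bp(ps, pe, *q.span)
            if ov >= min_overlap_fraction * (pe - ps):
                shared.add((cell_a, i))
                g.add_edge((cell_a, i), (cell_b, j))
    comp_cells: dict[tuple, frozenset] = {}
    for comp in nx.connected_components(g):
        cells = frozenset(cell for cell, _ in comp)
        for node in comp:
            comp_cells[node] = cells
    return [
        PairSpecificity(cell, p, (cell, i) not in shared, comp_cells[(cell, i)])
        for cell, i, p in nodes
    ]


@dataclass
class MetageneResult:
    """Strand-specific average profile around aligned genomic anchors."""

    offsets: np.ndarray  # bin start offsets relative to the center
    profiles: dict  # strand -> mean counts per bin
    matrices: dict  # strand -> (n_centers, n_bins) per-center counts
    centers_used: list


def metagene(
    reads: Iterable[AlignedRead] | ReadIndex,
    centers: Sequence[tuple[str, int]],
    half_window: int = 4000,
    bin_size: int = 100,
    chrom_lengths: Mapping[str, int] | None = None,
) -> MetageneResult:
    """Average read 5'-end profile in bins around a set of centers.

    Counts fall in ``[center - half_window, center + half_window)``;
    ``half_window`` must be a multiple of ``bin_size``. Centers too close
    to a chromosome edge are skipped with a warning.
    """
    if not centers:
        raise ValueError("no centers provided")
    if half_window % bin_size:
        raise ValueError("half_window must be a multiple of bin_size")
    index = reads if isinstance(reads, ReadIndex) else ReadIndex(reads)
    n_bins = 2 * half_window // bin_size
    kept: list[tuple[str, int]] = []
    for chrom, pos in centers:
        limit = chrom_lengths.get(chrom) if chrom_lengths else None
        if pos - half_window < 0 or (limit is not None and pos + half_window > limit):
            warnings.warn(f"center {chrom}:{pos} too close to chromosome edge; skipped")
            continue
        kept.append((chrom, pos))
    mats = {s: np.zeros((len(kept), n_bins)) for s in ("+", "-")}
    for row, (chrom, pos) in enumerate(kept):
        bounds = pos - half_window + bin_size * np.arange(n_bins + 1, dtype=np.int64)
        for strand in ("+", "-"):
            mats[strand][row] = index.segment_counts(chrom, strand, bounds)
    profiles = {
        s: (m.mean(axis=0) if len(kept) else np.zeros(n_bins)) for s, m in mats.items()
    }
    offsets = -half_window + bin_size * np.arange(n_bins)
    return MetageneResult(offsets, profiles, mats, kept)
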