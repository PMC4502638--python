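"""Shared domain records for stranded genomic intervals and windowed counts.

All coordinates are 0-based half-open (BED convention) throughout the
package; 1-based annotation formats (GTF) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-")


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely mapped, strand-specific read.

    The 5' end of the read marks the engaged-polymerase position: ``start``
    for plus-strand reads, ``end - 1`` for minus-strand reads.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid read interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class WindowedCounts:
    """Read counts in fixed-width windows on one chromosome strand.

    Window ``i`` covers ``[i * window_size, (i + 1) * window_size)``; the
    vector length is ``ceil(chrom_length / window_size)``.
    """

    chrom: str
    strand: str
    window_size: int
    counts: np.ndarray
    chrom_length: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError("window counts must be non-negative")
        if self.chrom_length == 0:
            self.chrom_length = len(self.counts) * self.window_size

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class TranscriptionUnit:
    """A stranded genomic interval called as one primary transcription unit."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid unit interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """5'-most coordinate (transcription start side)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """3'-most coordinate (termination side)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class GeneModel:
    """One isoform of a gene as drawn from an annotation source."""

    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene interval for {self.symbol}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ConsensusAnnotation:
    """A non-overlapping per-symbol gene interval with explicit TSS/TTS."""

    symbol: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid consensus interval for {self.symbol}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Width of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))
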