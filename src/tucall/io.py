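"""Readers and writers for BED/GTF inputs, plus strand-specific binning.

BED6 is the mandatory read format (strand column required — nascent
run-on data is meaningless without orientation). GTF (1-based inclusive)
is converted to 0-based half-open on read. Binned counts round-trip
through a versioned ``.npz`` archive (see :func:`save_counts`).
"""

from __future__ import annotations

import json
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import AlignedRead, GeneModel, TranscriptionUnit, WindowedCounts

COUNTS_FORMAT_VERSION = 1


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path) -> list[AlignedRead]:
    """Read aligned reads from a BED6 file (tab-delimited, no header).

    Every line must carry six fields with a '+'/'-' strand; a '.' strand is
    rejected because downstream binning is strand-specific.
    """
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 6 BED fields, got {len(fields)}"
                )
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if strand not in ("+", "-"):
                raise BedParseError(
                    f"{path}:{lineno}: strand must be '+' or '-' (got {strand!r}); "
                    "strand-specific reads are required"
                )
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end")
            reads.append(AlignedRead(chrom, start, end, strand))
    return reads


def read_bam(path: str | Path) -> list[AlignedRead]:
    """Optional convenience reader: mapped primary alignments from a BAM/SAM.

    Mapping-quality and mismatch filtering are the aligner's job; every
    mapped, non-secondary, non-supplementary record is returned.
    """
    import pysam

    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path)) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            strand = "-" if rec.is_reverse else "+"
            reads.append(
                AlignedRead(rec.reference_name, rec.reference_start, rec.reference_end, strand)
            )
    return reads


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def bin_reads(
    reads: Iterable[AlignedRead],
    window_size: int,
    chrom_lengths: dict[str, int],
) -> dict[tuple[str, str], WindowedCounts]:
    """Bin reads into strand-specific fixed-width windows by 5' position.

    Each read increments exactly one window — the one containing its 5'-most
    base (``start`` on '+', ``end - 1`` on '-'); spanning reads are never
    split. Returns one :class:`WindowedCounts` per (chrom, strand), including
    empty vectors for strands with no reads.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    out: dict[tuple[str, str], WindowedCounts] = {}
    for chrom, length in chrom_lengths.items():
        n_windows = -(-length // window_size)
        for strand in ("+", "-"):
            out[(chrom, strand)] = WindowedCounts(
                chrom, strand, window_size, np.zeros(n_windows, dtype=np.int64), length
            )
    for read in reads:
        if read.chrom not in chrom_lengths:
            raise KeyError(f"read chromosome {read.chrom!r} not in chrom_lengths")
        pos = read.five_prime
        if pos >= chrom_lengths[read.chrom]:
            raise ValueError(
                f"read [{read.start},{read.end}) on {read.chrom}{read.strand} "
                f"past chromosome end ({chrom_lengths[read.chrom]})"
            )
        out[(read.chrom, read.strand)].counts[pos // window_size] += 1
    return out


def write_transcripts_bed(units: Sequence[TranscriptionUnit], path: str | Path) -> None:
    """Write transcription units as BED6, sorted by (chrom, start); score 0."""
    rows = sorted(units, key=lambda u: (u.chrom, u.start, u.end, u.strand))
    with open(path, "w") as fh:
        for i, u in enumerate(rows):
            name = u.id or f"TU{i + 1:06d}"
            fh.write(f"{u.chrom}\t{u.start}\t{u.end}\t{name}\t0\t{u.strand}\n")


def read_transcripts_bed(path: str | Path) -> list[TranscriptionUnit]:
    """Read transcription units back from BED6."""
    units = []
    for r in read_bed(path):
        units.append(TranscriptionUnit(r.chrom, r.start, r.end, r.strand))
    # recover names: read_bed drops them, reparse cheaply
    names = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("track", "browser", "#")):
                names.append(line.split("\t")[3])
    return [
        TranscriptionUnit(u.chrom, u.start, u.end, u.strand, id=n)
        for u, n in zip(units, names)
    ]


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_genes(
    path: str | Path,
    symbol_attribute: str = "gene_name",
    feature: str = "transcript",
    source_tag: str = "",
) -> list[GeneModel]:
    """Read gene/transcript intervals from GTF/GFF (1-based inclusive -> BED).

    One :class:`GeneModel` per row whose feature column matches ``feature``
    (falling back to ``gene`` rows if no such features exist), keyed on a
    configurable attribute for the symbol.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"],
        dtype={"chrom": str},
    )
    rows = df[df["feature"] == feature]
    if rows.empty:
        rows = df[df["feature"] == "gene"]
    models = []
    for rec in rows.itertuples(index=False):
        attrs = dict(_GTF_ATTR.findall(rec.attrs))
        if symbol_attribute not in attrs:
            # GFF3 style key=value fallback
            attrs.update(
                kv.split("=", 1) for kv in rec.attrs.split(";") if "=" in kv
            )
        symbol = attrs.get(symbol_attribute) or attrs.get("gene_id") or attrs.get("ID")
        if symbol is None or rec.strand not in ("+", "-"):
            continue
        models.append(
            GeneModel(symbol, rec.chrom, rec.strand, int(rec.start) - 1, int(rec.end),
                      source=source_tag or str(rec.source))
        )
    return models


def read_bed_genes(path: str | Path, source_tag: str = "") -> list[GeneModel]:
    """Read gene intervals from BED6 or BED12 (name column is the symbol)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise BedParseError(f"{path}:{lineno}: expected >= 6 fields")
            if f[5] not in ("+", "-"):
                raise BedParseError(f"{path}:{lineno}: invalid strand {f[5]!r}")
            models.append(
                GeneModel(f[3], f[0], f[5], int(f[1]), int(f[2]), source=source_tag)
            )
    return models


def save_counts(counts: dict[tuple[str, str], WindowedCounts], path: str | Path) -> None:
    """Persist binned counts as a versioned ``.npz`` archive.

    Layout (format version 1): one integer array per (chrom, strand) under the
    key ``"{chrom}|{strand}"``, plus a JSON metadata entry ``__meta__`` with
    the format version, window size and chromosome lengths.
    """
    arrays: dict[str, np.ndarray] = {}
    meta = {"format_version": COUNTS_FORMAT_VERSION, "window_size": None, "chrom_lengths": {}}
    for (chrom, strand), wc in counts.items():
        arrays[f"{chrom}|{strand}"] = np.asarray(wc.counts, dtype=np.int64)
        meta["window_size"] = wc.window_size
        meta["chrom_lengths"][chrom] = wc.chrom_length
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_counts(path: str | Path) -> dict[tuple[str, str], WindowedCounts]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta["format_version"] != COUNTS_FORMAT_VERSION:
            raise ValueError(f"unsupported counts archive version {meta['format_version']}")
        out = {}
        for key in npz.files:
            if key == "__meta__":
                continue
            chrom, strand = key.rsplit("|", 1)
            out[(chrom, strand)] = WindowedCounts(
                chrom, strand, meta["window_size"], npz[key],
                meta["chrom_lengths"][chrom],
            )
    return out


def units_by_strand(
    units: Iterable[TranscriptionUnit],
) -> dict[tuple[str, str], list[TranscriptionUnit]]:
    """Group units by (chrom, strand), each group sorted by start."""
    groups: dict[tuple[str, str], list[TranscriptionUnit]] = defaultdict(list)
    for u in units:
        groups[(u.chrom, u.strand)].append(u)
    for g in groups.values():
        g.sort(key=lambda u: (u.start, u.end))
    return dict(groups)
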