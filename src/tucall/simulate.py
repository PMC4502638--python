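"""Ground-truth genome and read simulator for offline testing.

A planted gene layout (non-overlapping per strand, log-normal lengths,
organism-density presets) is transcribed with the same emission regime
the HMM assumes: each 50-bp window inside a transcribed unit draws a rate
from Γ(k_T, θ_T) and a Poisson read count at that rate (a gamma-Poisson
mixture — read counts are integers, and the gamma-mixed mean matches the
model fitted after pseudocounting), while background windows draw a small
Poisson count. Enhancers are planted as short overlapping divergent pairs
placed far from genes by construction.

All randomness flows from the single spec seed, split per stage with
``np.random.default_rng([seed, stage])`` (stage 1 = genome layout,
stage 2 = reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .classify import EnhancerPair
from .core import AlignedRead, GeneModel, TranscriptionUnit

#: Average gene densities (genes/Mb) of the organisms emulated.
PRESETS = {
    "human": {"gene_density": 11.0, "gene_length_median": 23_000.0},
    "fly": {"gene_density": 76.0, "gene_length_median": 3_000.0},
    "worm": {"gene_density": 200.0, "gene_length_median": 1_500.0},
}


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one simulated study condition.

    Defaults describe a deeply sequenced mammalian-like setting: 11
    genes/Mb with a 23-kb median length, transcribed windows emitting a
    gamma-Poisson count with mean ``scale * k_t * theta_t = 10`` reads per
    50-bp window, and a sparse Poisson background.
    """

    chrom_lengths: dict = field(default_factory=lambda: {"chrSim": 10_000_000})
    gene_density: float = 11.0  # genes per Mb
    gene_length_median: float = 23_000.0
    gene_length_sigma: float = 0.6  # log-scale sd of the log-normal
    min_gene_length: int = 500
    min_gene_gap: int = 1_000  # same-strand spacing floor (bp)
    n_enhancers: int = 10
    enhancer_length_median: float = 1_500.0
    enhancer_length_sigma: float = 0.4
    enhancer_margin: int = 25_000  # clearance from genes and other pairs (bp)
    k_t: float = 2.0
    theta_t: float = 5.0
    scale: float = 1.0  # reads per transcribed window = scale * k_t * theta_t
    background_rate: float = 0.05  # reads per background window
    window_size: int = 50
    read_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_density <= 0:
            raise ValueError("gene density must be positive")
        if self.k_t <= 0 or self.theta_t <= 0:
            raise ValueError("emission parameters must be positive")

    @classmethod
    def preset(cls, name: str, **overrides) -> "GenomeSpec":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(**{**PRESETS[name], **overrides})


@dataclass
class SimulatedGenome:
    spec: GenomeSpec
    genes: list  # GeneModel truth annotations
    truth_units: list  # TranscriptionUnit: genes + enhancer transcripts
    enhancer_pairs: list  # EnhancerPair


def simulate_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Plant genes and enhancer pairs; reproducible from the spec seed.

    Gene counts are Poisson(density × Mb) per chromosome; placement is
    rejection sampling against same-strand overlap (with a spacing
    floor). Raises when the requested density cannot be placed.
    """
    rng = np.random.default_rng([spec.seed, 1])
    mu = math.log(spec.gene_length_median)
    genes: list[GeneModel] = []
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, length in sorted(spec.chrom_lengths.items()):
        n_genes = rng.poisson(spec.gene_density * length / 1e6)
        occupied[(chrom, "+")] = []
        occupied[(chrom, "-")] = []
        for gi in range(n_genes):
            placed = False
            for _ in range(500):
                glen = int(rng.lognormal(mu, spec.gene_length_sigma))
                glen = max(min(glen, length // 4), spec.min_gene_length)
                strand = "+" if rng.random() < 0.5 else "-"
                start = int(rng.integers(0, max(length - glen, 1)))
                end = start + glen
                lo, hi = start - spec.min_gene_gap, end + spec.min_gene_gap
                if any(s < hi and e > lo for s, e in occupied[(chrom, strand)]):
                    continue
                occupied[(chrom, strand)].append((start, end))
                genes.append(
                    GeneModel(f"G{len(genes) + 1:05d}", chrom, strand, start, end, "sim")
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place gene {gi + 1}/{n_genes} on {chrom}; "
                    "lower the gene density or shorten genes"
                )

    pairs = _plant_enhancers(spec, rng, genes)
    truth_units = [
        TranscriptionUnit(g.chrom, g.start, g.end, g.strand, id=g.symbol) for g in genes
    ]
    for i, p in enumerate(pairs):
        truth_units.extend([p.plus_unit, p.minus_unit])
    return SimulatedGenome(spec, genes, truth_units, pairs)


def _plant_enhancers(spec: GenomeSpec, rng, genes) -> list[EnhancerPair]:
    """Short divergent overlapping pairs, > margin bp from any gene end."""
    pts: dict[str, np.ndarray] = {}
    for chrom in spec.chrom_lengths:
        vals = [g.start for g in genes if g.chrom == chrom]
        vals += [g.end for g in genes if g.chrom == chrom]
        pts[chrom] = np.sort(np.asarray(vals, dtype=np.int64))
    mu = math.log(spec.enhancer_length_median)
    chroms = sorted(spec.chrom_lengths)
    pairs: list[EnhancerPair] = []
    taken: list[tuple[str, int, int]] = []
    for _ in range(spec.n_enhancers):
        for _ in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = spec.chrom_lengths[chrom]
            center = int(rng.integers(spec.enhancer_margin, max(length - spec.enhancer_margin, spec.enhancer_margin + 1)))
            p = pts[chrom]
            i = np.searchsorted(p, center)
            near = min(
                (abs(int(p[j]) - center) for j in (i - 1, i) if 0 <= j < len(p)),
                default=spec.enhancer_margin + 1,
            )
            if near <= spec.enhancer_margin:
                continue
            if any(
                c == chrom and abs(center - cc) <= spec.enhancer_margin
                for c, cc, _ in taken
            ):
                continue
            lp = int(np.clip(rng.lognormal(mu, spec.enhancer_length_sigma), 500, 9_000))
            lm = int(np.clip(rng.lognormal(mu, spec.enhancer_length_sigma), 500, 9_000))
            ov = min(1_000, lp // 2, lm // 2)
            plus = TranscriptionUnit(
                chrom, center - ov // 2, center - ov // 2 + lp, "+",
                id=f"E{len(pairs) + 1:03d}+",
            )
            minus = TranscriptionUnit(
                chrom, center + ov - ov // 2 - lm, center + ov - ov // 2, "-",
                id=f"E{len(pairs) + 1:03d}-",
            )
            pairs.append(EnhancerPair(plus, minus, center))
            taken.append((chrom, center, ov))
            break
        else:
            raise RuntimeError(
                "could not place an enhancer pair away from genes; "
                "lower the gene density or n_enhancers"
            )
    pairs.sort(key=lambda p: (p.chrom, p.span))
    return pairs


def simulate_reads(truth: SimulatedGenome, spec: GenomeSpec | None = None) -> list[AlignedRead]:
    """Strand-specific reads from the planted layout (gamma-Poisson).

    Windows fully inside a truth unit emit Poisson(scale × Γ(k_T, θ_T))
    reads; all other windows emit Poisson(background_rate). Read 5' ends
    are uniform within their window and carry the unit's strand
    (background reads draw a uniform strand).
    """
    spec = spec or truth.spec
    rng = np.random.default_rng([spec.seed, 2])
    w = spec.window_size
    reads: list[AlignedRead] = []
    for chrom, length in sorted(spec.chrom_lengths.items()):
        n_win = length // w
        for strand in ("+", "-"):
            transcribed = np.zeros(n_win, dtype=bool)
            for u in truth.truth_units:
                if u.chrom != chrom or u.strand != strand:
                    continue
                w0, w1 = -(-u.start // w), u.end // w
                transcribed[w0:w1] = True
            counts = rng.poisson(spec.background_rate, size=n_win)
            n_t = int(transcribed.sum())
            if n_t and spec.scale > 0:
                rates = rng.gamma(spec.k_t, spec.theta_t, size=n_t)
                counts[transcribed] = rng.poisson(rates * spec.scale)
            elif n_t:
                counts[transcribed] = 0
            windows = np.repeat(np.arange(n_win), counts)
            if len(windows) == 0:
                continue
            pos = windows * w + rng.integers(0, w, size=len(windows))
            pos = np.minimum(pos, length - 1)
            rl = spec.read_length
            for p in pos:
                p = int(p)
                if strand == "+":
                    reads.append(AlignedRead(chrom, p, min(p + rl, length), "+"))
                else:
                    reads.append(AlignedRead(chrom, max(p - rl + 1, 0), p + 1, "-"))
    return reads


def expected_read_count(truth: SimulatedGenome, spec: GenomeSpec | None = None) -> tuple[float, float]:
    """(mean, sd) of the total simulated read count (Poisson moments)."""
    spec = spec or truth.spec
    w = spec.window_size
    n_trans = 0
    for u in truth.truth_units:
        n_trans += max(u.end // w - (-(-u.start // w)), 0)
    n_total = 2 * sum(length // w for length in spec.chrom_lengths.values())
    n_bg = n_total - n_trans
    mean_t = spec.scale * spec.k_t * spec.theta_t
    mean = n_trans * mean_t + n_bg * spec.background_rate
    # Poisson mixed over a gamma rate: var = m + m^2/k per window
    var = n_trans * (mean_t + (spec.scale * spec.theta_t) ** 2 * spec.k_t) \
        + n_bg * spec.background_rate
    return mean, math.sqrt(var)


def write_simulation(truth: SimulatedGenome, reads, outdir: str | Path) -> dict[str, Path]:
    """Emit reads.bed, truth.gtf, truth_units.bed and enhancers.bed."""
    from .io import write_transcripts_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.bed",
        "truth_gtf": outdir / "truth.gtf",
        "truth_units": outdir / "truth_units.bed",
        "enhancers": outdir / "enhancers.bed",
        "chrom_sizes": outdir / "chrom.sizes",
    }
    with open(paths["reads"], "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i + 1}\t0\t{r.strand}\n")
    with open(paths["truth_gtf"], "w") as fh:
        for g in truth.genes:
            attrs = f'gene_id "{g.symbol}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tsim\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    write_transcripts_bed(truth.truth_units, paths["truth_units"])
    enh_units = []
    for p in truth.enhancer_pairs:
        enh_units.extend([p.plus_unit, p.minus_unit])
    write_transcripts_bed(enh_units, paths["enhancers"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, length in sorted(truth.spec.chrom_lengths.items()):
            fh.write(f"{chrom}\t{length}\n")
    return paths
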