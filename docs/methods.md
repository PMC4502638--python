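# Methods

## Model

`tucall` segments strand-specific windowed read counts with a two-state
(transcribed / non-transcribed) hidden Markov model. The observation for
window t is x_t = c_t + p, where c_t is the number of read 5′ ends in the
window and p ≥ 0 is a pseudocount (default 1) that keeps the continuous
gamma emission densities defined at zero-count windows.

- Non-transcribed emission: Γ(shape = σ², scale = 1/σ²). The shape/scale
  pairing pins the mean at exactly 1, the background level after a unit
  pseudocount in sparse run-on data; σ² then only controls spread. The
  tool's "UTS" tuning parameter is this **shape**: the distribution is
  implemented exactly as the formula Γ(σ², 1/σ²) even though the shape of
  a gamma is not literally its variance — the formula, not the label, is
  the operational definition.
- Transcribed emission: Γ(k_T, θ_T), unconstrained.
- Transitions: P(T→N) = e^(−v) with v > 0 (the "−LtProbB" tuning
  parameter, natural-log scale — the log base is a modelling choice here,
  natural log, and v ∈ [50, 500] for mammalian data). P(N→T) = N;
  self-transitions are complements. Exiting the transcribed state costs v
  nats, so a gap splits a unit only when the accumulated background
  emission advantage across the gap exceeds v: v is a length penalty with
  direct control over fragmentation versus merging.
- Initial distribution: every chromosome strand starts non-transcribed
  with probability 1 (chromosome ends lie outside genes).
- Scan orientation: each strand is processed 5′→3′ — minus-strand window
  vectors are reversed before decoding and the state path mapped back —
  because the asymmetric transition structure encodes 3′-end behaviour.

All recursions (forward, backward, Viterbi, E-step statistics) run in log
space with two-state log-sum-exp, so v = 350 (P(T→N) ≈ 10^(−152)) and
genome-length products are exact in double precision.

## Training

k_T, θ_T and N are estimated by constrained Baum-Welch EM; σ², v and the
pseudocount are never touched by training. The M-step for the transcribed
gamma maximises the posterior-weighted likelihood exactly: Newton
iteration on log k − ψ(k) = log(weighted mean) − weighted mean of log x,
started from the standard closed-form approximation. The exact MLE (rather
than posterior-weighted moment matching) is used deliberately: it is a true
M-step, so the EM log-likelihood is guaranteed non-decreasing — a property
the test suite asserts on every run. N is the standard expected-transition
ratio. Convergence: stop when the likelihood gain drops below `tol`
(default 1e-4) or after `max_iter` iterations.

Initialisation: k_T, θ_T from the moments of emission values above their
75th percentile (a crude proxy for transcribed windows); N = 1e-3, the
scale of one gene-sized run per thousand background windows. EM on this
problem is insensitive to initialisation at realistic depths; any start
satisfying the monotonicity and recovery properties is equivalent.

Degenerate inputs: if the weighted spread of transcribed emissions is zero
(constant data) the gamma shape is capped at 1e6 with a warning; zero
posterior mass on a state leaves its parameters unchanged with a warning;
non-finite E-step statistics raise with the iteration number.

## Decoding and numerical conventions

Viterbi decoding with ties broken toward the non-transcribed state —
deterministic and conservative (never lengthens a call on a tie). Maximal
transcribed runs become transcription units with boundaries at run edges ×
window size, clipped to the chromosome length. Log-densities and
log-probabilities are floored at −1e12 to keep −∞ out of arithmetic.

Reads are assigned to windows by their 5′-most base (start on ‘+’, end−1
on ‘−’): run-on reads mark the polymerase position, and no spanning rule
is imposed. Coordinates are 0-based half-open everywhere; GTF input is
converted on read. Mappability masking is not applied.

## Tuning-parameter selection

`grid_search` trains and scores one model per (v, σ²) pair (default 10×10
over v ∈ [50, 500], σ² ∈ [5, 50]; a gene-dense preset extends v to 2000,
since dense genomes need stronger penalties to keep neighbouring genes
apart). `select_optimal` then (1) keeps models whose median unit length
lies within the IQR of medians across the grid, (2) keeps models calling
strictly between 1.25× and 1.5× the consensus-annotation count, and
(3) returns the minimum-error-rate survivor, breaking ties toward smaller
v then smaller σ². On small genomes a filter can empty the pool; it is
then skipped with a warning rather than failing — the published procedure
does not cover this case.

## Evaluation metrics

- **Matching**: each annotation maps to its best-overlap (bp) same-strand
  unit; ties go to the 5′-most unit. A unit may serve several annotations.
- **Merged annotation error**: a called unit overlapping ≥ 2 expressed
  annotations (counted per offending unit). **Dissociated annotation
  error**: an expressed annotation overlapped by ≥ 2 units (counted per
  offending annotation). **Rate** = (merged + dissociated) / number of
  expressed annotations evaluated. The published optimum table's rate
  column is not exactly reconstructible from its printed counts under any
  stated denominator, so the denominator here is defined explicitly (and
  is what the tests assert against).
- **TUA**: per matched annotation, the covered fraction of the gene body
  (TP̂ contribution) and of the upstream evaluation region (5′FP̂
  contribution); aggregates are means over all evaluated annotations, the
  aggregate 5′FP̂ is capped at TP̂ (the constraint 5′FP̂ + 5′TN̂ = TP̂ is
  imposed on the aggregate areas, not per gene), and
  TUA = (2·TP̂ − 5′FP̂)/(1 + TP̂). The upstream/downstream evaluation
  regions default to the gene's own scaled length (`upstream_fraction =
  1.0`) — equal scaled widths for the three panels; the physical span is
  configurable since no canonical value exists. PostTTŜ is computed
  identically downstream and reported but never enters TUA.
- **EDR**: segment boundaries at floor(k·L/n), which spreads remainder bp
  by at most 1 bp and makes segments at n′ | n exact unions of segments at
  n — so EDR monotonicity over divisor ladders holds exactly.
- **Transcript density**: fraction of annotations whose matched unit spans
  each scaled bin's genomic midpoint, over upstream/body/downstream in
  transcript orientation. **Genome coverage**: 100-bp windows classified
  genic/intergenic per strand by expressed-annotation overlap; covered
  when any same-strand unit intersects.

## Consensus annotations

Per gene symbol with ≥ 2 isoforms, the consensus interval is the longest
merged fragment of the region at isoform-stack depth ≥ 2 ("the interval
shared by two or more isoforms", made precise); symbols with disjoint
isoforms fall back to the longest isoform, single-isoform symbols pass
through. Cross-symbol overlaps on a strand are resolved in transcription
order: the upstream-TSS gene's 3′ end is trimmed to the downstream gene's
TSS, so every TSS survives verbatim; a gene emptied by trimming (shared
TSS) is dropped with a warning. Symbols with conflicting strands or
chromosomes are dropped with a warning.

## Boundary repair

Two annotation-guided heuristics (the published pipeline names the
procedure but not its rules; these are this package's own, symmetric and
deterministic choices):

- **break**: a unit overlapping ≥ 2 same-strand annotations is cut at the
  midpoint of each inter-annotation gap; fragments shorter than one window
  are dropped.
- **combine**: all units best-matched to the same annotation and lying
  within its span ± one window (call quantisation slack) are replaced by
  one unit spanning their extremes.

Break-then-combine is the identity on truth-equal calls, keeps per-strand
disjointness, and changes covered bp only by dropped sub-window scraps or
within-gene gap filling.

## Functional classification

Ten classes, first match wins, in this order: protein-coding (> 20 % of
the unit over a coding gene, sense), non-coding RNA (any overlap with a
small-ncRNA annotation, either strand — small RNAs are much shorter than
TUs, so overlap quality is deliberately unrestricted), lncRNA (> 20 %,
sense), enhancer (member of a detected pair), divergent (> 10 % of the
unit over the ±500-bp promoter of an opposite-strand primary transcript
> 1 kb, and the unit < 50 % of the primary's size), antisense (> 20 % of
the unit covering > 20 % of an opposite-strand coding/lncRNA gene), repeat
(> 50 % of the unit in repeat-masked regions, union coverage, strandless),
other genic sense then antisense (residual < 20 % overlap of any gene
annotation), intergenic. The two "other genic" orientations are separate
classes, bringing the count to ten.

Enhancer pairs: opposite-strand units, both < 10 kb (the 10-kb figure is
used where the source material also mentions 9 kb; both thresholds are
flags), overlapping by ≥ 1 bp, with both TSSs > 10 kb from every annotated
TSS and TTS; pairing is greedy by overlap width (ties leftmost), one pair
per unit, center = overlap midpoint. Cell-type specificity: a pair is
shared when a pair from another cell type overlaps its merged span by
≥ 20 % of the query pair's length; active cell sets are connected
components of the sharing graph. Metagene profiles count read 5′ ends in
fixed bins around centers, per strand, skipping centers within one
half-window of a chromosome edge.

## Synthetic data

The simulator emulates the data regime the model assumes: non-overlapping
(per strand) genes at organism-preset densities — human 11, fly 76, worm
200 genes/Mb — with log-normal lengths (medians 23 kb / 3 kb / 1.5 kb;
σ_log = 0.6, chosen to give a realistic right tail without exceeding the
placement budget), planted divergent enhancer pairs ≥ 25 kb from genes,
and reads generated per window as Poisson(scale × Γ(k_T, θ_T)) inside
units (defaults k_T = 2, θ_T = 5, scale = 1 → mean 10 reads per 50-bp
window, a saturating depth) and Poisson(0.05) background. Reads are
integers by construction (gamma-Poisson), and the gamma-mixed mean is what
the HMM recovers after pseudocounting. All randomness flows from one spec
seed via `default_rng([seed, stage])`.

What the simulator does **not** emulate: promoter-proximal pause peaks,
intronic coverage dips, post-poly(A) run-through, mappability gaps,
overlapping same-strand genes, or library-specific biases. Passing tests
therefore demonstrate correctness of the algorithmics and calibration
under the model's own assumptions, not performance on any particular real
library; on real data the tuning grid exists precisely to absorb such
deviations.

## Problem sizes

The test suite and the acceptance script use a 10-Mb single-chromosome
genome with a 5×5 tuning grid for the end-to-end analysis, 1-Mb genomes
for the ten-seed density-stress comparison, 1e5 windows for parameter
recovery, and ≤ 12-window vectors (100 cases) for exact brute-force
equivalence — sizes at which every distributional property asserted is
already stable.

## Known limitations

Two states only: pause peaks and gene-internal expression shifts are not
modelled, and very close same-strand genes merge unless the boundary
repair separates them (gene-dense genomes remain the hardest case — the
worm-preset stress quantifies exactly this failure mode). The emission
model treats windows as conditionally independent; correlated artefacts
(e.g. repeat pile-ups) can create spurious short units, which the
classification stage flags rather than removes. Training is deterministic
given counts and initialisation; no multi-start is performed.
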