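# Methods

## The statistic

For a motif *m* and a foreground peak set, the pipeline computes the
occurrence count *x* of *m* in fixed windows around the peak summits, then
an empirical null distribution of that count, and summarizes enrichment as

    z = (x − μ) / σ

where μ and σ are the mean and standard deviation of the count over
`n_reps` replicate sets of random genomic regions, each length-matched
one-to-one to the foreground windows. The null is distribution-free: it
asks "how often does this motif occur in arbitrary genomic sequence of
exactly this amount and shape?", and the z-score measures how far the
observed count sits outside that resampling distribution. An add-one
empirical p-value, p = (1 + #{replicate counts ≥ x}) / (n_reps + 1),
accompanies z; it is bounded below by 1/(n_reps+1) and never exactly 0.
Across the motifs of one peak set (one test family per set), p-values are
Benjamini–Hochberg adjusted to q-values.

σ uses the sample (n−1) denominator — the null mean is itself estimated
from the replicates, so the unbiased convention applies. At the default
n_reps = 100 the population-denominator alternative differs by < 1%; the
choice is recorded in the archived run config (`sigma_denominator: n-1`)
so it is auditable.

## Summit windows

Each peak contributes one window [summit − w/2, summit + w/2), half-open,
with w = 200 by default ("200 bp around the summit" read as total width,
i.e. ±100 bp). The summit is the recorded narrowPeak point source when
present, else the region midpoint (integer division) — the only principled
fallback for plain BED. Edge windows are clipped to the chromosome rather
than discarded (discarding would silently shrink n; clipping is logged).
Windows with identical coordinates are collapsed to one, keeping first
occurrence order; the collapse count is logged. All coordinates everywhere
are 0-based half-open; there is no 1-based surface.

## The PWM scanner

Motifs are position frequency matrices with a background model. Counts are
smoothed with a total pseudocount of 0.1 distributed by background
frequency (common scanner practice, configurable) and converted to
log-odds in bits:

    log_odds[i][b] = log2( p[i][b] / background[b] ),
    p[i][b] = (counts[i][b] + 0.1·background[b]) / (total[i] + 0.1)

A window of width-w sequence scores the sum of log-odds over its bases.
Every offset of every region is evaluated on the plus strand and (by
default) the minus strand, via the reverse-complemented matrix at the same
plus-strand coordinates. Overlapping matches each count — the occurrence
count has no merging rule, which is the simplest auditable choice.
Windows containing N are skipped entirely rather than scored against the
background, so masked sequence can never fabricate matches. Regions
shorter than the motif contribute zero matches.

### Match threshold

A match is a window whose score reaches the smallest achievable score t
with P(score of a random background window ≥ t) ≤ α (default α = 10⁻⁴ —
the conventional scanner default; both α and strand handling are recorded
in the run metadata). The distribution is computed exactly by dynamic
programming: log-odds entries are rounded to a lattice of 10⁻³ bits and
the per-position score distributions convolved position by position under
the background model. Two numerical details:

- The tail comparison uses a tolerance of 10⁻⁹ so exact probability ties
  (and the α → 1 limit, where every outcome qualifies and t is the
  minimum achievable score) are stable against float accumulation.
- The DP threshold lies on the lattice while scan scores are continuous;
  per-entry rounding can displace a window's exact score by up to
  width·(10⁻³)/2 bits relative to its lattice score. Matches are therefore
  accepted at `t − width·resolution/2`, so a window whose rounded score
  reaches the threshold is never lost to discretization. Without this,
  a threshold equal to the rounded maximum score can exclude even the
  exact consensus.

If no achievable score is rare enough (e.g. a uniform motif), the
threshold is +∞ and the motif can never match; the pipeline flags the
resulting degenerate (σ = 0) null rather than dividing by zero, and the
CLI exits with a dedicated code when every motif is degenerate.

## Null sampling

For each replicate and each foreground window, one random region of
identical length is drawn: the chromosome with probability proportional to
its number of valid placements (length − region length + 1), the start
uniform among them — i.e. uniform over all genomic placements. Draws are
independent within and across replicates (positions sampled with
replacement); replicate i uses an RNG substream derived from (seed, i), so
extending a run with more replicates never perturbs earlier ones. Null
regions are scanned as-is with the foreground scan parameters — they
already have the foreground window lengths, so no summit re-windowing
applies. The foreground itself is *not* excluded from the sampling space
by default: with a sparse foreground the contamination is negligible, and
an explicit exclusion list (e.g. assembly gaps, or the peaks themselves)
can be supplied, enforced by rejection sampling with a 1000-attempt cap.
Matching is on length only; GC- or repeat-matched nulls are a possible
extension, not implemented.

## Synthetic data

The generator emulates exactly the structure the statistic assumes: an
i.i.d. background genome with controllable GC content, peaks placed
uniformly over valid positions (chromosome chosen proportional to valid
placements, summit at the midpoint), and motif instances planted into a
chosen fraction of peaks with a recorded truth table. Instances are
sampled column-by-column from the motif's probability matrix — not always
the consensus — so the score threshold is exercised on degenerate matches;
at most one instance is planted per peak, keeping the expected detected
count ≈ (planted fraction) × (detection probability) × n; planting
overwrites sequence in place, preserving all coordinates.

The standard scenario is two 300 kb chromosomes at GC 0.5, 200 peaks of
200 bp, an 8-bp motif with 90% consensus weight per column (~1.3
bits/column) planted at probability 0.5, scanned at α = 10⁻⁴ with 100 null
replicates. The negative control is the same motif with its columns in
shuffled order. A bare random shuffle occasionally produces a shifted
near-copy of the original consensus, which still matches planted
instances at offset ±1 and is therefore not a valid negative control;
permutations are rejected until the shuffled consensus shares no substring
longer than half the motif width with the original consensus or its
reverse complement (the least-similar permutation is kept if none passes,
e.g. for near-homopolymers).

What the synthetic data does *not* emulate: positional nucleotide
heterogeneity, repeats, chromatin signal, read-level noise, multiple
instances per peak, or motif co-occurrence. Passing tests therefore show
that the statistic and its null behave correctly under the model's own
assumptions — not that real peak sets satisfy those assumptions (real
genomes have composition structure that a length-only null ignores).

## Problem sizes and calibration

In the standard scenario the statistic is strongly separated: the planted
motif reaches z ≈ 20–25 while the decoy stays within |z| ≲ 0.5. With
nothing planted, z measured over 100 independent datasets has mean −0.06
and SD 1.03 — centred and close to unit scale — but the underlying count
is a small-count (Poisson-like, λ ≈ 1) variable, so individual z values
are discrete and right-skewed and small batches of datasets wander
accordingly. The calibration analysis uses 20 datasets (mean z −0.25,
p<0.05 rate 0.05); the acceptance script uses 50 for a steadier reported
mean. Each dataset takes well under a second to analyse: scanning is
vectorized over equal-length region batches, and null replicates reuse a
counting path that never materializes hit objects.

## Known limitations

- The null matches on length only; GC-rich motifs scanned against
  GC-heterogeneous real genomes will show composition-driven enrichment
  that this null does not remove.
- The empirical p-value saturates at 1/(n_reps+1); ranking beyond that
  resolution relies on z.
- The score-lattice resolution (10⁻³ bits) bounds the threshold's
  accuracy; thresholds agree with exhaustive enumeration only up to
  width × resolution.
- Replicate draws may overlap foreground peaks unless an exclusion list is
  supplied; for sparse peak sets on megabase genomes the effect is
  negligible.
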