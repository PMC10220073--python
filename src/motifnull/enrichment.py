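"""Empirical-null construction and the enrichment Z-score.

The null recomputes the occurrence count on many independent sets of
random genomic regions, each length-matched one-to-one to the foreground
regions. Enrichment of the observed count x is then summarized as
z = (x - mu) / sigma with mu and sigma the mean and sample standard
deviation of the replicate counts, together with a distribution-free
empirical p-value and a BH-adjusted q across motifs.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .scan import count_occurrences
from .types import (
    EnrichmentResult,
    GenomeSequence,
    MotifMatrix,
    NullDistribution,
    PeakSet,
    Region,
)

logger = logging.getLogger(__name__)

_MAX_REJECTION_ATTEMPTS = 1000


def sample_matched_regions(
    foreground: PeakSet,
    genome: GenomeSequence,
    n_reps: int,
    exclude: Optional[PeakSet] = None,
    rng_seed: int = 0,
) -> list[PeakSet]:
    """Replicate sets of random regions length-matched to the foreground.

    For each replicate and each foreground region one random region of
    identical length is drawn: the chromosome with probability proportional
    to the number of valid start positions (length - region length + 1),
    the start uniform among them. Draws overlapping an ``exclude`` interval
    are rejected and redrawn (up to 1000 attempts, then an error).

    Replicate i uses an independent RNG substream derived from
    (rng_seed, i), so adding replicates never perturbs earlier ones.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    chrom_names = list(genome.chromosomes)
    chrom_lengths = np.array([len(genome.chromosomes[c]) for c in chrom_names])
    lengths = [r.length for r in foreground.regions]
    if max(lengths, default=0) > chrom_lengths.max(initial=0):
        raise ValueError("a foreground region is longer than every chromosome")

    trees: dict[str, IntervalTree] = {}
    if exclude is not None:
        for r in exclude:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)

    replicates: list[PeakSet] = []
    for rep in range(n_reps):
        rng = np.random.default_rng([rng_seed, rep])
        regions: list[Region] = []
        for L in lengths:
            valid = np.maximum(chrom_lengths - L + 1, 0)
            probs = valid / valid.sum()
            for attempt in range(_MAX_REJECTION_ATTEMPTS):
                ci = rng.choice(len(chrom_names), p=probs)
                start = int(rng.integers(0, valid[ci]))
                chrom = chrom_names[ci]
                tree = trees.get(chrom)
                if tree is None or not tree.overlap(start, start + L):
                    regions.append(Region(chrom, start, start + L))
                    break
            else:
                raise RuntimeError(
                    f"rejection sampling exhausted ({_MAX_REJECTION_ATTEMPTS} attempts) "
                    f"for a region of length {L}"
                )
        replicates.append(PeakSet(regions, label=f"{foreground.label}_null_{rep}"))
    return replicates


def build_null(
    replicate_sets: Sequence[PeakSet],
    genome: GenomeSequence,
    motif: MotifMatrix,
    threshold: float,
    both_strands: bool = True,
) -> NullDistribution:
    """Occurrence count of the motif in each replicate random region set.

    Null regions are scanned as-is, with the same scan parameters as the
    foreground — they already have the foreground window lengths, so no
    summit re-windowing applies.
    """
    if len(replicate_sets) < 2:
        raise ValueError("need at least 2 replicate sets")
    counts = [
        int(count_occurrences(genome, rep.regions, motif, threshold, both_strands).sum())
        for rep in replicate_sets
    ]
    return NullDistribution(motif.motif_id, counts)


def zscore(
    x: int, null: NullDistribution, set_label: str = "", n_regions: int = 0
) -> EnrichmentResult:
    """z = (x - mu) / sigma; degenerate (sigma = 0) nulls are flagged, not divided."""
    mu, sigma = null.mu, null.sigma
    if sigma > 0:
        z: Optional[float] = (x - mu) / sigma
        degenerate = False
    else:
        z = None
        degenerate = True
        logger.warning("motif %s: degenerate null (sigma = 0)", null.motif_id)
    return EnrichmentResult(
        motif_id=null.motif_id,
        set_label=set_label,
        n_regions=n_regions,
        x=x,
        mu=mu,
        sigma=sigma,
        z=z,
        p_empirical=empirical_pvalue(x, null),
        degenerate=degenerate,
    )


def empirical_pvalue(x: int, null: NullDistribution) -> float:
    """Add-one permutation p-value: (1 + #{replicates >= x}) / (n_reps + 1)."""
    ge = sum(1 for c in null.replicate_counts if c >= x)
    return (1 + ge) / (null.n_reps + 1)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()
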