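"""Summit-window extraction and log-odds PWM scanning.

The scanner evaluates every offset of every region on the plus strand
(and, by default, the minus strand via the reverse-complemented matrix)
and reports matches whose log-odds score reaches a threshold. The
threshold is calibrated from the exact score distribution of a random
background-distributed window, computed by dynamic programming on a
discretized score lattice — the same match definition ("p-value < alpha")
used by the standard external scanners.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import GenomeSequence, MotifHit, MotifMatrix, OccurrenceStat, PeakSet, Region

logger = logging.getLogger(__name__)

#: Score lattice resolution for the threshold DP, in bits.
SCORE_RESOLUTION = 1e-3

# Byte-value lookup: A=0 C=1 G=2 T=3 N=4.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map an A/C/G/T/N string to uint8 codes 0..4 (N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Summit windows


def extract_summit_windows(
    peaks: PeakSet, window: int, genome_sizes: dict[str, int]
) -> PeakSet:
    """Fixed-width windows centred on peak summits.

    Each output region is ``[summit - window/2, summit + window/2)`` clipped
    to the chromosome. A recorded summit offset is used when present; plain
    BED regions fall back to their midpoint. Duplicate windows (identical
    chrom/start/end) collapse to one, keeping first-occurrence order; the
    collapse and clip counts are logged and recorded in the output's
    provenance.
    """
    if window < 2 or window % 2 != 0:
        raise ValueError("window must be an even integer >= 2")
    half = window // 2
    seen: dict[tuple[str, int, int], int] = {}
    out: list[Region] = []
    n_clipped = 0
    n_collapsed = 0
    for r in peaks:
        if r.chrom not in genome_sizes:
            raise ValueError(f"chromosome {r.chrom!r} absent from sizes")
        summit = r.summit()
        start = summit - half
        end = summit + half
        clipped_start = max(0, start)
        clipped_end = min(genome_sizes[r.chrom], end)
        if (clipped_start, clipped_end) != (start, end):
            n_clipped += 1
        key = (r.chrom, clipped_start, clipped_end)
        if key in seen:
            n_collapsed += 1
            continue
        seen[key] = len(out)
        out.append(Region(r.chrom, clipped_start, clipped_end, name=r.name))
    if n_collapsed:
        logger.info("%s: collapsed %d duplicate windows", peaks.label, n_collapsed)
    if n_clipped:
        logger.info("%s: clipped %d windows at chromosome edges", peaks.label, n_clipped)
    return PeakSet(
        out,
        label=peaks.label,
        provenance={"window": window, "n_collapsed": n_collapsed, "n_clipped": n_clipped},
    )


# ---------------------------------------------------------------------------
# Score threshold from the exact background score distribution


def score_distribution(motif: MotifMatrix, resolution: float = SCORE_RESOLUTION):
    """Exact distribution of the plus-strand score of a random background
    window, on a lattice of ``resolution`` bits.

    Returns ``(scores, probabilities)`` with scores ascending, computed by
    convolving the per-position score distributions position by position.
    """
    iv = np.rint(motif.log_odds / resolution).astype(np.int64)
    lo = int(iv.min(axis=1).sum())
    hi = int(iv.max(axis=1).sum())
    probs = np.zeros(hi - lo + 1)
    # Initialize with position 0, then convolve the rest.
    off0 = int(iv[0].min())
    cur = np.zeros(int(iv[0].max()) - off0 + 1)
    for b in range(4):
        cur[iv[0, b] - off0] += motif.background[b]
    cur_lo = off0
    for i in range(1, motif.width):
        ilo, ihi = int(iv[i].min()), int(iv[i].max())
        nxt = np.zeros(len(cur) + ihi - ilo)
        for b in range(4):
            shift = iv[i, b] - ilo
            nxt[shift : shift + len(cur)] += cur * motif.background[b]
        cur = nxt
        cur_lo += ilo
    probs[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    scores = (np.arange(lo, hi + 1)) * resolution
    mask = probs > 0
    return scores[mask], probs[mask]


def score_threshold(
    motif: MotifMatrix, alpha: float, resolution: float = SCORE_RESOLUTION
) -> float:
    """Smallest achievable score t with P(random window scores >= t) <= alpha.

    A small tolerance (1e-9) on the tail comparison keeps exact probability
    ties (and the alpha -> 1 limit, where the whole distribution qualifies
    and the minimum achievable score is returned) stable against float
    accumulation in the DP.

    Returns ``inf`` when no achievable score is rare enough, in which case
    scanning reports no matches.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    scores, probs = score_distribution(motif, resolution)
    tails = np.cumsum(probs[::-1])[::-1]  # tails[i] = P(score >= scores[i])
    ok = tails <= alpha + 1e-9
    if not ok.any():
        return float("inf")
    return float(scores[np.argmax(ok)])


# ---------------------------------------------------------------------------
# Scanning


def match_cutoff(threshold: float, width: int, resolution: float = SCORE_RESOLUTION) -> float:
    """Effective score cutoff compensating the threshold's lattice rounding.

    ``score_threshold`` returns a value on the discretized score lattice;
    an exact window score can fall up to width x resolution / 2 below the
    lattice value of the same window. Matches are therefore accepted at
    ``threshold - width * resolution / 2`` so a window whose rounded score
    reaches the lattice threshold is never lost to discretization.
    """
    if not np.isfinite(threshold):
        return threshold
    return threshold - width * resolution / 2 - 1e-12


def _batch_scores(batch: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Scores at every offset for equal-length encoded sequences.

    ``batch`` is (n_seqs, L) uint8; ``lom`` is the (width, 4) log-odds.
    Offsets whose window contains an N score -inf (skipped, never a match).
    """
    w = lom.shape[0]
    n, L = batch.shape
    n_off = L - w + 1
    if n_off <= 0:
        return np.empty((n, 0))
    lom5 = np.concatenate([lom, np.zeros((w, 1))], axis=1)  # N column, masked below
    scores = np.zeros((n, n_off))
    for i in range(w):
        scores += lom5[i, batch[:, i : i + n_off]]
    is_n = (batch == 4).astype(np.int32)
    cum = np.concatenate([np.zeros((n, 1), dtype=np.int32), np.cumsum(is_n, axis=1)], axis=1)
    has_n = (cum[:, w:] - cum[:, :-w]) > 0
    scores[has_n] = -np.inf
    return scores


def _iter_length_groups(regions: Sequence[Region]):
    groups: dict[int, list[int]] = {}
    for idx, r in enumerate(regions):
        groups.setdefault(r.length, []).append(idx)
    return groups.items()


def scan_regions(
    genome: GenomeSequence,
    windows: PeakSet,
    motif: MotifMatrix,
    threshold: float,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All motif matches scoring >= threshold across a region set.

    Every offset with room for the motif is evaluated on the plus strand
    and, if requested, on the minus strand (reverse-complemented matrix at
    the same plus-strand coordinates). Overlapping matches each count;
    windows containing N are skipped. Regions shorter than the motif yield
    no hits. The acceptance rule is ``score >= match_cutoff(threshold,
    width)``, which compensates the threshold's lattice discretization.
    """
    cutoff = match_cutoff(threshold, motif.width)
    hits: list[MotifHit] = []
    mats = [("+", motif.log_odds)]
    if both_strands:
        mats.append(("-", motif.reverse_complement_matrix()))
    for length, idxs in _iter_length_groups(windows.regions):
        if length < motif.width:
            continue
        batch = np.empty((len(idxs), length), dtype=np.uint8)
        for row, idx in enumerate(idxs):
            r = windows[idx]
            batch[row] = encode_sequence(genome.fetch(r.chrom, r.start, r.end))
        for strand, lom in mats:
            scores = _batch_scores(batch, lom)
            rows, offs = np.nonzero(scores >= cutoff)
            for row, off in zip(rows.tolist(), offs.tolist()):
                hits.append(MotifHit(idxs[row], off, strand, float(scores[row, off])))
    hits.sort(key=lambda h: (h.region_index, h.offset, h.strand))
    return hits


def count_occurrences(
    genome: GenomeSequence,
    regions: Sequence[Region],
    motif: MotifMatrix,
    threshold: float,
    both_strands: bool = True,
) -> np.ndarray:
    """Per-region match counts: the fast path behind the null replicates.

    Equivalent to counting ``scan_regions`` hits per region, without
    materializing the hit objects.
    """
    cutoff = match_cutoff(threshold, motif.width)
    counts = np.zeros(len(regions), dtype=np.int64)
    mats = [motif.log_odds]
    if both_strands:
        mats.append(motif.reverse_complement_matrix())
    for length, idxs in _iter_length_groups(regions):
        if length < motif.width:
            continue
        batch = np.empty((len(idxs), length), dtype=np.uint8)
        for row, idx in enumerate(idxs):
            r = regions[idx]
            batch[row] = encode_sequence(genome.fetch(r.chrom, r.start, r.end))
        group_counts = np.zeros(len(idxs), dtype=np.int64)
        for lom in mats:
            group_counts += (_batch_scores(batch, lom) >= cutoff).sum(axis=1)
        counts[idxs] = group_counts
    return counts


def occurrence_frequency(
    hits: Iterable[MotifHit], windows: PeakSet, motif_id: str, set_label: str
) -> OccurrenceStat:
    """Total occurrence count x and the number of hit-bearing regions."""
    hits = list(hits)
    return OccurrenceStat(
        motif_id=motif_id,
        set_label=set_label,
        n_regions=len(windows),
        x=len(hits),
        regions_with_hit=len({h.region_index for h in hits}),
    )


def hits_to_bed(
    hits: Iterable[MotifHit], windows: PeakSet, motif_id: str, motif_width: int
) -> list[str]:
    """Hits as BED6 lines with absolute coordinates and score x100."""
    lines = []
    for h in hits:
        r = windows[h.region_index]
        start = r.start + h.offset
        lines.append(
            f"{r.chrom}\t{start}\t{start + motif_width}\t{motif_id}\t"
            f"{round(h.score * 100)}\t{h.strand}"
        )
    return lines
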