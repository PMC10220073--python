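import itertools

import numpy as np
import pytest

from motifnull import MotifMatrix, reverse_complement
from motifnull.scan import match_cutoff


@pytest.fixture
def consensus_motif():
    """Consensus-only motif: one base per column (ACGT)."""
    counts = np.zeros((4, 4))
    for i in range(4):
        counts[i, i] = 10.0
    return MotifMatrix("CONSENSUS_ACGT", counts, pseudocount_total=0.0)


@pytest.fixture
def soft_motif():
    """Degenerate 4-bp motif with 70/10/10/10 columns (consensus ACGT)."""
    counts = np.full((4, 4), 10.0)
    for i in range(4):
        counts[i, i] = 70.0
    return MotifMatrix("SOFT_ACGT", counts)


def random_motif(rng, width, pseudocount_total=0.1):
    """A random count matrix with no all-zero columns."""
    counts = rng.integers(0, 50, size=(width, 4)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1.0
    return MotifMatrix(f"RAND_w{width}", counts, pseudocount_total=pseudocount_total)


def naive_scan(seq, motif, threshold, both_strands=True):
    """Independent per-window re-scorer: the scanner's oracle.

    Scores every offset directly from the log-odds definition; minus-strand
    scores come from reverse-complementing the window. Returns
    (offset, strand, score) triples.
    """
    cutoff = match_cutoff(threshold, motif.width)
    w = motif.width
    hits = []
    for o in range(len(seq) - w + 1):
        window = seq[o : o + w]
        if "N" in window:
            continue
        score = sum(motif.log_odds[i, "ACGT".index(b)] for i, b in enumerate(window))
        if score >= cutoff:
            hits.append((o, "+", score))
        if both_strands:
            rc = reverse_complement(window)
            score = sum(motif.log_odds[i, "ACGT".index(b)] for i, b in enumerate(rc))
            if score >= cutoff:
                hits.append((o, "-", score))
    return hits


def enumeration_threshold(motif, alpha):
    """Threshold oracle: exhaustive enumeration of all 4^w windows."""
    by_score = {}
    for word in itertools.product(range(4), repeat=motif.width):
        s = sum(motif.log_odds[i, b] for i, b in enumerate(word))
        p = float(np.prod([motif.background[b] for b in word]))
        by_score[s] = by_score.get(s, 0.0) + p
    tail = 0.0
    best = None
    for s in sorted(by_score, reverse=True):
        tail += by_score[s]
        if tail <= alpha + 1e-9:
            best = s
        else:
            break
    return best if best is not None else float("inf")
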