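from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifnull import (
    GenomeSequence,
    MotifMatrix,
    PeakSet,
    Region,
    extract_summit_windows,
    occurrence_frequency,
    scan_regions,
    score_threshold,
)
from motifnull.scan import count_occurrences, hits_to_bed
from motifnull.types import MotifHit

from conftest import enumeration_threshold, naive_scan, random_motif


class TestSummitWindows:
    SIZES = {"chr1": 10_000}

    def test_window_arithmetic_around_summit(self):
        peaks = PeakSet([Region("chr1", 500, 900, summit_offset=200)])
        win = extract_summit_windows(peaks, 200, self.SIZES)
        assert (win[0].start, win[0].end) == (600, 800)

    def test_midpoint_fallback_without_summit(self):
        peaks = PeakSet([Region("chr1", 100, 301)])  # midpoint 200
        win = extract_summit_windows(peaks, 100, self.SIZES)
        assert (win[0].start, win[0].end) == (150, 250)

    def test_edge_window_clipped_not_discarded(self):
        peaks = PeakSet([Region("chr1", 0, 100, summit_offset=50)])
        win = extract_summit_windows(peaks, 200, self.SIZES)
        assert (win[0].start, win[0].end) == (0, 150)
        assert win.provenance["n_clipped"] == 1

    def test_duplicate_windows_collapse_keeping_order(self):
        peaks = PeakSet(
            [
                Region("chr1", 500, 700, summit_offset=100),
                Region("chr1", 550, 750, summit_offset=50),  # same summit: 600
                Region("chr1", 900, 1100, summit_offset=100),
            ]
        )
        win = extract_summit_windows(peaks, 200, self.SIZES)
        assert [(r.start, r.end) for r in win] == [(500, 700), (900, 1100)]
        assert win.provenance["n_collapsed"] == 1

    @pytest.mark.parametrize("window", [0, 3, -2])
    def test_odd_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            extract_summit_windows(PeakSet([Region("chr1", 0, 10)]), window, self.SIZES)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            extract_summit_windows(
                PeakSet([Region("chrX", 0, 10)]), 4, self.SIZES
            )


class TestScoreThreshold:
    def test_width_one_hand_enumeration(self):
        # Scores (2,-1,-1,-1) uniform background: only A (prob 1/4) reaches 2.
        stub = SimpleNamespace(
            width=1,
            log_odds=np.array([[2.0, -1.0, -1.0, -1.0]]),
            background=np.full(4, 0.25),
        )
        assert score_threshold(stub, 0.25) == pytest.approx(2.0, abs=1e-9)

    def test_alpha_near_one_returns_minimum_achievable(self, soft_motif):
        t = score_threshold(soft_motif, 1 - 1e-12)
        assert t == pytest.approx(soft_motif.min_score, abs=soft_motif.width * 1e-3)

    def test_uniform_motif_has_no_rare_score(self):
        m = MotifMatrix("U", np.full((4, 4), 5.0))
        assert score_threshold(m, 0.01) == float("inf")

    @pytest.mark.parametrize("alpha", [0.25, 1e-2, 1e-3])
    @pytest.mark.parametrize("width", [2, 3, 4, 5])
    def test_dp_matches_exhaustive_enumeration(self, width, alpha):
        rng = np.random.default_rng(width * 100 + int(-np.log10(alpha)))
        for _ in range(3):
            m = random_motif(rng, width)
            expected = enumeration_threshold(m, alpha)
            got = score_threshold(m, alpha)
            if np.isinf(expected):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(expected, abs=width * 1e-3)

    def test_alpha_bounds_rejected(self, soft_motif):
        for alpha in (0.0, 1.0, -1.0, 2.0):
            with pytest.raises(ValueError):
                score_threshold(soft_motif, alpha)


class TestScanRegions:
    def test_planted_consensus_found_at_max_score(self, consensus_motif):
        seq = "TTTTTTTTTTACGTTTTTTTTT"
        g = GenomeSequence({"chr1": seq})
        windows = PeakSet([Region("chr1", 0, len(seq))])
        hits = scan_regions(g, windows, consensus_motif, 5.0, both_strands=False)
        assert [(h.offset, h.strand) for h in hits] == [(10, "+")]
        assert hits[0].score == pytest.approx(consensus_motif.max_score)

    def test_all_n_sequence_yields_no_hits(self, consensus_motif):
        g = GenomeSequence({"chr1": "N" * 50})
        windows = PeakSet([Region("chr1", 0, 50)])
        assert scan_regions(g, windows, consensus_motif, -100.0) == []

    def test_palindromic_motif_hits_both_strands(self):
        # AT is its own reverse complement.
        counts = np.zeros((2, 4))
        counts[0, 0] = counts[1, 3] = 10.0
        pal = MotifMatrix("PAL_AT", counts, pseudocount_total=0.0)
        g = GenomeSequence({"chr1": "GGATGG"})
        windows = PeakSet([Region("chr1", 0, 6)])
        hits = scan_regions(g, windows, pal, pal.max_score - 1e-6)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+"), (2, "-")]

    def test_region_shorter_than_motif_yields_no_hits(self, consensus_motif):
        g = GenomeSequence({"chr1": "ACGTACGT"})
        windows = PeakSet([Region("chr1", 0, 3)])
        assert scan_regions(g, windows, consensus_motif, -100.0) == []

    def test_matches_naive_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGTN"))
        for trial in range(8):
            L = int(rng.integers(20, 400))
            seq = "".join(rng.choice(bases, size=L, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            m = random_motif(rng, int(rng.integers(3, 9)))
            threshold = score_threshold(m, 0.02)
            g = GenomeSequence({"chr1": seq})
            windows = PeakSet([Region("chr1", 0, L)])
            got = [(h.offset, h.strand, h.score) for h in scan_regions(g, windows, m, threshold)]
            expected = sorted(naive_scan(seq, m, threshold), key=lambda h: (h[0], h[1]))
            assert [(o, s) for o, s, _ in got] == [(o, s) for o, s, _ in expected]
            assert np.allclose([x[2] for x in got], [x[2] for x in expected], atol=1e-9)

    def test_strand_symmetry_under_reverse_complement(self):
        from motifnull import reverse_complement

        rng = np.random.default_rng(7)
        seq = "".join(np.random.default_rng(3).choice(list("ACGT"), size=120))
        m = random_motif(rng, 6)
        g1 = GenomeSequence({"chr1": seq})
        g2 = GenomeSequence({"chr1": reverse_complement(seq)})
        w1 = PeakSet([Region("chr1", 0, len(seq))])
        threshold = score_threshold(m, 0.05)
        fwd = scan_regions(g1, w1, m, threshold)
        rev = scan_regions(g2, w1, m, threshold)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (len(seq) - h.offset - m.width, flip[h.strand], round(h.score, 9)) for h in rev
        )
        assert sorted((h.offset, h.strand, round(h.score, 9)) for h in fwd) == mirrored

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-2.0, 8.0), st.floats(0.0, 6.0))
    def test_raising_threshold_never_increases_hits(self, seed, t_low, delta):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        m = random_motif(rng, 5)
        g = GenomeSequence({"chr1": seq})
        regions = [Region("chr1", 0, 100)]
        lo = count_occurrences(g, regions, m, t_low).sum()
        hi = count_occurrences(g, regions, m, t_low + delta).sum()
        assert hi <= lo


class TestOccurrenceFrequency:
    WINDOWS = PeakSet([Region("chr1", i * 100, i * 100 + 50) for i in range(10)])

    def test_zero_hits(self):
        stat = occurrence_frequency([], self.WINDOWS, "M", "s")
        assert (stat.x, stat.regions_with_hit, stat.n_regions) == (0, 0, 10)

    def test_total_and_per_region_counts(self):
        hits = [
            MotifHit(0, 1, "+", 5.0),
            MotifHit(0, 7, "-", 5.0),
            MotifHit(0, 20, "+", 5.0),
            MotifHit(4, 3, "+", 5.0),
        ]
        stat = occurrence_frequency(hits, self.WINDOWS, "M", "s")
        assert (stat.x, stat.regions_with_hit) == (4, 2)

    def test_count_occurrences_agrees_with_scan(self, soft_motif):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        g = GenomeSequence({"chr1": seq})
        regions = [Region("chr1", i * 300, i * 300 + 250) for i in range(10)]
        windows = PeakSet(list(regions))
        threshold = score_threshold(soft_motif, 0.01)
        hits = scan_regions(g, windows, soft_motif, threshold)
        counts = count_occurrences(g, regions, soft_motif, threshold)
        assert counts.sum() == len(hits)
        per_region = np.bincount([h.region_index for h in hits], minlength=10)
        assert np.array_equal(counts, per_region)


def test_hits_export_as_bed6(consensus_motif):
    windows = PeakSet([Region("chr1", 100, 160)])
    hits = [MotifHit(0, 10, "-", 7.4321)]
    lines = hits_to_bed(hits, windows, consensus_motif.motif_id, consensus_motif.width)
    assert lines == ["chr1\t110\t114\tCONSENSUS_ACGT\t743\t-"]
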