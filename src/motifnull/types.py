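"""Domain types shared across the pipeline.

Coordinates are 0-based half-open (BED native) everywhere; there is no
1-based surface anywhere in the package.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Sentinel meaning "no summit recorded" (narrowPeak column 10 value -1).
SUMMIT_ABSENT = None


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _longest_common_substring(a: str, b: str) -> int:
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


@dataclass
class GenomeSequence:
    """Named chromosomes of A/C/G/T/N characters.

    The search space for motif scanning and for null-region sampling.
    Sequences are stored uppercased; any non-ACGTN character has been
    normalized to N by the reader.
    """

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chromosomes[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]

    def copy(self) -> "GenomeSequence":
        return GenomeSequence(dict(self.chromosomes))


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open, with an optional summit.

    ``summit_offset`` is the offset of the point source from ``start``
    (narrowPeak column 10); ``None`` means absent.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    summit_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside region of length "
                f"{self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def summit(self) -> int:
        """Absolute summit position: recorded point source, else midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return self.start + self.length // 2


@dataclass
class PeakSet:
    """An ordered list of regions with a provenance label."""

    regions: list[Region]
    label: str = ""
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    def validate_against(self, sizes: dict[str, int]) -> None:
        """Check every region fits inside the companion genome."""
        for i, r in enumerate(self.regions):
            if r.chrom not in sizes:
                raise ValueError(f"region {i}: unknown chromosome {r.chrom!r}")
            if r.end > sizes[r.chrom]:
                raise ValueError(
                    f"region {i}: {r.chrom}:{r.start}-{r.end} exceeds "
                    f"chromosome length {sizes[r.chrom]}"
                )


class MotifMatrix:
    """A position frequency matrix with background model and log-odds scores.

    The log-odds matrix is derived deterministically from the counts::

        log_odds[i][b] = log2( p[i][b] / background[b] )
        p[i][b] = (counts[i][b] + pseudocount_total * background[b])
                  / (column_total[i] + pseudocount_total)

    where ``i`` indexes motif positions and ``b`` the bases A,C,G,T.
    Scores are in bits.
    """

    def __init__(
        self,
        motif_id: str,
        counts: Sequence[Sequence[float]],
        background: Optional[Sequence[float]] = None,
        pseudocount_total: float = 0.1,
        name: str = "",
    ) -> None:
        self.motif_id = motif_id
        self.name = name
        self.counts = np.asarray(counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be a width x 4 matrix (A,C,G,T)")
        if self.counts.shape[0] < 1:
            raise ValueError("motif width must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if background is None:
            background = np.full(4, 0.25)
        self.background = np.asarray(background, dtype=float)
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise ValueError("background must be 4 strictly positive probabilities")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background probabilities must sum to 1")
        if pseudocount_total < 0:
            raise ValueError("pseudocount_total must be nonnegative")
        self.pseudocount_total = float(pseudocount_total)
        col_tot = self.counts.sum(axis=1) + self.pseudocount_total
        if np.any(col_tot <= 0):
            raise ValueError("each counts column total must be positive after pseudocounts")
        self._probabilities = (
            self.counts + self.pseudocount_total * self.background
        ) / col_tot[:, None]
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self._probabilities / self.background)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Per-position base probabilities (pseudocount-smoothed)."""
        return self._probabilities

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[b] for b in self.counts.argmax(axis=1))

    def reverse_complement_matrix(self) -> np.ndarray:
        """Log-odds for scanning the minus strand on plus-strand coordinates."""
        return self.log_odds[::-1, ::-1]

    def column_shuffled(self, seed: int, suffix: str = "_shuffled") -> "MotifMatrix":
        """A decoy motif: same columns in permuted position order.

        The decoy keeps the per-column information content but must lose
        the positional arrangement, so it works as a negative control:
        permutations are rejected when the shuffled consensus shares a
        substring of more than half the motif width with the original
        consensus or its reverse complement (a shifted near-copy would
        still match real instances). The least-similar permutation seen is
        kept if no candidate passes (e.g. near-homopolymer motifs).
        """
        rng = np.random.default_rng(seed)
        original = self.consensus()
        targets = (original, reverse_complement(original))
        best_perm, best_shared = None, self.width + 1
        limit = self.width // 2
        for _ in range(200):
            perm = rng.permutation(self.width)
            if self.width > 1 and np.array_equal(perm, np.arange(self.width)):
                continue
            cand = "".join(original[i] for i in perm)
            shared = max(_longest_common_substring(cand, t) for t in targets)
            if shared < best_shared:
                best_perm, best_shared = perm, shared
            if shared <= limit:
                break
        return MotifMatrix(
            self.motif_id + suffix,
            self.counts[best_perm],
            self.background,
            self.pseudocount_total,
            name=self.name + suffix,
        )

    def __repr__(self) -> str:
        return f"MotifMatrix({self.motif_id!r}, width={self.width})"


@dataclass(frozen=True)
class MotifHit:
    """One motif match inside a scanned region."""

    region_index: int
    offset: int
    strand: str
    score: float


@dataclass
class OccurrenceStat:
    """Observed motif occurrences over a region set.

    ``x`` is the total number of matches (overlapping matches each count);
    ``regions_with_hit`` counts regions containing at least one match.
    """

    motif_id: str
    set_label: str
    n_regions: int
    x: int
    regions_with_hit: int

    def __post_init__(self) -> None:
        if not (0 <= self.regions_with_hit <= self.n_regions):
            raise ValueError("regions_with_hit outside [0, n_regions]")
        if self.regions_with_hit > self.x:
            raise ValueError("regions_with_hit cannot exceed total hits")


@dataclass
class NullDistribution:
    """Motif occurrence counts over replicate random region sets."""

    motif_id: str
    replicate_counts: list[int]

    def __post_init__(self) -> None:
        if len(self.replicate_counts) < 2:
            raise ValueError("need at least 2 null replicates")

    @property
    def n_reps(self) -> int:
        return len(self.replicate_counts)

    @property
    def mu(self) -> float:
        return float(np.mean(self.replicate_counts))

    @property
    def sigma(self) -> float:
        # Sample SD ((n-1) denominator): the null mean is itself estimated.
        return float(np.std(self.replicate_counts, ddof=1))


@dataclass
class EnrichmentResult:
    """Enrichment of one motif in one foreground peak set."""

    motif_id: str
    set_label: str
    n_regions: int
    x: int
    mu: float
    sigma: float
    z: Optional[float]
    p_empirical: float
    q_bh: Optional[float] = None
    degenerate: bool = False


@dataclass
class ResultTable:
    """Enrichment results plus the run metadata needed to reproduce them."""

    rows: list[EnrichmentResult]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class PlantingTruth:
    """Record of motif instances written into a synthetic genome."""

    @dataclass(frozen=True)
    class Edit:
        region_index: int
        offset: int  # offset of the instance start within the region
        strand: str
        motif_id: str

    edits: list["PlantingTruth.Edit"]
    planting_probability: float
    seed: int

    def __len__(self) -> int:
        return len(self.edits)
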