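"""Synthetic genomes, peak sets and planted motif instances.

A fully self-contained toy dataset emulating the statistical structure
the enrichment analysis assumes: foreground regions enriched for a motif
against a background of matched nucleotide composition. Instances are
sampled from the motif's column probability distributions (not always the
consensus), so downstream score thresholding is exercised on degenerate
matches; each peak receives at most one instance, which keeps the
expected detected count analytically simple; planting overwrites the
background sequence in place, preserving all coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import io as mio
from .types import (
    BASES,
    GenomeSequence,
    MotifMatrix,
    PeakSet,
    PlantingTruth,
    Region,
    reverse_complement,
)


def generate_genome(
    chrom_lengths: list[int], gc_content: float, seed: int
) -> GenomeSequence:
    """I.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not (0 < gc_content < 1):
        raise ValueError("gc_content must lie in (0, 1)")
    if any(L < 1 for L in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 1")
    rng = np.random.default_rng(seed)
    at = (1 - gc_content) / 2
    gc = gc_content / 2
    probs = [at, gc, gc, at]  # A, C, G, T
    chromosomes = {}
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i, L in enumerate(chrom_lengths, start=1):
        draws = rng.choice(4, size=L, p=probs)
        chromosomes[f"chr{i}"] = base_bytes[draws].tobytes().decode("ascii")
    return GenomeSequence(chromosomes)


def generate_peaks(
    genome: GenomeSequence, n_peaks: int, peak_length: int, seed: int
) -> PeakSet:
    """Peaks placed uniformly over all valid genomic positions.

    The chromosome is chosen with probability proportional to its number
    of valid placements (length - peak_length + 1); the summit is recorded
    at the peak midpoint. Peaks may overlap.
    """
    if n_peaks <= 0:
        raise ValueError("n_peaks must be positive")
    names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in names])
    if peak_length > lengths.min():
        raise ValueError("peak_length exceeds the shortest chromosome")
    valid = lengths - peak_length + 1
    probs = valid / valid.sum()
    rng = np.random.default_rng(seed)
    regions = []
    for k in range(n_peaks):
        ci = rng.choice(len(names), p=probs)
        start = int(rng.integers(0, valid[ci]))
        regions.append(
            Region(
                names[ci],
                start,
                start + peak_length,
                name=f"peak_{k + 1}",
                score=0.0,
                summit_offset=peak_length // 2,
            )
        )
    return PeakSet(regions, label="synthetic_peaks")


def plant_motifs(
    genome: GenomeSequence,
    peaks: PeakSet,
    motif: MotifMatrix,
    planting_probability: float,
    seed: int,
) -> tuple[GenomeSequence, PlantingTruth]:
    """Write motif instances into a fraction of peaks, recording the truth.

    Each peak independently receives, with ``planting_probability``, one
    instance sampled column-by-column from the motif's probability matrix,
    at a uniform valid offset and on a uniform strand (written as its
    reverse complement when minus). The genome is copied; bases outside
    the recorded edits are unchanged.
    """
    if not (0 <= planting_probability <= 1):
        raise ValueError("planting_probability must lie in [0, 1]")
    for r in peaks:
        if motif.width > r.length:
            raise ValueError(
                f"motif width {motif.width} exceeds region length {r.length}"
            )
    rng = np.random.default_rng(seed)
    chroms = {name: bytearray(seq, "ascii") for name, seq in genome.chromosomes.items()}
    edits: list[PlantingTruth.Edit] = []
    probs = motif.probabilities
    for idx, r in enumerate(peaks):
        if rng.random() >= planting_probability:
            continue
        instance = "".join(BASES[rng.choice(4, p=probs[i])] for i in range(motif.width))
        strand = "+" if rng.random() < 0.5 else "-"
        written = instance if strand == "+" else reverse_complement(instance)
        offset = int(rng.integers(0, r.length - motif.width + 1))
        pos = r.start + offset
        chroms[r.chrom][pos : pos + motif.width] = written.encode("ascii")
        edits.append(PlantingTruth.Edit(idx, offset, strand, motif.motif_id))
    edited = GenomeSequence({n: s.decode("ascii") for n, s in chroms.items()})
    return edited, PlantingTruth(edits, planting_probability, seed)


def default_planted_motif(motif_id: str = "PLANTED") -> MotifMatrix:
    """An 8-bp high-information motif (~1.3 bits/column) used by the demo.

    Each column gives 90% weight to one consensus base; sampled instances
    therefore carry occasional off-consensus bases, exercising the score
    threshold rather than exact string matching.
    """
    consensus = "ACGTGACC"
    counts = np.full((len(consensus), 4), 10 / 3)
    for i, base in enumerate(consensus):
        counts[i] = [10 / 3] * 4
        counts[i, BASES.index(base)] = 90.0
    return MotifMatrix(motif_id, counts)


def generate_demo_dataset(
    output_dir: Union[str, Path],
    seed: int,
    chrom_lengths: tuple[int, ...] = (300_000, 300_000),
    gc_content: float = 0.5,
    n_peaks: int = 200,
    peak_length: int = 200,
    planting_probability: float = 0.5,
    motif: Optional[MotifMatrix] = None,
) -> dict[str, Path]:
    """Generate and write the standard synthetic scenario.

    A two-chromosome 2 x 300 kb genome at GC 0.5, 200 peaks of 200 bp with
    midpoint summits, one 8-bp information-rich motif planted into half the
    peaks, plus a column-shuffled decoy sharing its composition. Emits
    standard files (FASTA genome, narrowPeak peaks, JASPAR motifs,
    chrom.sizes, truth TSV) and returns their paths.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if motif is None:
        motif = default_planted_motif()
    decoy = motif.column_shuffled(seed=seed + 1, suffix="_DECOY")
    genome = generate_genome(list(chrom_lengths), gc_content, seed)
    peaks = generate_peaks(genome, n_peaks, peak_length, seed + 2)
    genome, truth = plant_motifs(genome, peaks, motif, planting_probability, seed + 3)

    paths = {
        "genome": output_dir / "genome.fa",
        "chrom_sizes": output_dir / "genome.chrom.sizes",
        "peaks": output_dir / "peaks.narrowPeak",
        "motifs": output_dir / "motifs.jaspar",
        "truth": output_dir / "truth.tsv",
    }
    mio.write_fasta(genome, paths["genome"])
    mio.write_chrom_sizes(genome.sizes, paths["chrom_sizes"])
    mio.write_peaks(peaks, paths["peaks"], dialect="narrowPeak")
    mio.write_motifs_jaspar([motif, decoy], paths["motifs"])
    mio.write_truth_table(truth, peaks, paths["truth"])
    return paths
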