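"""Readers and writers for the standard formats the pipeline touches.

FASTA via Bio.SeqIO, motif matrices via Bio.motifs (JASPAR PFM and MEME
minimal), peak tables via pandas. All coordinates stay 0-based half-open
exactly as in the files.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .types import (
    EnrichmentResult,
    FormatError,
    GenomeSequence,
    MotifMatrix,
    PeakSet,
    Region,
    ResultTable,
)

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

RESULT_COLUMNS = [
    "motif_id",
    "set_label",
    "n_regions",
    "x",
    "mu",
    "sigma",
    "z",
    "p_empirical",
    "q_bh",
    "n_reps",
    "window",
    "threshold_pvalue",
    "seed",
]


# ---------------------------------------------------------------------------
# FASTA / chrom.sizes


def read_fasta(path: Union[str, Path]) -> GenomeSequence:
    """Read a (possibly line-wrapped) FASTA file into a GenomeSequence.

    Sequences are uppercased; any character outside {A,C,G,T,N} is mapped
    to N and the substitution count is logged.
    """
    path = Path(path)
    chromosomes: dict[str, str] = {}
    n_subst = 0
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises ValueError on malformed input
        raise FormatError(f"{path}: not parseable as FASTA: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: empty or non-FASTA file")
    for rec in records:
        name = rec.id
        if not name:
            raise FormatError(f"{path}: record with empty header")
        if name in chromosomes:
            raise FormatError(f"{path}: duplicate header {name!r}")
        seq = str(rec.seq).upper()
        cleaned = _NON_ACGTN.sub("N", seq)
        n_subst += sum(a != b for a, b in zip(seq, cleaned))
        chromosomes[name] = cleaned
    if n_subst:
        logger.warning("%s: %d non-ACGTN characters normalized to N", path, n_subst)
    return GenomeSequence(chromosomes)


def write_fasta(genome: GenomeSequence, path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: Union[str, Path]) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bases."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
        if name in sizes:
            raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_peaks(
    path: Union[str, Path],
    dialect: str = "narrowPeak",
    label: Optional[str] = None,
) -> PeakSet:
    """Read a BED3+ or ENCODE narrowPeak file.

    narrowPeak column 10 (point-source offset from start) becomes the
    region's summit offset; the sentinel -1 means absent. Coordinates are
    kept 0-based half-open exactly as in the file.
    """
    path = Path(path)
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    regions: list[Region] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        minimum = 10 if dialect == "narrowPeak" else 3
        if len(fields) < minimum:
            raise FormatError(
                f"{path}:{lineno}: {dialect} needs >= {minimum} columns, got {len(fields)}"
            )
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
        summit_offset = None
        if dialect == "narrowPeak":
            try:
                raw = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer summit offset") from exc
            if raw != -1:
                if not (0 <= raw < end - start):
                    raise FormatError(
                        f"{path}:{lineno}: summit offset {raw} outside region"
                    )
                summit_offset = raw
        regions.append(Region(chrom, start, end, name, score, summit_offset))
    return PeakSet(regions, label=label or path.stem)


def write_peaks(peaks: PeakSet, path: Union[str, Path], dialect: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for r in peaks:
            name = r.name if r.name is not None else "."
            score = f"{r.score:g}" if r.score is not None else "0"
            if dialect == "narrowPeak":
                summit = r.summit_offset if r.summit_offset is not None else -1
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t.\t0\t-1\t-1\t{summit}\n"
                )
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# Motif matrices


def read_motifs(
    path: Union[str, Path],
    fmt: str = "jaspar_pfm",
    background: Optional[Sequence[float]] = None,
    pseudocount_total: float = 0.1,
) -> list[MotifMatrix]:
    """Read motifs from JASPAR PFM or MEME minimal format.

    MEME letter-probability rows are converted to counts by multiplying by
    the stated nsites (100 when absent), giving one internal representation
    for both formats. Log-odds are derived immediately.
    """
    path = Path(path)
    if fmt == "jaspar_pfm":
        bio_fmt = "jaspar"
    elif fmt == "meme_minimal":
        bio_fmt = "minimal"
    else:
        raise ValueError(f"unknown motif format {fmt!r}")
    try:
        with open(path) as fh:
            parsed = list(bio_motifs.parse(fh, bio_fmt))
    except OSError:
        raise
    except Exception as exc:  # Bio.motifs raises bare Exception on bad input
        raise FormatError(f"{path}: not parseable as {fmt}: {exc}") from exc
    if not parsed:
        raise FormatError(f"{path}: no motifs found")
    out: list[MotifMatrix] = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)])
        motif_id = getattr(m, "matrix_id", None) or m.name or f"motif_{len(out) + 1}"
        try:
            out.append(
                MotifMatrix(
                    motif_id,
                    counts,
                    background=background,
                    pseudocount_total=pseudocount_total,
                    name=m.name or "",
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: motif {motif_id}: {exc}") from exc
    return out


def write_motifs_jaspar(motifs_list: Sequence[MotifMatrix], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for m in motifs_list:
            fh.write(f">{m.motif_id} {m.name or m.motif_id}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{v:g}" for v in m.counts[:, bi])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Result tables


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_results(table: ResultTable, path: Union[str, Path]) -> None:
    """Write results as TSV with a fixed 13-column order.

    Floats use 6 significant digits; the run metadata (replicate count,
    window, threshold p-value, seed) is carried on every row so the file
    round-trips without a sidecar.
    """
    meta = table.metadata
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in table.rows:
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (
                        r.motif_id,
                        r.set_label,
                        r.n_regions,
                        r.x,
                        r.mu,
                        r.sigma,
                        r.z,
                        r.p_empirical,
                        r.q_bh,
                        meta.get("n_reps"),
                        meta.get("window"),
                        meta.get("threshold_pvalue"),
                        meta.get("seed"),
                    )
                )
                + "\n"
            )


def read_results(path: Union[str, Path]) -> ResultTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if list(df.columns) != RESULT_COLUMNS:
        raise FormatError(f"{path}: unexpected result columns {list(df.columns)}")
    rows = []
    for _, rec in df.iterrows():
        z = None if pd.isna(rec["z"]) else float(rec["z"])
        q = None if pd.isna(rec["q_bh"]) else float(rec["q_bh"])
        rows.append(
            EnrichmentResult(
                motif_id=str(rec["motif_id"]),
                set_label=str(rec["set_label"]),
                n_regions=int(rec["n_regions"]),
                x=int(rec["x"]),
                mu=float(rec["mu"]),
                sigma=float(rec["sigma"]),
                z=z,
                p_empirical=float(rec["p_empirical"]),
                q_bh=q,
                degenerate=z is None,
            )
        )
    metadata = {}
    if len(df):
        first = df.iloc[0]
        metadata = {
            "n_reps": int(first["n_reps"]),
            "window": int(first["window"]),
            "threshold_pvalue": float(first["threshold_pvalue"]),
            "seed": int(first["seed"]),
        }
    return ResultTable(rows, metadata)


def write_truth_table(truth, peaks: PeakSet, path: Union[str, Path]) -> None:
    """TSV audit of planted motif instances (synthetic data only)."""
    with open(path, "w") as fh:
        fh.write("region_index\tchrom\toffset\tstrand\tmotif_id\n")
        for e in truth.edits:
            r = peaks[e.region_index]
            fh.write(f"{e.region_index}\t{r.chrom}\t{e.offset}\t{e.strand}\t{e.motif_id}\n")


def write_null_counts(nulls: dict[str, "object"], path: Union[str, Path]) -> None:
    """Audit export of per-replicate null occurrence counts."""
    with open(path, "w") as fh:
        fh.write("motif_id\treplicate_index\tcount\n")
        for motif_id, null in nulls.items():
            for i, c in enumerate(null.replicate_counts):
                fh.write(f"{motif_id}\t{i}\t{c}\n")
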