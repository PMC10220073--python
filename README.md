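# motifnull

Transcription-factor motif enrichment at ChIP-seq peaks, scored against an
empirical null of length-matched random genomic regions.

Given a genome (FASTA), a peak set (BED or MACS narrowPeak, summit-aware)
and motif matrices (JASPAR PFM or MEME minimal), the pipeline

1. extracts fixed windows (default 200 bp total) around each peak summit;
2. counts motif occurrences in those windows with a log-odds PWM scanner
   whose match threshold is calibrated from the exact score distribution of
   a background window (default background p-value α = 10⁻⁴, both strands);
3. repeats the identical count on `n_reps` (default 100) independent sets
   of random genomic regions, each length-matched one-to-one to the
   foreground windows; and
4. reports, per motif, the enrichment **z = (x − μ)/σ**, where *x* is the
   observed occurrence count, and μ and σ are the mean and sample standard
   deviation of the counts over the random replicate sets — plus an
   add-one empirical p-value, (1 + #{replicates ≥ x})/(n_reps + 1), and a
   Benjamini–Hochberg q across motifs.

This resampling z-score is the statistic used to rank motif enrichment at
remodeller-bound regulatory sites (e.g. SWI/SNF/BRG1-occupied peaks); the
package makes that bespoke computation reproducible and testable. It is
aimed at regulatory-genomics analysts who have peak calls and motif
matrices and want a distribution-free enrichment measure with an auditable
null. A synthetic-data module (genome simulation with motif planting and a
truth table) makes every stage verifiable without any external download.

## Worked example

The one-command demonstration simulates a 2 × 300 kb genome (GC 0.5) with
200 peaks of 200 bp, plants an 8-bp information-rich motif into half of
the peaks, adds a column-shuffled decoy motif, and runs the full pipeline:

```bash
motifnull demo --output-dir demo_run --seed 0
```

prints

```
planted motif: x=45 mu=3.45 sigma=1.70 z=24.41 p=0.009901
decoy   motif: x=1 mu=0.92 sigma=1.02 z=0.08 p=0.604
```

The planted motif is found 45 times in the summit windows against a null
expectation of 3.45 ± 1.70 occurrences in length-matched random regions —
z ≈ 24, with the smallest empirical p-value attainable at 100 replicates
(1/101). The decoy, which has the same column composition but a shuffled
position order, stays at the null level (z ≈ 0): the enrichment is
specific to the planted arrangement, not to base composition.
`demo_run/results.tsv` holds the full table; `null_counts.tsv` the
per-replicate null counts; `config_resolved.yaml` the archived
configuration; `run.log` the seed and every clip/collapse/degeneracy
event. Other subcommands (`simulate`, `windows`, `scan`, `enrich`) expose
the individual stages; `enrich` also accepts a YAML config with CLI
overrides.

The same workflow as a scripted analysis lives under `analysis/`:
`01_simulate_dataset.py` (writes the synthetic dataset to `results/data/`),
`02_motif_enrichment.py` (the enrichment table above, to
`results/enrichment/`), `03_null_calibration.py` (20 unplanted datasets;
mean z −0.25, p<0.05 rate 0.05 — a centred null with near-uniform p).

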