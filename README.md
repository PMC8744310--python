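# isoqc

Validation, novelty classification and differential-usage analysis for
long-read transcriptome annotations, exercised end-to-end on synthetic data
with known ground truth.

Given a reference annotation (GTF), a candidate annotation containing
putative novel transcripts, a genome (FASTA) and orthogonal short-read
evidence, `isoqc`:

- classifies every candidate transcript's novel features relative to the
  reference — cassette exons, novel donor/acceptor sites, exons with both
  boundaries novel, novel junctions between known sites, novel TSS/TTS —
  and removes antisense duplicates that perfectly mirror existing models;
- validates novel exons against short-read coverage (≥ 15 reads over
  ≥ 75% of exon length), junctions against split-read support, and
  expression (≥ 5 reads in ≥ 3 samples); flags internally-primed 3' ends
  (20 bp A-rich window);
- assigns coding status through a decision tree: noncoding parent gene →
  frameshift test against the best-matching reference isoform → a
  trainable coding-potential model (ORF length/coverage, Fickett TESTCODE,
  hexamer bias; logistic regression, call threshold 0.364);
- checks novel transcription start sites against CAGE peaks (±500 bp);
- quantifies differential expression (TMM factors, NB exact-style test,
  BH correction, ±1.5 logFC / FDR 0.05 filter), differential transcript
  usage (isoform fractions, per-gene sum |dIF| permutation test), and
  classifies alternative-splicing events between isoform pairs
  (ES/MES/IR/A5/A3/ATSS/ATTS/MEE);
- analyses spike-in sensitivity: TPM, expected vs observed log-fold
  change, and a broken-stick limit-of-quantification fit.

The `isoqc.simulate` module generates every input with ground-truth labels
(genome, annotations with injected novel features of each category,
coverage tracks with designed pass/fail exons, NB count matrices with
planted DE/DTU, spike-in mixes with a detection floor, CAGE peaks), so the
whole pipeline is testable by parameter recovery without external data.

## CLI

```sh
# write a synthetic input bundle (FASTA/GTF/BedGraph/TSV/BED + truth labels)
isoqc simulate --out-dir bundle --seed 7

# run every stage; outputs + manifest.json land in bundle/results
isoqc all --config bundle/config.toml

# single stages (same config; other inputs are ignored)
isoqc classify --config bundle/config.toml
isoqc de --config bundle/config.toml --lfc 1.0 --fdr 0.1
```

All thresholds in the TOML config can be overridden with flags; every
stage logs record counts and timings to stderr and registers its output
files (with checksums) in `manifest.json`. Stages whose inputs are absent
are skipped and noted in the manifest.

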