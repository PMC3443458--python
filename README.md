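# dauerx

Cross-species two-color microarray analysis under global transcriptional
repression, exercised end-to-end on synthetic data with known ground truth.

The pipeline reproduces the analysis pattern of a comparative dauer-stage
transcriptome study on a common-reference design:

1. **synthgen** — generate a complete two-species synthetic study: spot-level
   two-color scans (dye swaps included), probe→gene maps with spike-in flags,
   directional sequence-search hit tables, and a full annotation bundle
   (ontology, gene sets, clusters, protein domains, pathways, pioneer genes).
   A global mRNA-fraction repression factor *f* scales the dauer sample
   channel while spike-ins are deliberately left unscaled — they carry the
   information that separates global repression from dye/array effects.
2. **normalize** — per-channel background correction under the
   Normal-background + Exponential-signal convolution model (conditional
   expectation, computed stably in log space), M/A computation with the
   dye-orientation sign convention, and a robust weighted loess of M on A
   with up-weighted spikes plus an affine spike anchor.  With *f* = 0.5 the
   anchored normalization leaves null genes at median M ≈ −1 while the naive
   equal-weight unanchored loess erases the shift — both behaviours are
   asserted in the test suite.
3. **diffexp** — probe→gene weighted-median summarization, per-gene
   two-group linear model, empirical-Bayes variance moderation (moments
   estimation of the prior degrees of freedom via the inverse trigamma),
   moderated t-statistics and Benjamini–Hochberg FDR calls.
4. **orthomap** — reciprocal-best-hit 1:1 orthology with a 50-bit score
   cutoff, HSP collapsing and a deterministic tie-break chain.
5. **xcompare** — joins the two species' results over ortholog pairs,
   labels conservation classes 1–4 and fold-change quadrants, computes the
   one-sided Fisher overlap test and Pearson correlation report.
6. **enrich** — ontology-term enrichment with DAG propagation and 1:1
   annotation transfer, expression-cluster score matrix (per-column BH,
   −log10 scores), protein-family median fold-change profiles, pathway
   up/down/no-change tabulation, and a two-sample Kolmogorov–Smirnov
   subset-shift test.

## CLI

Run the whole pipeline from one YAML config:

```bash
dauerx run --config cfg.yaml
```

with a config such as

```yaml
seed: 3
outdir: out
fdr_threshold: 0.05
synthetic:
  n_genes_per_species: 2000
  n_orthologs: 600
  repression_factor: 1.0
```

Stage subcommands (`dauerx simulate / normalize / diffexp / orthologs /
compare / enrich`) operate on the corresponding files so each stage can be
re-run standalone; see `dauerx <cmd> --help`.  Outputs are plain TSVs plus a
deterministic `summary.json` (DE summary counts, class and quadrant counts,
Fisher overlap test, correlation report, enrichment table paths).

## Layout

```
src/dauerx/        arrayio, synthgen, normalize, diffexp, orthomap,
                   xcompare, enrich, pipeline, cli
tests/             unit + property tests per module, test_acceptance.py
scripts/acceptance.py
```
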