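# srnapipe

A small-RNA-seq analysis pipeline built around an early-embryo
wild-type vs mutant × three-timepoint × three-replicate design:

- **synthetic data** (`srnapipe.synthetic`) — toy genome with miRNA hairpins,
  structural RNAs, TE copies, cis-NAT pairs and gene models; simulated FASTQ
  libraries with per-read ground truth (source locus, isoform type, 3' tail)
  and five planted miRNA expression classes (A–E).
- **preprocess** (`srnapipe.preprocess`) — exact adapter removal, all-base
  phred >= 20 filter, 18–30 nt length filter, collapsing to unique sequences,
  optional in-silico depletion (e.g. 2S rRNA).
- **align / annotate** (`srnapipe.align`) — exact-match index over both
  strands, bounded-mismatch ungapped realignment, uniform 1/k multi-mapper
  weights, and priority-ordered class annotation (miRNA > structural >
  cis-NAT (21 nt) > TE > exon > intron > intergenic; TE-siRNA = 21 nt,
  TE-piRNA >= 23 nt) plus per-library class composition and piRNA-cluster
  distributions.
- **isomiR classification** (`srnapipe.isomir`) — canonical (exact mature
  match), noncanonical (perfect genome match inside the mature locus extended
  2 nt 5' / 5 nt 3'), and 3' non-templated addition (NTA): trim the last
  3 nt, realign perfectly, realign the full read to the hairpin with <= 3
  mismatches, and accept only the MMX / MXX / XXX terminal patterns. Per-miRNA
  isoform quantification, summary tables, and length / first-nucleotide /
  tail-composition distributions.
- **quantify** (`srnapipe.quantify`) — RPM, expression filter (RPM > 1 in
  >= 6 of 18 libraries), TMM normalization (30% M-trim, 5% A-trim,
  inverse-variance weights; matches the reference implementation to 4
  decimals), and a negative-binomial GLM likelihood-ratio test
  (genotype × timepoint grouped means, Cox–Reid adjusted-profile-likelihood
  dispersion with empirical-Bayes shrinkage, BH FDR).
- **profiles** (`srnapipe.profiles`) — sample-set means, hierarchical
  clustering of log2 RPM profiles into k = 5 classes, class summaries, and
  the downregulated / noncanonical-subset / NTA-subset selection filters.
- **overlap** (`srnapipe.overlap`) — gene lists, target-set assembly from a
  TargetScan-like table, one-tailed Fisher overlap tests (hypergeometric
  upper tail) with sample and conditional-MLE odds ratios.
- **pipeline / CLI** (`srnapipe.pipeline`, `srnapipe.cli`) — end-to-end
  orchestration with provenance-stamped TSV outputs.

## Tests

```sh
python -m pytest tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` (one test per acceptance criterion). One strict
consistency test is intentionally red: a single printed percentage cell in
the source table is not reproducible from its own printed components
(rounding adjusted to sum to 100); see `/root/notes` ledger for details —
the companion test covering the 17 consistent cells passes.

## CLI

```sh
srnapipe demo --out demo_run --seed 1          # simulate + full pipeline
srnapipe simulate --out sim --seed 1           # reference bundle + FASTQs
srnapipe preprocess --fastq sim/fastq/wt_UF0_2h_r1.fastq --out collapsed.fa
srnapipe all --reference-dir sim/reference --manifest sim/fastq/manifest.tsv \
             --outdir results --adapter TGGAATTCTCGGGTGCCAAGG
srnapipe overlap --universe 6191 --list-a a.txt --list-b b.txt
```

Stage outputs (collapsed FASTA, composition, isoform count matrices, TMM
factors, DE tables, class assignments, subset selections) are TSVs with a
`# srnapipe <version> stage=... config=<hash> seed=<seed>` provenance header.

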