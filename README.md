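# snpenrich

Tissue- and cell-type-specific epigenomic enrichment testing for GWAS SNP
sets, with covariate-matched background sampling.

Most trait-associated variants found by genome-wide association studies fall
outside protein-coding sequence, and a large fraction of them land in
cell-type-specific regulatory DNA — DNase I hotspots, histone-mark broadPeaks,
chromatin-state segments.  Asking *which* cell types a GWAS signal prefers is
therefore one of the first functional questions after an association scan.
`snpenrich` answers it for a SNP set and a collection of biosample annotation
tracks, for researchers who want a statistically calibrated alternative to
naive overlap counting: raw overlap rates are confounded by minor allele
frequency, distance to transcription start sites and local GC content, all of
which co-vary with regulatory annotation density.

## Method

For an input SNP set of size *n* (optionally LD-pruned at a greedy
r² ≥ 0.8 filter that keeps the first SNP of each correlated group) and each
biosample *s*:

1. **Overlap score.** k = number of input SNPs whose position falls inside
   one of *s*'s intervals (0-based half-open point membership, precomputed
   into a SNP × biosample bitstring database).
2. **Matched backgrounds.** 1000 background SNP sets are drawn from the SNP
   universe, each background SNP matched to an input SNP on its decile bin of
   (MAF, TSS distance, GC), so the backgrounds reproduce the input's
   covariate profile exactly.
3. **Test.** The pooled background overlap fraction p̂ estimates the null
   per-SNP overlap probability; the enrichment p-value is the exact one-sided
   binomial tail P(X ≥ k), X ~ Binomial(n, p̂).  An empirical Z-score
   (k − mean)/sd against the background score distribution is reported
   alongside.
4. **Correction.** Benjamini–Hochberg across all biosamples of the run;
   q < 0.01 flags significance.  Depletion (z < 0) is reported, never flagged.

Batch mode splits a GWAS-catalogue association TSV by phenotype (≥ 5 SNPs
each), runs the pipeline per phenotype, and assembles a phenotype × biosample
−log₁₀(q) matrix with row-max normalisation and complete-linkage Euclidean
clustering.  A synthetic-data module generates universes, confounded tracks
and spiked input sets with exact ground truth, and a false-positive-rate
harness pushes thousands of uniform-random SNP sets through the full pipeline.

## Worked example

Simulate a small study (10,000 SNPs, 10 biosamples), build the overlap
database, and test a 25-SNP input constructed so that 60% of its SNPs fall in
biosample `S003`'s covered regions:

```sh
snpenrich simulate --out-dir fixture --n-snps 10000 --n-samples 10 --seed 11
snpenrich build-db fixture/universe.tsv fixture/manifest.tsv overlap.db
snpenrich run overlap.db fixture/universe.tsv gwas_hits.txt --out-dir results --seed 7
```

The log reports `1/10 samples significant at q < 0.01`, and the top of
`results/results.tsv` reads (selected columns):

```
sample_id  n   k_obs  p_hat    bg_mean  bg_sd  z      p_binom   q         significant
S003       25  15     0.17492  4.373    1.483  7.168  2.41e-06  2.41e-05  True
S007       25  6      0.17348  4.337    1.483  1.121  0.258     0.655     False
S006       25  5      0.14828  3.707    1.463  0.884  0.309     0.655     False
```

15 of the 25 input SNPs overlap `S003`, against a matched-background
expectation of ~4.4 (p̂ = 0.175 per SNP): the spiked biosample is recovered
with q = 2.4 × 10⁻⁵, while every unspiked biosample stays at q ≈ 0.66.
`results/per_variant.tsv` lists which variants drive the call, and
`run_manifest.json` records the seed, config and input digests for
reproducibility.

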