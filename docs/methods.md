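# Methods

## The statistical model

The quantity tested, per biosample, is the overlap score k of an n-SNP input
set: the count of input SNPs whose genomic position lies inside the
biosample's annotation intervals.  The null hypothesis is that the input set
overlaps no more than an exchangeable SNP set would, where "exchangeable"
means: drawn from the same universe with the same profile of minor allele
frequency (MAF), distance to the nearest transcription start site (TSS) and
local GC content.  These three covariates jointly predict regulatory
annotation density, so an unmatched null would mistake covariate bias for
cell-type signal.

Exchangeability is operationalised by decile binning: each covariate is cut
at its empirical deciles over the whole universe (ties to the lower bin;
heavily tied covariates collapse onto fewer effective bins), giving every SNP
a key (maf_decile, tss_decile, gc_decile) in a 10×10×10 grid.  Background
sets are drawn per input SNP, uniformly from that SNP's bin.

The test itself is parameterised as follows.  With B background sets (default
1000) the pooled background overlap fraction

    p̂ = (Σ background overlaps) / (B · n)

estimates the null per-SNP overlap probability for the input's covariate
mixture, and the p-value is the exact upper binomial tail P(X ≥ k) for
X ~ Binomial(n, p̂).  This choice — rather than, say, an empirical rank
against the B background scores — keeps resolution below 1/B and is
validated by the calibration harness rather than by derivation: under
uniform-random inputs the marginal distribution of a random SNP's overlap
indicator, conditional on its bin, is exactly Bernoulli(bin mean), so the
binomial composite is the correct marginal null up to estimation noise in
p̂, and within-set covariate heterogeneity only lowers the true variance
below the binomial's (conservative).  The empirical Z-score
(k − mean(bg)) / sd(bg) (sample sd, denominator B−1) is reported alongside as
a distribution-free check.  Benjamini–Hochberg runs across all biosamples of
one run; q < 0.01 is the significance threshold.  Testing is one-sided:
depletion appears as z < 0 but is never flagged.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_background_sets` | 1000 | background sets per run; p̂ resolution is 1/(1000·n) |
| `r2_threshold` | 0.8 | greedy LD filter: keep first SNP, drop later SNPs at r² ≥ 0.8 with any retained SNP |
| `q_threshold` | 0.01 | BH q-value significance cut |
| `exclude_input_from_background` | true | input SNPs are removed from candidate pools |
| catalogue `min_snps` | 5 | minimum SNPs per phenotype in batch mode |

p̂ is floored at 1/(2·B·n) so an overlap observed with empty backgrounds can
never yield p = 0.

## Numerical choices

- **Binomial tail.**  Computed by direct pmf summation in log space
  (cumulative log binomial ratios, then a reverse `logaddexp` accumulation so
  the tail is summed smallest-terms-first).  No normal approximation.  This
  stays within ~3 × 10⁻¹³ relative of exact integer-arithmetic summation over
  the whole n ≤ 200 grid, including deep tails (~1e−283) where naive float
  term products underflow.
- **BH.**  Delegated to `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`) behind the package's `bh_adjust` surface, with input validation;
  the test suite checks it against a literal step-up implementation.
- **Clustering.**  `scipy.cluster.hierarchy.linkage` (complete linkage,
  Euclidean) on rows sorted lexicographically by label, so equal-distance
  merges break ties deterministically; checked against a naive O(n³)
  agglomeration loop.
- **Interval membership.**  Per-chromosome interval unions in sorted arrays
  with binary search; chromosome names match literally ("chr1" ≠ "1" unless
  `--strip-chr-prefix` is used at load).  SNP positions are matched as
  0-based points against 0-based half-open BED intervals (s ≤ pos < e).
- **Degenerate backgrounds.**  sd = 0 gives z = 0 if k equals the background
  mean, else ±inf with a `degenerate_background` flag.
- **Empty bins.**  If an input SNP's bin has no candidates (after input
  exclusion), sampling falls back one decile step — MAF first, then TSS,
  then GC, lower neighbour before upper — with a logged warning; if all six
  neighbours are empty, the run fails naming the bin.  Within one background
  set, draws inside a bin are without replacement whenever the bin holds at
  least as many candidates as input SNPs mapped to it, otherwise with
  replacement (warned).
- **Tie-breaking.**  Results sort by (q, −z, sample_id); per-phenotype batch
  seeds are `master_seed XOR crc32(label)` masked to 31 bits, so batch output
  is independent of phenotype order.

## Design choices made where the design was open

- Backgrounds are drawn **once per run** and shared across all biosamples,
  keeping per-sample results comparable and the run O(B·n) in sampling cost.
- Background SNPs drawn from the universe but absent from the database
  contribute zero overlap; in normal use universe and database are built from
  the same SNP table, so this path is inert.
- The batch matrix cell is −log₁₀(q) (0 where q ≥ 1), giving the clustering
  graded structure; row normalisation divides by the row maximum and keeps
  the maxima as a side vector.
- GC content is consumed as an input column (convention: GC fraction of a
  ±50 bp window, computed upstream), decoupling the engine from reference
  FASTA access.  TSS distance is unsigned; strand is ignored.
- Universe and track chromosome/position conventions, the TSV dialects, and
  the sqlite database layout (rsid-indexed bitstrings + sample metadata +
  versioned header) are documented in the module docstrings.

## What the synthetic generator emulates — and what it does not

`simulate_universe` draws MAF from a scaled Beta(0.8, 3) on (0.005, 0.5)
(decreasing density, as in population variant panels), TSS distance from a
60/40 mixture of exponentials (scale 5 kb near-TSS mass, 150 kb tail), and GC
from Beta(20.5, 29.5) (mean 0.41, the genomic average).  `simulate_tracks`
covers each SNP in each biosample independently with probability

    p = base_rate · exp(c₁ z(maf) + c₂ z(log1p tss) + c₃ z(gc)) / mean(·)

with defaults base_rate 0.1 and (c₁, c₂, c₃) = (0.5, −0.5, 0.5): common SNPs
near TSSs in GC-rich contexts are covered more often, the confounding pattern
decile matching exists to absorb.  A `SpikeSpec` multiplies one sample's
coverage probability (optionally restricted to a bin set) to plant true
signal.  Covered SNPs receive intervals of up to ±50 bp truncated at
neighbouring SNP positions, so every interval covers exactly its own SNP and
the Bernoulli draw matrix *is* the interval-overlap matrix — an exact oracle
for database construction — while decoy intervals exercise parsing of
intervals that cover nothing.

Deliberate non-realism: coverage is independent across biosamples and SNPs
(no LD between nearby SNPs, no correlated samples from shared cell lineages,
no broad multi-SNP peaks), interval lengths are not hotspot-like, and the
confounding is a smooth multiplicative model rather than the messier
empirical relationship.  Passing tests therefore show that the statistics are
calibrated and recover planted signal *under the assumed sampling model*;
they do not certify behaviour on real consortium tracks, where peak-width
structure and inter-sample correlation add dependence the binomial test does
not model (the paper-scale analogue of this caveat is why the empirical
false-positive harness exists at all).

## Problem sizes used in the shipped checks

The calibration harness simulates a 200,000-SNP universe across 22
chromosomes and 50 biosamples, and pushes 2,000 uniform-random input sets
(250 at each size in {5, 10, 15, 20, 30, 40, 50, 100}; 100,000 set–sample
tests, 1000 backgrounds each) through the full pipeline; the spike-recovery
checks use a 20,000-SNP, 10-sample study with 50 replicates per condition.
These sizes give tight Monte-Carlo resolution (a rate of a few per 100,000)
while keeping the whole suite comfortably runnable on a laptop core.

## Known limitations

- The binomial null ignores LD between input SNPs beyond the greedy r² prune;
  strongly clumped inputs should be pruned with a population-matched LD table.
- Background matching is marginal per SNP; the joint covariate distribution
  within a set is matched only through the per-SNP bins.
- p̂ is estimated, not known; at n·B below ~10³ its noise visibly widens the
  p-value distribution (still conservative in the shipped calibration).
- The sqlite store keeps bitstrings as text for portability, trading space
  for simplicity; very large track collections would warrant a packed binary
  column.
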