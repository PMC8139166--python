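# Methods

This document describes the statistical model behind each pipeline stage,
the parameters and their defaults, the design of the synthetic data
generator, the numerical choices, and the known limitations.

## Co-expression networks

For every vlincRNA–mRNA pair, expression profiles across samples are scored
by Spearman correlation. Ranks use midranks for ties; for n ≤ 9 untied
samples the two-sided p is computed by exhaustive permutation of one rank
vector, otherwise by the t-approximation
t = rho·sqrt((n−2)/(1−rho²)) with n−2 degrees of freedom. A constant series
yields an undefined correlation (reported as NaN and excluded). Edges
require |rho| > `rho_min` (default 0.35) and p < `p_max` (default 0.01);
the edge sign is the sign of rho.

Differential expression per drug: fold change against the mean of the
matched solvent-control samples at the same time point, with pseudocount
0.1 on both sides; a gene is called up (down) only if the fold change
exceeds 1.5 (falls below 1/1.5) at **both** the 3 h and 6 h time points.
Drugs with fewer than two time points are skipped with a warning; a missing
solvent control is an error naming the drug.

The negative-partner excess is a one-sided Wilcoxon signed-rank test of the
paired per-vlincRNA counts (negative vs positive partners); with all counts
tied the p is reported as 1 with a warning, and fewer than two vlincRNAs is
an error.

Expression stratification splits expressed mRNAs (maximum abundance > 0)
into halves by their maximum abundance, descending; an odd count puts the
extra gene in the top half.

## Proximity (RAT) region calling

Tracks are per-base scores keyed by chromosome. Processing per track:

1. **Normalize** by total reads (depth correction).
2. **Subtract** the matching no-oligo control track; negative values are
   retained — truncation would bias the genome-wide ranking.
3. **Region calling** per replica at percentile `pct`: keep bases whose
   score is > 0 in **both** oligo tracks of the replica; rank the surviving
   scores of the scoring track genome-wide; keep the top
   k = ceil(pct/100 · n) bases, where n is the number of surviving bases,
   with all ties at the k-th largest value kept; merge adjacent kept bases
   into half-open regions.
4. **Gene sets**: at *gene level* a gene qualifies if it overlaps at least
   one region in each replica; at *region level* the base-wise intersection
   of the two replicas' regions must be non-empty within the gene.

Keeping ties makes the kept base sets nested across percentiles
(1 ⊆ 5 ⊆ 10 ⊆ 20 ⊆ 30), which propagates to nested gene sets and makes the
stringency sweep monotone by construction. Replica concordance is the odds
ratio and one-sided hypergeometric p of the two replicas' gene sets over
the gene universe.

## Metagene (ANARS) profiles

Each gene body is scaled to 5,000 positions by slice means: position i
averages the bases in the i-th of 5,000 equal slices; an empty slice (gene
shorter than 5,000 bases) takes the value of the base containing the
slice's midpoint. Slice means preserve total signal mass up to rounding,
unlike interpolation. The 5-kb flanks are unscaled; body and flanks are
orientated 5′→3′ by gene strand; flank positions outside the chromosome are
zero. A group profile is the per-position mean over its genes.

The enrichment test ranks each group's profile values independently, takes
the top 30 % of each (k = max(1, round(0.3·n))), and applies a one-sided
Wilcoxon rank-sum test (group A > group B): exact when both sides have
< 50 values and share no value, otherwise the normal approximation with tie
correction. The cis-vs-all comparison drops zero values from both sides
first and is skipped with a warning if either side becomes empty.

## Network validation

Co-expressed genes of each sign are split by expression half and overlapped
with the RAT gene sets at every percentile and level via a 2×2 table over
the expressed-gene universe: odds ratio (a·d)/(b·c) with the
Haldane–Anscombe 0.5 correction to all cells when any cell is zero, and a
one-sided hypergeometric enrichment p, P(X ≥ a) with
X ~ Hypergeom(N, a+b, a+c). The designated groups — negative network in the
top expression half, positive network in the bottom half — pick the final
percentile per sign: lowest gene-level p, ties and the all-p-equal-1
fallback resolving to the strictest percentile (flagged). The validated
network is the full co-expressed sign group intersected with the RAT genes
at the chosen threshold. Stability across treatments reports the shared
fraction (|intersection| / |smaller set|), odds ratio and hypergeometric p;
the cis/trans comparison recomputes the overlap odds ratio restricted to
the vlincRNA's chromosome and compares cis vs genome-wide odds ratios
across samples with a rank-sum test.

## Knockdown quantification

Input tables carry FPKM columns T0, T3, T6 (targeting arm) and NT0, NT3,
NT6 (mismatch-control arm). Genes with any value > 1 FPKM (strict) are
kept. With pseudocount 0.01 added to **every** value:

- FC_Td = T_d / (T_d + T_0), and likewise FC_NTd — bounded in (0, 1);
- RFC_Td = FC_Td / (FC_Td + FC_NTd);
- RFC_T36 = (RFC_T3 + RFC_T6) / 2.

Adding the same pseudocount to every value preserves the structural
identities exactly in floating point: T_d = T_0 gives FC = 0.5, and equal
targeting and control arms give RFC = 0.5, because both reduce to
x/(x+x). Genes are grouped by their correlation with the targeted vlincRNA
(network positive/negative past the thresholds, ordered by strength;
background by sign of rho, optionally requiring p > p_max). Effects are
the difference of medians, Cohen's d (pooled SD) and one-sided rank-sum p
of negative > positive RFC, at all/top-100/top-50/background granularity,
pooling day 3 and day 6 or per day. Groups with fewer than 3 genes report
missing statistics.

## Survival screen

Pooled gRNA counts are normalized to per-(condition, replicate) fractions.
For each targeting/control pair and condition the ratio of fractions is
computed per replicate and averaged; replicates with a zero control
fraction are dropped and flagged, and a pair-condition with no usable
replicate reports a missing ratio. Conditions are compared with a one-sided
paired t-test over pairs (ratio higher in A than B); fewer than two
complete pairs is an error.

## Synthetic data generator

The generator is seeded once; each stage draws from an independent child
stream (`SeedSequence([seed, stream])`, streams 0–5 for annotation, ground
truth, expression, chromatin, knockdown, survival), so changing one stage's
parameters never perturbs another stage's draws.

**Layout.** Genes occupy fixed slots (`gene_length` + `spacer`) per
chromosome; vlincRNAs are appended after the gene block round-robin. An
explicit chromosome length too small for the layout is rejected.

**Expression.** For a planted pair with target Spearman rho_s, the
vlincRNA and target load on a shared standard-normal factor with loading
sqrt(rho_p), where rho_p = 2·sin(π·rho_s/6) is the Pearson correlation of
the Gaussian copula whose population Spearman equals rho_s exactly.
Negative targets flip the sign. Latents become abundances via
base·exp(noise_sd·z) with lognormal base levels — a strictly increasing
transform, so the planted rank correlation survives untouched. A small set
of non-network genes receives per-drug fold effects so the
differential-expression caller has structure to find.

**Chromatin.** Background coverage is Poisson at `rat_background_rate`
(default 20 per base, after which normalization makes scores
quasi-continuous). The default rate is set high enough that subtracted
scores are effectively tie-free: at low rates the subtracted scores
collapse onto a small integer lattice, massive ties make the percentile
cut keep far more than pct % of bases, and the stringency sweep loses its
meaning. Enrichment multiplies the rate by `chromatin_enrichment` over the
target gene bodies **plus** a 5-kb flank on each side (`chromatin_flank`),
matching the expectation that chromatin contact extends beyond annotated
boundaries — without flank signal the metagene flank comparison would have
nothing to find. The default `spacer` (6 kb) exceeds the flank so planted
signal never bleeds into a neighboring gene body and the planted gene sets
stay exact. For speed, the whole genome is drawn at the scalar background
rate and the merged enriched spans are then redrawn at the enriched rate —
distributionally identical to an inhomogeneous per-base draw and
deterministic given the stream.

**Knockdown.** Targeting-arm day-3/day-6 values shift negatively
co-expressed genes up by (1 + effect) and positively co-expressed genes
down by (1 − effect); the vlincRNA itself is depleted; both arms carry
mean-corrected lognormal noise.

**Survival.** Each condition carries a multiplicative depletion of the
targeting guides with mean-one lognormal replicate noise; counts are
Poisson at the configured depth.

## Numerical and I/O choices

- All iteration over dictionaries and sets is sorted before any draw or
  write, and the output manifest excludes the output directory path, so a
  full pipeline run is byte-deterministic given the config.
- bedGraph output omits zero runs; reading validates sorted, non-overlapping
  intervals and reports the offending line number, as does BED parsing.
- JSON output is sorted and newline-terminated.
- Exact tests are used where cheap (permutation Spearman p at n ≤ 9, exact
  rank-sum below 50 untied values); otherwise standard asymptotics with tie
  corrections.

## Limitations

- **The top-30 % metagene test is anti-conservative under the null.**
  Selecting the top 30 % of each profile independently before the rank-sum
  test invalidates its null distribution: each group's block sits above its
  own sample's 70th percentile, which fluctuates between samples, so the
  statistic is overdispersed and null p-values pile up in both tails. On
  pure iid N(0,1) profiles of length 5,000 this measures KS D = 0.16
  (p ≈ 5e-23 over 1,000 replicates) against the uniform, and D = 0.15 at
  length 500; the identical rank-sum without the selection step is
  calibrated (KS p = 0.82). Significance thresholds applied to this test
  are therefore optimistic; the planted-enrichment detections reported by
  the package are far below any plausible corrected threshold (p ≈ 0 at 3×
  enrichment), but borderline p-values should not be taken at face value.
  The acceptance suite keeps an intentionally failing assertion of null
  uniformity as a record of this property.
- One-sided hypergeometric p-values are discrete; with small universes they
  are super-uniform (conservative) by up to the largest point mass.
- The differential-expression caller with one sample per (drug, time point)
  is a pure fold-change filter; at the generator's default noise level most
  calls are noise. It reports what the data support; replication is the
  remedy, not the caller.
- The generator plants disjoint target sets across vlincRNAs and
  homogeneous Poisson chromatin backgrounds; real assays have shared
  targets, mappability structure and overdispersion that the synthetic
  calibration cannot capture.
- The signed-rank test for negative-partner excess is meaningful only with
  a population of vlincRNAs; at the default two vlincRNAs it has
  essentially no power.
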