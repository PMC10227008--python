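# Methods

This note records what `pgcmasc` computes, the modelling assumptions, and the
numerical choices.  All defaults named here are package design decisions,
chosen to represent a typical prenatal-exposure PGC study at desk scale.

## Study design and data model

A study is a count matrix (genes × samples) with per-sample metadata:
`generation` ∈ {F1, F2, F3}, `sex` ∈ {M, F}, and `dose` ∈
{0, 0.033, 0.2, 2} (µg/kg/day-style dose labels; 0 is vehicle).  Counts are
modelled as negative binomial (NB) with gene-wise mean µ_gj proportional to
an effective library size and a gene dispersion φ_g, so that
Var = µ + φµ².

## TMM normalization (`pgcmasc.tmm`)

Between-sample scaling factors follow the trimmed mean of M-values.  The
reference sample is the one whose 75th-percentile counts-per-million is
closest to the mean such percentile (ties break by column order).  For each
sample against the reference, genes with a zero in either sample are
dropped; per-gene log-ratios M, average log-abundances A, and delta-method
variances

    M = log2((obs/N_obs)/(ref/N_ref))
    A = 0.5*log2((obs/N_obs)*(ref/N_ref))
    var = (N_obs-obs)/(N_obs*obs) + (N_ref-ref)/(N_ref*ref)

are computed; the most extreme 30% of M and 5% of A are trimmed from each
tail by average rank, and the factor is 2 to the inverse-variance-weighted
mean of the surviving M values.  Fewer than 10 surviving genes yields a
factor of 1 with a warning.  Factors are rescaled to geometric mean one;
effective library size = raw library size × factor.  CPM values add a
pseudo-count of 0.5 scaled to each sample's relative effective depth.

## Differential expression (`pgcmasc.diffexpr`)

Dispersions: a per-gene method-of-moments estimate from pooled within-group
variances on the normalized scale, floored at zero, is shrunk toward a
common dispersion with weight n0/(n0 + residual df), n0 = 10.  The common
value maximizes a Cox–Reid adjusted profile likelihood (the adjustment term
is half the log of the summed working weights per group); unadjusted
profile likelihood and the median of the raw estimates are both noticeably
biased low at small group sizes, which inflates type-I error.

Testing: an NB generalized linear model with log link and
log-effective-library-size offset is fitted by iteratively reweighted least
squares, batched across genes for a shared design (working weights
w = µ/(1+φµ), a 1e-10 ridge on the normal equations, linear predictor
clipped to ±30).  For φ below 1e-8 the Poisson likelihood is used.  The
likelihood-ratio statistic between nested designs is referred to a χ²
distribution; non-converged genes get p = 1 with a warning.
Benjamini–Hochberg adjustment uses the standard step-up with enforced
monotonicity and a stable sort.

Sex-specific genes are called on vehicle samples pooled across generations:
FDR < 0.05 and |log2FC| > 1 with a male-positive sign convention; the two
sets are disjoint by construction.  Exposure rankings compare one sex at
one or more pooled doses against vehicle, ordering genes by ascending
p-value with deterministic tie-breaks (descending |log2FC|, then gene id).

## Enrichment against a permutation null (`pgcmasc.enrichment`)

The expressed universe is the set of genes whose maximum raw count across
samples strictly exceeds 100.  Both the ranked exposure list and the
sex-specific sets are intersected with the universe before any counting.
The enrichment curve reports, for k = 1..200, the fraction of the top-k
exposure genes that are male- (or female-) specific.

The null distribution of that fraction is built literally: s genes are
drawn without replacement from the universe 5000 times (s ∈ {50, 100, 200})
and the sex-specific fraction recorded.  A gamma distribution is fitted to
the draws by moment matching (shape = m²/v, rate = m/v with the unbiased
variance); its 95% quantile is the flag threshold at each k, using the null
whose s is nearest to k.  Degenerate nulls (zero variance) fall back to the
empirical quantile.  "Sustained" enrichment means flagged at every
k in 1..50.  The marginal null is exactly hypergeometric, which the test
suite exploits as an independent oracle; note the continuous gamma fit
slightly overestimates the far tail of the discrete null at s = 50.

## Repeat methylome (`pgcmasc.repeats`, `pgcmasc.io`)

Bismark coverage files (1-based) are converted to 0-based positions, with
the percentage field cross-checked against the counts (0.5-point
tolerance) and zero-coverage records dropped.  Repeat annotations are
BED-like half-open intervals with a family → class map (IAP, LINE-1, B1–B4,
other).  CpGs are assigned to repeat loci via an interval tree; a CpG in
overlapping loci is counted in each, and unannotated CpGs fall into a
"non-repeat" bin.  All methylation summaries are pooled-read weighted:
Σ methylated reads / Σ total reads, never a mean of per-CpG fractions.
Rankings report the top 35 families by CpG coverage or by weighted
methylation (families with ≥ 50 interrogated CpGs), with per-locus
distributions (quartiles) and fixed-width windowed tracks available.

## Synthetic data (`pgcmasc.simulate`)

Transcriptome: 15,423 genes by default, 3 replicates per
generation × sex × dose cell (72 samples).  Baseline means are lognormal
(σ = 2) with the location chosen in closed form so that the expected
expressed-universe size is 3100 genes; because the universe criterion is a
maximum over 72 NB draws, the quantile is matched at an effective threshold
of 0.36 × 100 counts, calibrated once against the realized universe size.
150 male- and 150 female-specific genes are placed in the
top-3100-expression pool (base rate ≈ 4.8% of the universe) and receive a
symmetric ±sex_log2fc/2 shift (default total 1.5).  Library sizes are
lognormal (σ = 0.2); dispersions are Gamma(shape 2, rate 10), mean 0.2.
The masculinization effect adds `masc_effect` log2 units to a
`masc_fraction` (default 0.5) of the male-specific genes in exposed
(dose > 0) female samples only; the default `masc_effect` is 0 (no effect)
so null data are the default.

Methylome: non-overlapping loci for four families (IAP-like 0.80,
LINE1-like 0.25, two SINE-like at 0.05 true methylation), CpGs every 20 bp,
Poisson read depth (mean 20, zero-depth CpGs dropped), binomial methylated
reads around a per-locus truth with Gaussian noise (sd 0.02).  Under
exposure, a configured fraction of a family's loci shifts by a configured
amount.

## Pipeline and determinism (`pgcmasc.pipeline`, `pgcmasc.cli`)

Stages (simulate, normalize, deg, enrich, repeats) receive independent
child seeds from a `SeedSequence` spawned off the study seed (reduced
mod 2³¹).  All tables are written with a fixed float format (`%.10g`), so
identical config + seed reproduces every output byte-for-byte.  Failures
write a `FAILED` marker naming the stage.

## Limitations

The generator draws genes independently (no correlation structure, no
composition effects beyond library size), uses a single dispersion per gene
across conditions, and plants exposure effects only in the configured gene
sets; real data violate all three.  The enrichment flags are marginal per-k
decisions against a 95% null quantile — the curve is cumulative, so flags
at neighbouring k are strongly dependent and the per-k flag rate is not a
family-wise error rate.  The gamma null summary is an approximation to a
discrete hypergeometric law and is least accurate for small s and extreme
tails.  The NB GLM uses a fixed (shrunken) dispersion per gene rather than
re-estimating under each hypothesis.
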