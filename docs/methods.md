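# Methods

This note documents the models, estimators and numerical conventions behind
`hapscan`, the assumptions they rest on, and the design decisions taken where
the underlying procedures are usually done by eye or left unspecified.

## Coordinate and data model

All internal coordinates are 0-based half-open (BED convention); VCF and
BEAGLE positions (1-based) are converted at the I/O boundary, so a site at
1-based position `w·width` belongs to window `w−1`.  Genotype likelihood
triples (hom-major, het, hom-minor) are normalized to probabilities at read
time; all-zero or malformed triples become missing.  The working
representation downstream is the posterior expected minor-allele dosage in
[0, 2].  The dosage prior is uniform over the three genotypes by default; a
Hardy–Weinberg prior at a supplied per-site frequency is available.  Uniform
is the most neutral reproducible choice when no frequency estimate exists
yet, and the two priors converge as depth grows.

## The synthetic study

The generator reproduces the statistical structure of a multi-population,
low-coverage resequencing study; its defaults are the package's reference
study conditions and are used unchanged by the test suite and acceptance
script.

* **Populations.** 8 populations × 25 diploids.  Neutral allele frequencies
  follow a Balding–Nichols model: ancestral p ~ U(0.05, 0.95) per site
  (mimicking SNP ascertainment with a minor-allele-frequency floor), and
  population j draws from Beta with mean p and variance F_j·p(1−p), with
  F_j spaced evenly in (0, F_max].  F_max defaults to 0.05: with evenly
  spaced F the expected pairwise F_ST is ≈ F̄ ≈ 0.027, the differentiation
  scale typical of recently expanded, highly connected plant populations of
  the kind this pipeline targets.
* **The inversion.** One planted inversion (2.0–3.0 Mb of a 5-Mb contig,
  i.e. windows 20–29 of fifty 100-kb windows; 100 sites per window).  Its
  two arrangements A and B differ at a random fraction *d* (default 0.3) of
  inversion sites, which are fixed differences (|q_A − q_B| = 1); the
  remaining sites are shared polymorphism at the background frequency.  The
  expected per-site arrangement frequency difference therefore equals *d*
  exactly, d = 1 gives fixed differences everywhere, and d = 0 removes the
  signal entirely.  This diagnostic-site mixture mirrors how old inversions
  actually look (a backbone of arrangement-diagnostic SNPs embedded in
  shared variation) and is what produces the three-cluster PCA and the
  LD-contrast signatures jointly.  There is no recombination between
  arrangements: sites are drawn independently given the arrangement, so all
  inversion-region LD flows through arrangement dosage and collapses within
  homozygotes — the signature the LD validation step tests.
* **The cline.** Arrangement-B frequency in population j is
  logistic(β0 + β1·env_j) with env evenly spaced on [−1, 1]; the defaults
  β0 = 0, β1 = log(4) ≈ 1.386 give a 0.2 → 0.8 cline across the gradient.
  Optional environment-cline regions impose
  freq = logistic(logit(p) + β1·env) on ordinary sites, for
  environment-association power studies.
* **Sequencing.** Depth ~ Poisson(c) per sample × site (c defaults to 4;
  1 reproduces a very-low-coverage design), minor-allele reads ~
  Binomial(depth, ψ) with ψ = (g/2)(1−ε) + (1−g/2)ε and ε = 0.005
  (a post-quality-filter error rate); genotype likelihoods are the binomial
  read likelihoods; depth 0 is missing.  Optional lognormal per-sample
  coverage multipliers exercise the 0.4× coverage filter.

What the generator does **not** emulate: linkage between ordinary sites
(background LD beyond population structure), recombination gradients at
inversion breakpoints, mutation-rate or coverage heterogeneity along the
genome, batch effects, and reference bias.  Passing tests therefore
demonstrate that the estimators and the discovery logic are correct under
the model's assumptions, not that real data meet those assumptions.

## Haploblock discovery

Window covariances use mean-imputed, site-centered dosages:
C = X_cX_cᵀ/(m−1), trace-normalized, over windows with ≥ 10 polymorphic
sites.  Mean imputation keeps the covariance well defined at low coverage
without inventing genotypes.  Between-window distance is the Frobenius norm
between rank-k approximations of the normalized covariances, k = 2: one axis
captures a three-genotype haploblock, the second tolerates superimposed
global structure.  Classical (Torgerson) MDS embeds the distance matrix on
five axes; axes with non-positive eigenvalues are zero-filled and flagged;
each axis's sign is fixed by making its largest-|coordinate| window
positive.

**Corner outliers.**  For each pair of axes, coordinates are rescaled by the
per-axis max |coordinate| and the ceil(0.05·n) windows with the largest
projection onto each of the four diagonal directions (±1, ±1)/√2 are
labeled (a window may carry several labels).  A three-corner variant
(triangle vertices at 120°) is available as an option.

**Clustering into candidate regions.**  A haploblock manifests as a stretch
of windows jointly extreme in the *same direction* along one MDS axis, while
any single 5% corner holds only ceil(0.05·n) windows — fewer than a typical
haploblock span — so clustering strictly within corner labels fragments the
region.  The default mode therefore pools corner labels per (axis, side),
keeping only windows whose coordinate on that axis has the matching sign and
a magnitude of at least half the axis maximum.  The sign requirement removes
windows that entered a corner through the *other* axis of the pair; the
half-max guard removes continuum noise, exploiting the bimodal geometry a
real haploblock produces (a tight extreme clump versus a background clump
across the centroid).  Pooled windows are merged into runs tolerating gaps
of ≤ 2 windows, runs with ≥ 3 outlier windows become regions, and
overlapping regions from different labels are merged into a union region
that records all contributing labels.  A strict per-(pair, corner) mode is
retained for comparison.  Both `min_run` and `max_gap` are exposed: the
original procedure selected clustered regions by eye, and these two
parameters are the smallest sufficient formalization.  A known limitation of
the half-max guard: two haploblocks of very different strength loading the
same side of the same axis would suppress the weaker one; in practice
distinct haploblocks dominate distinct axes.

## Genotyping and validation

Samples below 0.4× mean depth are excluded (inclusive boundary: exactly
0.4× is retained).  Without a depth table, a declared fraction-of-missing
proxy must be supplied explicitly; the filter refuses to guess.

Region PCA uses mean-imputed centered dosages over region sites with pooled
MAF ≥ 0.05.  Genotypes come from 1-D three-component Gaussian mixtures
(shared variance, means initialized at the 10th/50th/90th percentiles,
200 EM iterations, tolerance 1e−8, fixed seed) fit on each of the first two
axes; the axis where the three-component fit beats the one- and
two-component fits by BIC is used.  Components are ordered by mean, the
outer two are homozygotes, and samples with maximum posterior < 0.9 are set
to missing; "a" denotes the arrangement of the larger homozygote cluster.
The mixture replaces the manual cluster assignment of the original
procedure; every threshold is exposed.  Labels are invariant to the
arbitrary PCA axis sign because polarity is re-anchored to cluster sizes.

Heterozygosity per sample is the mean posterior heterozygote probability
over region sites under an HWE prior at the pooled frequency.  The two
validation tests are one-sided Wilcoxon rank-sum tests (ab > aa, ab > bb),
exact when both groups have ≤ 25 members and no ties, normal approximation
with continuity correction otherwise; fully tied data return p = 0.5.

LD validation samples up to 5,000 MAF-filtered sites per chromosome (seeded,
no distance cap) and computes squared Pearson correlations of dosages for
(i) a random sample subset and (ii) the major-homozygote subset of the same
size.  The summary is the ratio of within-region mean r²:
`ld_ratio = mean_i / mean_ii` (the mean was chosen over the median or block
extent as the simplest summary of the genotype-driven excess); the flank
background is the mean r² over pairs fully outside the region.  A region is
accepted as a haploblock iff three clusters were found with ≥ 3 samples
each, both heterozygosity p-values fall below α = 0.05, and ld_ratio > 2.
α is deliberately a conventional threshold rather than the far smaller
p-values a strong haploblock actually produces; reason codes record every
failed criterion.

## Selection and environment-association scans

Standardized frequencies use x = (p − π̂)/√(π̂(1−π̂)) with π̂ the
sample-size-weighted mean across populations (or the true ancestral
frequency, when a simulation supplies it).  Ω is estimated from ≥ 100
control sites with weighted mean frequency strictly inside (0.05, 0.95) as
the moment matrix (1/L)Σxxᵀ, shrunk toward its diagonal by λ = 0.05 —
enough to restore invertibility when populations are few or highly
correlated while leaving the structure essentially untouched.  These are
deterministic moment analogues of the Bayesian covariance-corrected scan
statistics; identical contracts, no claim of numerical parity with MCMC
implementations.

For the Balding–Nichols generator the model Ω is diagonal with entries
F_j/(1−F_j) + 1/n (the (1−F) factor corresponds to standardizing by the
expected within-population heterozygosity π(1−π)(1−F); 1/n is binomial
sampling noise from n sampled chromosomes).  With this Ω the neutral mean
of XtX is Σ(1−F_j) ≈ n_pops and its upper tail tracks χ²_{n_pops} to within
the tolerance the tests assert; the naive diag(F) scale passes the mean but
inflates the 1% tail beyond 1.5% through the Beta skew at ancestral
frequencies near the 0.05 boundary.

Kendall τ_b is computed vectorized over sites by signed pair enumeration
with the standard tie correction (verified against scipy per site).
Empirical p-values are upper-tail ranks with average ties: p = rank-from-top
/(n+1), so the maximum of n values gets 1/(n+1) and p never touches 0 or 1.
WZA scores clamp p to [1/(2n), 1 − 1/(2n)] before Φ⁻¹ to avoid infinite
quantiles at the extreme ranks, and weight sites by q̄(1−q̄), the expected
heterozygosity weighting of the weighted-Z approach.  Outlier windows are
the top ceil(0.01·n) per statistic with boundary ties included; the XtX-EAA
flag marks windows that are XtX outliers and outliers for at least one
environment variable.

## Enrichment, clines, fitness, expression null

Hypergeometric overlap tests are computed in log space via the survival
function; windows overlapping a haploblock by any amount count as haploblock
windows.  Haploblock clines regress individual arrangement frequency
(aa = 0, ab = 0.5, bb = 1, so population means equal allele frequencies) on
latitude per range by OLS; fits with no residual degrees of freedom report a
missing p.  Relative fitness divides each individual's seed mass by the mean
of the best genotype within the same garden, so exactly one genotype per
garden attains mean 1.  The differential-expression null preserves synteny
by resampling contiguous runs of exactly g genes in genome order, confined
to single chromosomes, with starts uniform over all valid starts
genome-wide; per draw it records the FDR < 0.1 count and the mean |log2FC|,
and empirical p is the inclusive add-one form (1 + #{null ≥ obs})/(1 + B),
which can never be zero.  An exhaustive-start mode enumerates every valid
run for deterministic verification.  Where several haploblocks exist the
null is computed per haploblock separately.  GWAS-hit DE percentages are
rounded half-up to one decimal, matching how such fractions are reported.

## Numerical conventions and degenerate inputs

Frequency EM iterates p ← mean posterior dosage/2 under HWE from a naive
uniform-prior start, tolerance 1e−8, ≤ 100 iterations; sites whose GL
triples are all uninformative are flagged rather than silently converged.
Per-site Hudson numerators are kept unclamped (the ratio-of-averages
estimator is only unbiased without clamping).  Tajima's D returns missing
when S = 0.  Polymorphism checks use absolute tolerances (1e−9 on dosage
standard deviations) to absorb floating-point crumbs in constant columns.
Windows with degenerate covariance are skipped with a recorded reason;
degenerate MDS axis pairs are skipped with a warning; the `--max_kb_dist 0`
convention of LD tools is read as "no distance limit".  Problem sizes in the
tests and acceptance script (50 windows × 100 sites for recovery; 50,000
sites for null calibration; 20 replicates × 100 windows for power) were
chosen as the smallest designs at which each property is statistically
crisp.

## Known limitations

Breakpoints are resolved only to window resolution; inversions are not
distinguished from other rearrangements that suppress recombination; the
scan statistics' χ² calibration assumes the drift regime is moderate
(Gaussian-like frequency deviations) and degrades toward fixation; and the
LD ratio assumes enough major-arrangement homozygotes for an equal-size
comparison set — regions where one arrangement is rare return missing LD
evidence rather than a noisy ratio.
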