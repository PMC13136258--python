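# Methods

This note records the statistical definitions the package implements,
the choices made where the conventions were genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## Phenotypic diversity

Per-trait statistics use the sample standard deviation (n−1
denominator) throughout; CV = σ/μ × 100 is undefined (reported NaN with
a warning) when the mean is zero. The seven-level classification bins a
value by its distance from the trait mean in residual-SD units, with cut
points μ ± 0.5σ, μ ± 1.5σ, μ ± 2.5σ. All intervals are half-open and
lower-closed; the bottom level is unbounded below and the top level is
closed at μ + 2.5σ (x ≥ μ + 2.5σ). The Shannon–Wiener index
H′ = −Σ Pᵢ ln Pᵢ is computed in nats over the level frequencies, with
0·ln 0 := 0, and is therefore bounded by ln 7 ≈ 1.946 for any
quantitative trait. Published germplasm tables sometimes print H′
values above this bound for seven-level data; such values cannot arise
from this binning, and the test suite records the inconsistency as an
expected failure rather than altering the bin count.

Qualitative traits keep their descriptor-standard integer codes exactly
as printed, including non-contiguous code sets; H′ comes from the code
frequencies. A CV is also reported for coded traits because summary
tables conventionally include one, but it is σ/μ on the arbitrary
coding scale and should not be compared across recodings.

When accessions are phenotyped over multiple years, the diversity and
multivariate stages consume per-accession across-year means; the ANOVA
consumes the replicate-level records. The two-way Year × Variety ANOVA
is fixed-effects with interaction. On balanced data the sums of squares
come from the exact cell-mean decomposition (so SS_total equals the sum
of the parts to machine precision); unbalanced input triggers a warning
and sequential (type-I) SS in Year, Variety, interaction order via an
OLS fit. F is always MS_source/MS_error; a design without within-cell
replication cannot estimate the interaction and is rejected with
guidance. Correlation p-values are raw two-sided t-tests
(pairwise-complete observations, minimum three per pair) with a
three-level star display; no multiplicity correction is applied.

## Composite evaluation (PCA)

All traits — qualitative codes included, numerically — are Z-scored and
the PCA is the eigendecomposition of the trait correlation matrix, the
appropriate choice when units are mixed across traits. Components with
eigenvalue > 1 are retained (at least one is always kept). Loadings are
eigenvectors scaled by √λ; communalities are sums of squared retained
loadings. Component scores are standardized to unit sample variance,
matching the common statistical-package default for factor scores; this
is the main dialect choice the composite-score convention leaves open,
and it makes F a weighted sum of unit-variance components. Because a
component's sign is arbitrary, each is oriented so its largest-|loading|
trait loads positively; published loading tables may need a sign flip
for comparison. Weights are Wᵢ = cᵢ/Σⱼ≤ₖ cⱼ (summing to 1), the score is
F = Σ Wᵢ Fᵢ, ranks break ties lexicographically by accession id, and
elite screening supports both the F > 1.00 threshold and top-N modes.
Missing cells are mean-imputed before PCA with a warning.

With k independent unit-variance scores, F ~ N(0, Σ Wᵢ²); under the
nine-component weight profile Σ Wᵢ² ≈ 0.164, so the expected F > 1 elite
fraction of an unstructured panel is Φ̄(1/0.405) ≈ 0.7%. Larger elite
fractions indicate real multivariate structure.

## Clustering

Accessions are clustered on Z-scored traits with Euclidean distance and
complete linkage (farthest neighbour); Ward is exposed as an option for
comparison where a source describes both. scipy's agglomeration
resolves equal-distance merges deterministically by cluster index, so
results are platform-stable. Cutting at k labels clusters 1..k in order
of first appearance. Group comparisons use pairwise Welch t-tests per
trait at α = 0.01 with a greedy compact-letter display; singleton
groups are reported but not tested.

## Population genetics

Per-locus, per-population inputs are the alt-allele frequency p, the
called diploid count n and the observed heterozygote fraction, all over
called genotypes only. Diversity indices per locus: He = 2pq,
Ne = 1/(p² + q²), I = −p ln p − q ln q, and the small-sample-corrected
gene diversity (2n/(2n−1))·He, reported both as `nei_unbiased` and as
the per-variant-site nucleotide diversity π (identical for biallelic
SNPs; a genome-wide per-bp π would need invariant-site counts, which a
filtered SNP matrix does not carry). Statistics are averaged across
post-filter variant sites; F_IS = 1 − mean(Ho)/mean(He) within each
subpopulation, F_IT = 1 − mean(Ho)/mean(He_total) against pooled-panel
frequencies. The summary "Average" row is the unweighted mean of the
subpopulation rows.

Pairwise F_ST is the Weir & Cockerham (1984) estimator: per-locus
variance components a (among populations), b (among individuals within
populations) and c (within individuals), combined across loci as
Σa / Σ(a+b+c) — the weighted "ratio of sums" convention. Negative
estimates (expected noise around zero differentiation) are reported as
computed, with an optional floor at zero.

The p-distance between individuals is the allele-sharing distance on
dosages, mean |gᵢ − gⱼ|/2 over loci called in both; unphased VCFs do not
support a haplotype-level distance. Neighbor joining is the Saitou–Nei
algorithm with the Q-criterion and standard two-point branch lengths;
ties resolve to the lexicographically smallest active pair, negative
branch lengths are kept, and the output is exact on additive matrices
(verified against an independent patristic-distance oracle and
dendropy's NJ). Genotype PCA eigendecomposes the GCTA-style GRM
(dosages centered at 2p, scaled by √(2p(1−p)), missing imputed at the
locus mean, monomorphic loci skipped).

VCF ingestion applies the filters in a fixed order: per-genotype depth
mask (DP < 3 ⇒ missing, matching a per-sample reading of the depth
rule), then per-locus missingness (> 0.1 dropped), then MAF on the
remaining calls (< 0.05 dropped; ties at the threshold kept).
Multiallelic records, non-SNP alleles and half-missing genotypes (./1)
are removed/masked up front; phased and unphased calls are equivalent.
The filter log's per-rule counts always reconcile with records in/out.

## Synthetic data

The phenotype generator emulates a germplasm trial: G latent groups
(default 6 × 35 accessions ≈ the 209-accession scale of the motivating
design), 20 traits, two years with 3 replicate measurements, a 1-SD
year main effect, genotype × year interaction draws (SD 0.3) and unit
Gaussian residuals. Group centers sit on orthonormal random directions
scaled so every pair of centers is exactly `group_separation` (default
6) residual SDs apart; spreading the signal over all traits keeps the
separation intact under per-trait standardization. The generator does
not emulate skewed or heavy-tailed trait distributions, trait-specific
error variances, or missing phenotypes — so passing tests show the
estimators are correct under the assumed Gaussian mixed structure, not
that real trials satisfy it.

The genotype generator draws ancestral frequencies Uniform(0.05, 0.95),
subpopulation frequencies from the Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) law (variance F·p(1−p), so pairwise
Weir–Cockerham estimates recover F), and genotypes at the
partial-selfing inbreeding equilibrium f = s/(2−s) with
P(het) = 2pq(1−f). Defaults (6 subpopulations × 30 samples, 2000 loci,
F = 0.08, s = 0.63 ⇒ f = 0.46) match the differentiation and inbreeding
scale of a predominantly selfing vegetable panel. Linkage, recombination
history, genotyping-error models beyond uniform missingness, and
admixture gradients are not simulated; Balding–Nichols is a structural
stand-in, not a demographic claim.

## Numerical choices and problem sizes

Frequency tolerances: Shannon inputs must sum to 1 within 1e-9;
F_IS/F_IT identities hold to 1e-12 by construction; NJ additivity is
checked at 1e-9. Degenerate inputs: σ = 0 traits bin everything into
level 4 with a warning; zero-variance columns are dropped before
standardization; fixed loci make F_IS undefined (NaN). Recovery
experiments in the test and acceptance suites use 20 seeds of
6 × 30 × 2000-locus panels for F_ST (|bias| ≤ 0.02), 20 seeds of
3 × 30 × 1000 for F_IS (|bias| ≤ 0.03), 1000 null replicates of the
2 × 20 × 3 ANOVA layout (type-I rate within [0.036, 0.064] per source),
and 20 seeds of the default phenotype panel for clustering recovery
(adjusted Rand ≥ 0.95); these sizes give tight Monte-Carlo error while
keeping the whole suite around ten seconds on one core.

## Known limitations

Qualitative-trait CV is scale-dependent (see above). The composite
score's absolute F > 1.00 threshold is only meaningful on standardized
scores; panels with little multivariate structure may screen zero
accessions. The ANOVA's unbalanced path is sequential type-I and
order-dependent, as documented, rather than type-III. Per-bp nucleotide
diversity and admixture-model structure inference are out of scope; the
package exports the genotype matrix and PCs that such tools consume.
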