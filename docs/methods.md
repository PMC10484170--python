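# Methods

This note documents the models implemented in `specsel`, the
conventions and tunable parameters that matter, what the synthetic-data
generators do and do not emulate, and the design choices made where the
design was genuinely open.

## Selection statistics

### Nei–Gojobori dN/dS (`codon_evolution`)

Site counting follows the unweighted-pathway NG86 scheme under the
standard nuclear genetic code. Each position of a sense codon
contributes a synonymous fraction equal to the number of its three
possible single-base changes that preserve the amino acid, divided by
the number of changes counted; N and S per codon always sum to 3.

*Stop-codon convention.* Published NG86 implementations disagree on
whether a single-base change into a stop codon counts as a
nonsynonymous opportunity or is excluded from the denominator. The
default here counts it as nonsynonymous (`stop_mutations=
"nonsynonymous"`); the alternative (`"exclude"`) is a documented toggle
so the difference is measurable. Pathways through stop codons are
excluded from the difference average whenever a stop-free pathway
exists; when every pathway crosses a stop, all pathways are averaged
with stop-crossing steps counted as nonsynonymous and the pair flagged
implicitly through its counts.

Codons containing ambiguous bases or stops are dropped from *both*
sequences of a pair, keeping site and difference counts on the same
codon set. N and S for a pair are the means of the two sequences'
counts. The Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) is applied
to both proportions; `saturated` is set when dS > 1 or when either
proportion reaches the 3/4 domain boundary, and dN/dS is reported as NA
when dS = 0.

*Known accuracy.* Under a uniform substitution process the estimator
carries a small systematic error from the mismatch between the JC
multiple-hit model (three equivalent targets per site) and real codon
structure (often fewer same-class targets per position, hence slightly
more reversions than JC assumes). Measured on planted-divergence
simulations (1,000 genes × 300 codons) the relative bias is about
+1.3% at dN = 0.05, ~0% at dN = 0.1 and −1.6% at dN = 0.3 — small in
absolute terms but resolvable at Monte-Carlo precision. This is a
property of the counting method itself, not of its implementation,
which agrees exactly with exhaustive enumeration on all 61 × 61
sense-codon pairs.

### Per-site Tajima's D (`popgen_stats`)

D is computed per variant site with the number of segregating sites
fixed at one (the variance term equals Tajima's e₁ coefficient with
S = 1) and averaged, unweighted, over a gene's variant sites. Each
site uses its own non-missing chromosome count, so missing genotypes
are handled site-locally rather than through a gene-wide n.

Sites with n < 4 are excluded from D (and logged): the variance term
is exactly zero at n ∈ {2, 3}, making D undefined there. The intended
use case is population panels with hundreds of chromosomes, where this
exclusion is vacuous.

### Diversity per site class

The per-site estimate is a ratio of sums across genotyped sites —
Σ differences / Σ comparisons with differences = c(n−c) and
comparisons = n(n−1)/2 per site — not a mean of per-site ratios, which
keeps the estimator unbiased under site-specific missingness. The
class-restricted analyses (missense + invariant, synonymous +
invariant) scale the per-site estimate by the number of genotyped
sites in the analysis and divide by the NG86 N or S count, yielding
diversity per nonsynonymous (synonymous) site. Invariant genotyped
sites carry no class label (there is no variant to classify) and enter
every class-restricted denominator; the algebra makes the final πN/πS
insensitive to how many invariant sites are included, because they
contribute comparisons to both the numerator scaling and the site
count symmetrically.

Statistics that are undefined (zero denominators, no variant sites,
n < 2) propagate as NA, never as 0.

## Expression summaries (`expression_metrics`)

Technical replicates (runs sharing an experiment ID) are averaged
first; conflicting metadata within an experiment is an error, not a
warning. Group means for τ include zeros — a gene absent from a
category is genuinely specific. The separate *average expression*
covariate excludes values below 5 TPM (boundary value kept: the rule
drops values strictly below the threshold) so that specific genes are
not automatically assigned low averages; the threshold is a parameter.
τ is computed on raw TPM means; a log transform can be applied upstream
but is not the default, since the index is already scale-invariant.
Tissue specificity applies the same formula to tissue-category means,
by default restricted to control-treatment samples.

## Surrogate variable analysis (`batch_correction`)

Expression is transformed to log2(TPM + 1); the treatment design is fit
as per-gene, per-category means; surrogates are the top right singular
vectors of the residual matrix. K is chosen by a Buja–Eyuboglu-style
row-permutation test (defaults B = 200, α = 0.05; the permuted matrix
is re-projected onto the design's orthogonal complement so observed
and null spectra are comparable). This is a deliberate simplification
of the iteratively reweighted svaseq estimator: the model contract
(design fit, surrogate span, per-gene loading removal) is the same,
the empirical-Bayes weighting is not. Loadings are estimated jointly
with the design so removal cannot absorb treatment signal; corrected
values are back-transformed and clipped at 0 (TPM cannot be negative).
The permutation RNG seed is a required argument — there is no implicit
global state.

*What removal can and cannot do.* Surrogates live in the row space of
the design residuals and are therefore exactly orthogonal to the
treatment indicators: correction never changes log-scale treatment
means. Consequently (i) batch variation *confounded* with treatment is
absorbed into the design fit and is structurally unremovable by this
(or any residual-based) SVA — apparent specificity created by such
confounding survives correction; (ii) the reduction in measured
treatment specificity after correction comes from removing
design-orthogonal batch noise, which otherwise inflates TPM-scale
group-mean contrasts. The batch-behavior tests therefore plant batch
shifts balanced across treatments, and the package makes no claim of
recovering from fully confounded designs beyond the
`subset_min_studies` guard (keep treatments observed in ≥ 2 studies).

## Partial Spearman correlation (`correlation_analysis`)

All variables are rank-transformed with average ranks for ties; the
partial correlation is read off the precision matrix of the rank-scale
correlation matrix, and the p-value uses the t statistic with
n − 2 − k degrees of freedom. No multiple-testing correction is
applied; raw p-values are reported with n alongside every coefficient.
Collinear covariates raise an error naming the offending pair. The
covariate rules per target: average expression, length, GC fraction
and tissue specificity always; family size added for πN and Tajima's D;
dN and DoS restricted to 1:1 orthologs; saturated genes dropped for dN
only. The all-pairs heatmap conditions each pair on all remaining
displayed variables by default; a fixed-covariate mode is available.

## Synthetic data (`synthetic_data`)

All generators are pure functions of (config, seed), with child seeds
derived deterministically from one master seed.

**ZINB experiment.** Matrices of 5 column groups × 5 replicates with
entries zero with probability 1 − p₂ = 0.6 and otherwise
NB(size = 100, p₁ = 0.1) in the (size, success-probability)
parameterization with mean size·(1−p)/p = 900 — stated explicitly
because "probability" alone is ambiguous between conventions; the
experiment's qualitative conclusion is insensitive to the choice.
1,000 matrices are generated per experiment; rows (genes) per matrix
default to 100, a scale at which the per-matrix Spearman correlations
are stable. The experiment shows that the strong negative τ–average
correlation is created by shared zeros: excluding zeros from the
average moves the correlation essentially to 0.

**Expression studies.** Log2-scale model: baseline + treatment profile
(a gene's preferred category at 1, others at 1 − s, so true τ = s)
+ per-study shift × per-gene loading (a rank-one batch) + Gaussian
noise (default SD 0.25 log2 units). Defaults: 2,000 genes, 5
treatments, 4 studies, batch SD 1.0 affecting 30% of genes. The
`incidence` switch controls whether every study covers every treatment
("balanced") or a rotating window ("unbalanced", emulating
heterogeneous public corpora where study and treatment are partially
confounded).

**Genotypes.** Segregating-site counts are Poisson with the neutral
expectation θ·L·a_n per class; allele counts follow the neutral
spectrum P(i) ∝ 1/i, under which the expected per-site diversity is
exactly θ; missingness (default 10%) drops diploid calls and
subsamples allele counts hypergeometrically. Defaults: n = 20
chromosomes, 600 nonsynonymous and 200 synonymous sites per gene,
θ_N = 0.002 and θ_S = 0.008 per site — values in the range typical of
selfing plant panels. Not emulated: linkage (sites are independent),
selection (constraint differences are planted through θ_N/θ_S, not a
forward simulator), and sequencing error.

**Codon pairs.** An ancestor of uniform random sense codons is mutated
along two lineages; per-lineage substitution counts are Poisson with
mean d/2 × (class site count), and each substitution is a uniformly
chosen single-base change accepted when its classification matches and
it creates no stop. Planted rates whose expected observed difference
proportion, 0.75·(1 − e^(−4d/3)), would reach the JC domain boundary
(≥ 0.72, i.e. d ≳ 2.2) are rejected as saturated by construction;
rates like dS = 1.2 generate normally and are flagged as saturated by
the estimator, as intended.

**Joined study.** Gene-level latent traits (τ, average expression,
length, GC, πN) are drawn from a Gaussian copula whose
partial-correlation matrix is planted directly (precision matrix with
unit diagonal and −ρ_partial off-diagonal, inverted and standardized).
Each latent maps monotonically to its observable, and measurement is
quasi-deterministic: expression replicates are noise-free with all
values above the 5-TPM cut (so measured τ and average equal their
planted values exactly), and per-gene diversity is realized by a
singleton-site construction whose only error is count quantization
(n = 100 chromosomes, 1,200 sites). This isolates the recovery test:
with per-gene measurement noise included, single-gene π̂ estimates are
so variable that any planted correlation of 0.1 would be attenuated
several-fold — a property of the measurement, not of the estimator
under test. The stochastic generators above cover the noisy-measurement
regime at the distribution level.

## Problem sizes and determinism

The test suite runs the exhaustive NG86 scan (61 codons, 3,721 pairs),
the full single-site Tajima's D grid (n = 4..100, all allele counts),
10,000-vector τ property checks, 500-instance partial-Spearman oracle
comparisons, the 1,000-matrix ZINB experiment, 1,000-gene divergence
recovery per planted rate, 500-gene diversity recovery, 10,000-gene
joined-study recovery and 20-run permutation-null calibration; the
whole suite completes in well under two minutes on one CPU. All
stochastic tests fix their seeds; `scripts/acceptance.py` derives every
generator seed from its `--seed` argument.

## Known limitations

* NG86+JC carries the ~1–2% divergence-dependent bias described above;
  for rate-ratio analyses this is immaterial, for absolute-rate
  calibration a likelihood method should be preferred.
* The SVA estimator is the simplified (unweighted) form; exact
  numerical agreement with svaseq on real data is not a goal, and
  confounded batch structure is out of reach by construction.
* The per-site Tajima's D average is not the classic multi-site D; the
  two agree only for genes with a single segregating site (this
  equivalence is tested exhaustively).
* Generators do not simulate linkage, demography, read-level noise, or
  ontology curation of sample labels.
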