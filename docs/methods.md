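# Methods

`rvset` implements set-based rare-variant association testing for
biobank-style binary and quantitative traits: Burden, SKAT and SKAT-O score
tests computed per gene on masked variant sets, with ultra-rare variants
collapsed into a single pseudo-marker, saddlepoint-corrected tails under
case–control imbalance, and Cauchy-combination aggregation across an
(annotation mask) × (maximum-MAF cutoff) testing grid.

## Model and test statistics

Step 1 fits the covariate-only null model. For a binary trait,
logit P(y_i = 1) = x_i'γ (IRLS to gradient norm < 1e-8); for a quantitative
trait, ordinary least squares with σ̂² = RSS/(N−p). The fit exposes the
fitted means μ̂, residuals y − μ̂ and working weights W (μ̂(1−μ̂) or 1/σ̂²).
In *offset mode* the covariate linear predictor is frozen and Step 2
projects out only the intercept — exact when genotypes are orthogonal to
covariates, and the cheap default for biobank-style runs.

Step 2 builds, for each testing cell, the score vector S = w ∘ G'(y − μ̂)
and its null covariance
Φ = w'(G'WG − G'WX(X'WX)⁻¹X'WG)w · r,
where w are per-marker weights and r is the variance-ratio calibration
(1 without a random effect). The three tests are:

* **Burden**: T = 1'S, Var = 1'Φ1, two-sided. For binary traits with
  |z| > 2 the normal tail is replaced by a saddlepoint approximation (below).
* **SKAT**: Q = Σ_j S_j², distributed as Σ λ_k χ²₁ with λ_k the eigenvalues
  of Φ; the tail is computed by characteristic-function inversion with
  saddlepoint and moment-matching fallbacks (below).
* **SKAT-O**: Q_ρ = (1−ρ)Q_SKAT + ρQ_Burden over the grid
  ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}; the minimum per-ρ p-value
  is combined by the standard one-dimensional integration over the shared
  burden component. Everything is derived from Φ alone: per-ρ eigenvalues
  come from (1−ρ)Φ + ρ(Φ^{1/2}1)(Φ^{1/2}1)', and the conditional remainder
  kernel is Φ − (Φ1)(1'Φ)/1'Φ1. Single-element grids {0} and {1} reduce
  exactly to SKAT and Burden.

### Ultra-rare collapsing

Before testing a cell, variants with minor allele count MAC ≤ 10
(real-valued dosage sum; the threshold is inclusive and recomputed after
masking) are merged into one pseudo-marker. Under the default Beta(1,25)
MAF weighting the collapsed dosage of a sample is the **maximum raw dosage**
among the ultra-rare variants it carries, the collapsed MAF is the allele
frequency of the merged column (capped at 0.5), and every marker — merged
column included — is weighted by the Beta(1,25) density at its MAF. With
user weights (or no weights, the unit-weight special case) ultra-rare
dosages are first multiplied by their weights and then merged by maximum;
the weights are thereby folded into the matrix and the reported weight
vector is all ones, so the test layer never re-weights.

Collapsing removes the near-degenerate singleton columns that break the
mixture-of-chi-squares approximation when cases are rare; it is the package's
calibration repair for variance-component tests at low MAF cutoffs.

### Saddlepoint tail for the burden score

For binary traits the score T = g'(y − μ̂) conditional on μ̂ has cumulant
generating function K(t) = Σ log(1 − μ_i + μ_i e^{g_i t}) − tΣg_iμ_i. The
saddlepoint K′(t) = s is found by a bracketed root search and the tail by
the Barndorff-Nielsen formula; the two-sided p sums the mass beyond |s| on
both sides (for a symmetric score this doubles one tail; for a score
bounded on one side the empty tail contributes 0). When every genotype
entry is an integer the score lives on a lattice and the tail uses Daniels'
continuity correction (evaluate at s − h/2 with 2·sinh(th/2) replacing th),
which is what brings the approximation within ~10% of exhaustive
enumeration at N = 12. The correction is skipped for weighted/projected
(non-lattice) genotypes. The SPA engages only when the standardized score
exceeds 2; when a testing cell collapses to a single pseudo-marker, the
SPA-adjusted single-variant p is reported for Burden, SKAT and SKAT-O
alike, since the three statistics coincide there.

### Mixture-of-chi-square tails

P(Σλχ²₁ > q) is computed by a ladder recorded per result:

1. **davies** — numerical inversion of the characteristic function (Imhof's
   integral) on a fixed grid dense enough for the oscillation rate
   (Σλ + q)/2, truncated where the envelope falls below tolerance and
   corrected by the leading integration-by-parts tail term; the error
   estimate is a Richardson difference plus the truncation bound. Accepted
   when the estimated error is below max(1e-9, 1e-3·p).
2. **kuonen** — Lugannani–Rice saddlepoint; used directly in the deep tail
   (p < 1e-4) and for wide spectra (K > 40), where the oscillatory integral
   is slow and the saddlepoint is accurate.
3. **liu** — Liu–Tang–Zhang moment matching, the last resort and the
   per-quadrature-point tail inside the SKAT-O integration.

Eigenvalues below 1e-10·λ_max are dropped.

## Null model with a sparse GRM

Relatedness is represented by a sparse GRM: mean over standardized common
markers of genotype products, with off-diagonal entries below 0.05 set to
zero. Quantitative traits are fitted by REML after eigen-rotation by the
GRM (profile likelihood in δ = τ/σ², bounded scalar search, boundary
checked against δ = 0). Binary traits use penalized quasi-likelihood:
the IRLS working response z = η + (y−μ)/w is refitted by the same
heteroscedastic REML until τ moves less than 1e-6 (50-iteration cap with a
reported trajectory on failure). τ ≥ 0 is enforced.

The variance ratio maps naive GLM score variances to mixed-model ones:
for probe markers g (30 by default; fewer triggers a warning),
r = mean[g'Pg / g'(W − WX(X'WX)⁻¹X'W)g] with
P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹, V = W⁻¹ + τK. With τ = 0 the two variances
coincide and r ≡ 1. This single-ratio calibration is a simplification of
the MAC-stratified recipes used at biobank scale and is adequate at the
sample sizes this package targets.

## Aggregation

Per-gene p-values across the testing grid are combined by the Cauchy
combination T = k⁻¹Σ tan((½ − p_i)π), p = ½ − arctan(T)/π, with the
1/(pπ) asymptote below 1e-15 for stability. The transform is undefined at
p = 1, so if any cell has p exactly 1 the gene instead reports
min(min_i p_i · k, 1) (minimum p with Bonferroni) and sets a fallback flag.
Values within 1e-15 of 1 are clamped rather than routed to the fallback.
Cells with no qualifying variants are excluded from k entirely — an absent
test carries no evidence, and imputing p = 1 would force the fallback
spuriously. Genes are flagged significant at the exome-wide threshold
p < 2.5e-6 (strict inequality).

## Synthetic data

`simulate_genotypes` draws independent bi-allelic variants: per-variant MAF
from a singleton-heavy spectrum (`wes_like`: 80% of variants with expected
MAC between 0.25 and 8, the rest log-uniform up to 1%; alternatives:
`uniform_log`, or a fixed value), then hard-call dosages equivalent to
Binomial(2, MAF) per sample (sampled by allele copy for speed). Monomorphic
draws are redrawn up to 10 times, then dropped. Annotations are assigned
lof/missense/synonymous at 0.1/0.6/0.3 by default.

`simulate_phenotype` draws one standard-normal covariate (effect 0.5) and
solves the logistic intercept by bisection so the marginal prevalence hits
the target within 0.001. Causal variants are sampled uniformly at rate
`causal_prop` among qualifying variants (optionally restricted by
annotation and maximum MAF); effects follow |β| = c·|log10 MAF| (or a
constant), with a configurable fraction of positive signs.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, population stratification, genotyping/annotation
error, and real exome site-frequency spectra. Passing studies therefore
demonstrate the statistical behaviour of the tests under idealized
independent-variant sampling, not performance on any particular cohort. An
adapter (`write_vcf` / group files) lets users with real genotypes run the
identical pipeline on their own data.

## Study harnesses and problem sizes

The type-I-error harness draws, per replicate, one null phenotype and a
batch of independent genes, runs every pipeline on the same data, and
reports empirical rejection rates with 95% binomial CIs, genomic-control
λ (median chi-square over 0.4549) and Q-Q points. The power harness runs
causal scenarios per configuration and additionally reports the median
chi-square statistic. Both are exactly reproducible from (config, seed);
all randomness flows from named substreams of the top-level seed.

Desk-scale sizes used by the shipped tests and acceptance script: the
calibration study runs 20,000 paired set tests at N = 5,000 with a 1:99
case:control ratio (the acceptance script uses 6,000 to keep its runtime
modest); power runs use N = 10,000 and replicate counts in the low
hundreds at α = 1e-3 — comparison margins are always ±2 s.e. computed from
the realized counts. The variance-component study uses 50 families of 20
at N = 1,000; the family size was chosen so the REML sampling distribution
of τ̂ identifies the component sharply (with very small families the
boundary estimator's spread dominates).

Two desk-scale caveats, measured and reported rather than hidden:

* At N = 5,000 the 0.01% MAF cell reduces to singletons only, so the
  collapsed pseudo-marker has on the order of 60–80 carriers and the score
  takes few discrete values. Empirical rejection rates at α = 0.01 are
  near-nominal, but the *median-based* λ_GC of the collapsed pipeline sits
  well above 1 purely because of this lattice discreteness (the p-value at
  the median score atom is ≈0.4, not 0.5) — with or without saddlepoint
  correction. At biobank N the same cell holds hundreds of carriers and
  the effect vanishes. The Q-Q data make the contrast with the
  uncollapsed pipeline's genuine tail inflation visible.
* At N ≈ 10 the exact null of Q carries point masses of up to ~0.09, so
  any asymptotic SKAT p-value differs from an exact resampling tail by a
  few hundredths; the package's tail computations are instead validated
  against the continuous distribution they assert (S ~ N(0, Φ)) and
  against exhaustive enumeration for the SPA.

## Numerical choices

* Minor-allele orientation is applied per variant before any MAC logic;
  missing genotypes are mean-imputed to 2·MAF of the non-missing samples.
* Multi-allelic VCF records are rejected (pre-split them).
* MAC on dosage data is the real-valued minor-dosage sum; MAC ≤ 10
  compares that real value.
* IRLS separation guard: |linear predictor| > 15 raises with advice.
* Davies tolerance 1e-9; SKAT-O integration uses 128 Gauss–Legendre nodes
  on the transformed (square-root) axis, is evaluated on the complement
  scale so small p suffers no cancellation, and falls back to
  min(min_ρ p·|grid|, 1) if the integral misbehaves.
* If the collapsed column exactly duplicates an existing column both are
  kept — the count law and provenance stay exact.

## Known limitations

Full dense-GRM REML, leave-one-chromosome-out, exact small-sample
resampling for tiny MAC, per-marker SPA inside the SKAT quadratic form,
conditional analyses and set-level effect estimation are out of scope.
Quantitative traits are not inverse-normal transformed by default.
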