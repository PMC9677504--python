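# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `omicsmr`, together with what the simulation-based
tests do and do not establish.

## Setting and assumptions

A gene is probed through m omics biomarkers X₁…X_m (exposures) and an outcome
Y. For each exposure we have cis-QTL summary statistics (per-SNP marginal
regression slope β̂_Xkj and standard error), for the outcome GWAS summary
statistics (β̂_Yj, σ̂_Yj), and an unsquared LD correlation matrix R over the
same SNPs. The usual instrumental-variable assumptions are taken as given:
the SNPs affect Y only through the exposures and are independent of
confounders. All engines are plug-in summary-statistics methods; none models
uncertainty in R itself.

Two-sample designs (disjoint QTL and GWAS subjects) are the intended regime.
One-sample designs correlate the exposure- and outcome-side estimation errors
through shared confounders and noise; the benchmark quantifies the resulting
type-I inflation rather than correcting it.

## Engines

- **IVW / GLS.** The GLS estimator
  θ̂ = (β̂_Xᵀ Ω⁻¹ β̂_X)⁻¹ β̂_Xᵀ Ω⁻¹ β̂_Y, var(θ̂) = (β̂_Xᵀ Ω⁻¹ β̂_X)⁻¹,
  Ω = diag(σ̂_Y) R diag(σ̂_Y), with a two-sided normal P for
  z = θ̂/√var. IVW is implemented as GLS with R = I, which fixes its
  denominator to Σ β̂_Xj² σ̂_Yj⁻² (the form consistent with the GLS reduction
  and with multivariable MR being its multi-exposure extension). The variance
  is first-order: QTL-side estimation error is ignored, which is accurate for
  adequately strong instruments and is the standard plug-in choice.
- **SMR.** T = z_Y² z_X²/(z_Y² + z_X²) against χ²(1). At z_X = z_Y = 0 the
  statistic is defined by its limit, T = 0 (P = 1). `smr_multi` exposes the
  `singleSNP` rule (per exposure, the SNP with max |z_X|) and the `allSNPs`
  rule (every SNP × exposure pair tested and all P-values passed to the
  combiner).
- **GSMR.** Per-SNP Wald ratios β̂_Yj/β̂_Xj pooled by GLS against their
  second-order covariance matrix V (diagonal and off-diagonal terms use
  var(β̂_X), var(β̂_Y) and r_ij; see the docstring for the exact
  expressions). Default instrument filters: pairwise r² < 0.95 with greedy
  pruning in descending |z_X| (the stronger of a collinear pair is kept —
  the selection rule is otherwise arbitrary and this one is deterministic),
  and instrument strength z_X² > 10. `min_snps` (default 10, the
  recommendation shipped with the reference implementation) is exposed so
  that 5-SNP benchmark settings can exercise the estimator; the benchmark
  runs it at 2. HEIDI-style outlier removal is out of scope.
- **Multivariable MR.** No-intercept weighted regression β̂_Y ~ Σ_k θ_k β̂_Xk
  with weights σ̂_Y⁻² (full GLS weighting when R is supplied); joint m-df
  Wald statistic θ̂ᵀ(XᵀΩ⁻¹X)θ̂. Requires p ≥ m+1 instruments and a full-rank
  design; otherwise the result carries `status = "insufficient_ivs"` instead
  of an estimate, mirroring how such genes drop out of real analyses.

Near-singular covariance matrices (reciprocal condition number < 1e-10, e.g.
duplicated SNPs with r = 1) raise a `NearSingularError` naming the most
collinear SNP pair.

## Combination tests

Given per-exposure P-values p₁…p_m (two-sided), with default equal weights:

- **Cauchy (ACAT).** T = Σ w_k tan{(0.5 − p_k)π}; P = 0.5 − arctan(T/Σw)/π.
  For T/Σw > 1e15 the tail expansion P = (Σw)/(Tπ) is used, and individual
  p_k < 1e-16 contribute their tangent's tail form w/(pπ) to avoid overflow.
  ACAT's validity under arbitrary dependence is asymptotic in the nominal
  level: at α = 0.05 and moderate z-correlation it can exceed nominal by a
  few thousandths (measured: 0.0545 at ρ = 0.5, m = 3, 10⁵ draws), which is
  visible in benchmark cells whose per-exposure tests are themselves exact.
- **HMP.** T = Σw / Σ(w/p) with weights normalized to sum 1. The P-value uses
  the asymptotically exact harmonic-mean calibration: S = 1/T follows, under
  the null, the one-sided stable (Landau) law with tail index λ = β = 1,
  location ln m + 1 + ψ(1) − ln(2/π) and scale π/2. The survival function is
  evaluated by direct quadrature of
  SF(y) = (1/π)∫₀^∞ exp(−t ln t − y t) sin(πt)/t dt,
  which matches `scipy.stats.levy_stable` (S1, α = β = 1) to ~1e-11 while
  being two orders of magnitude faster and stable in the far tail (the
  integrand is truncated to t ≤ 400/y for y > 40; SF ≡ 1 below y = −3 where
  the left tail is doubly-exponentially close to 1; SF ≈ 1/y above 1e120).
  No finite-m exact correction is applied, so the test is mildly conservative
  at small m (measured 0.046 at m = 3, ρ = 0).
- **MinP.** min p_k reported as-is — deliberately anti-conservative; kept
  because the benchmark needs the negative control.
- **Fisher χ².** −2Σ ln p_k vs χ²(2m); exact under independence only.
- **Fisher gamma.** The same statistic against a gamma null with moments
  E[T] = 2m and Var[T] = 4m + 2Σ_{i<j} c(ρ_ij), shape E²/Var, scale Var/E.
  The per-pair variance contribution uses the Brown/Kost cubic
  c(ρ) = 3.263|ρ| + 0.710ρ² + 0.027|ρ|³, applied to |ρ| because two-sided
  P-values make the induced dependence symmetric in the sign of ρ; the
  polynomial is exact at the anchors c(0) = 0 (reduction to χ²(2m)) and
  c(1) = 4 (perfect duplication, where the gamma collapses to an exponential
  and the combined P of (q, q) is exactly q). Two caveats, both verified
  numerically: the cubic was fitted to one-sided covariances and overstates
  the two-sided covariance at moderate ρ (e.g. 1.81 vs an exact 0.99 at
  ρ = 0.5), which errs conservative; and the two-moment gamma itself misses
  deep-tail probabilities by tens of percent regardless of the covariance
  used (at m = 3, ρ = 0.5, a true tail mass of 0.0049 is approximated as
  0.0064). Near the conventional 0.05 level the approximation is accurate
  (measured 0.039–0.049 null rejection across ρ ∈ {0, 0.5, 0.9}).

The z-statistic correlations for Fisher gamma come from
`gls_z_correlation`: each exposure's GLS z is the linear functional
a_kᵀ z_Y with a_k = R_k⁻¹γ̂_k/√(γ̂_kᵀR_k⁻¹γ̂_k), γ̂_k = β̂_Xk/σ̂_Y, and
cov(z_Y) ≈ R, so cov(z_k1, z_k2) = a_k1ᵀ R[S₁,S₂] a_k2 needs only the LD
submatrix over the two exposures' SNP sets (which may differ after per-omic
clumping). Estimated |ρ| marginally above 1 from numerical error is clamped
to ±1 with a warning.

When an engine fails recoverably on an exposure (insufficient instruments,
singular covariance), that exposure is dropped from the combination with m
decremented and a warning; a gene with no surviving exposure yields a missing
result rather than a fabricated P-value.

## LD clumping

Greedy selection in ascending QTL P-value (ties broken by lexicographically
smaller SNP id, making the output invariant to input row order); a candidate
is rejected if r² ≥ `r2_max` (default 0.2) with any selected SNP or its
distance to any selected SNP is ≤ `dist_max` (default 100 kb — acceptance
requires strictly greater). Coordinates are 1-based single positions with
distance = absolute difference; when no coordinates are supplied the distance
rule is skipped, which is also how the simulation benchmark runs (its
generative model has no genomic map, and its engines are meant to see all p
SNPs with LD handled by GLS). `analyze_gene` clumps only when `clump_r2` is
given.

## Simulation design

Defaults reproduce the benchmark's study conditions; every axis is a config
field.

- **Genotypes.** p SNPs (5 or 20), dosages Binomial(2, maf = 0.3), pairwise
  dosage correlation √r² (equicorrelated; r² ∈ {0, 0.01, 0.2}). Mechanism: a
  Gaussian copula on the two haplotypes — each haplotype allele is the
  indicator of an equicorrelated latent normal falling below Φ⁻¹(maf), with
  the latent correlation calibrated by bivariate-normal root finding so the
  realized Bernoulli (hence dosage) correlation hits the target exactly while
  the Binomial(2, maf) marginals are preserved by construction.
- **Structural equations.** Vertical pleiotropy (exposures in series):
  X₁ = (α/p)ΣZ + U + ε₁, X₂ = 2X₁ − U + ε₂, X₃ = −0.5X₂ + U + ε₃, outcome
  Y_C = β_X X₃ − U + ε_Y or logit P(Y_B = 1) = −2 + β_X X₃ − U. Horizontal
  pleiotropy (parallel): X₁ on all p SNPs (+U), X₂ = −(α/p)Σ_{j≤⌊p/2⌋}Z_j − U
  + ε₂, X₃ = +(α/p)Σ_{j>⌊p/2⌋}Z_j − U + ε₃, outcome on ΣX_k with +U (the
  same confounder throughout — the model has a single U). U and all ε are
  iid standard normal. IV strength α ∈ {0.5, 1, 2}; causal effect β_X ∈
  {0, 0.1}. An optional `beta_distributed` mode replaces the constant α/p
  loadings with iid Beta(1, 1)-scaled ones (parameters configurable; the
  canonical values are not fixed by the benchmark definition).
- **Samples.** Continuous outcome: each study (GWAS, QTL) has 500 subjects; a
  population of 500 + (1 − overlap)·500 is simulated and the QTL study shares
  overlap·500 subjects with the GWAS study (one cohort at overlap = 1,
  disjoint 500 + 500 at overlap = 0). Binary outcome: a population of up to
  5 000 is oversampled (logit intercept −2 gives ≈ 12% prevalence under the
  null), 250 cases + 250 controls form the GWAS arm, and the QTL sample is
  250 subjects — controls only when `controls_only_qtl`, with the configured
  overlap against the corresponding GWAS subjects; an informative error asks
  for a larger population if quotas cannot be met. Independent per-omic QTL
  samples (`shared_qtl_samples = False`) are defined only for the two-sample
  setting and are validated as such.
- **Summary statistics.** Per SNP: OLS of each exposure on dosage over that
  exposure's QTL sample; OLS (continuous) or Newton-Raphson logistic
  (binary; tolerance 1e-8, max 50 iterations, non-convergence flags the SNP)
  of the outcome over the GWAS sample. SNPs monomorphic in any involved
  subsample are excluded everywhere with a warning. The LD matrix is the
  empirical dosage correlation over all genotyped subjects of the replicate —
  the largest available reference, as a practitioner would use a panel;
  diagnostics showed type-I behavior is insensitive to this choice
  (GWAS-sample, population, or true matrix).
- **Benchmark loop.** Every method is evaluated on the same summary
  statistics per replicate; per-replicate RNG streams derive from
  (seed, setting index, replicate index), so results are bit-reproducible
  and independent of any parallel scheduling. Genotypes are redrawn every
  replicate (fully stochastic design). Replicates where a method yields no
  P-value are counted in `n_failed` and excluded from that method's rate
  denominator, with the fraction reported. The nominal level is 0.05
  throughout, exposed as a flag.

## What the tests show — and do not

The acceptance-level tests replicate, at 10 000 replicates: type-I control of
GLS + {Cauchy, HMP, Fisher gamma} in the two-sample null design; the failure
of MinP and Fisher χ² under the same correlated-exposure null; type-I
inflation of GLS + Cauchy under a one-sample design (overlap = 1, 20 SNPs)
and its absence under two samples (that control cell is estimated at 30 000
replicates because its true rate, ≈ 0.054 from ACAT's moderate-α behavior,
sits close to the allowance and a 10 000-replicate estimate is noisy); and
the power ordering GLS_Fisher_gamma ≥ GSMR_Cauchy under weak instruments
with convergence under strong ones (2 000 replicates per cell).

The generator emulates the benchmark's stylized world: equicorrelated LD,
exactly three exposures with fixed structural coefficients, Gaussian noise,
a single confounder, and no allele-coding or harmonization issues. Passing
tests therefore demonstrate correctness of the estimators and the validity
ordering of the combiners under these conditions — not robustness to
realistic LD block structure, winner's-curse instrument selection,
non-Gaussian traits, or misspecified reference LD. Engines deliberately do
not model uncertainty in R, and IVW/GLS use first-order variances, so very
weak instruments outside the benchmarked α range may behave worse than the
reported rates suggest.
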