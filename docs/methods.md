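# Methods

## The generative model behind the package

Brain image-derived phenotypes (IDPs) within a subtype are modeled as

    IDP_k = L + R_k + ε_k,     k = 1..K,

where L is a brain-wide latent component shared by all regions (variance
fixed at 1, so trait effect sizes are on a common scale), R_k is a
region-specific component with variance s², and ε_k is measurement noise
with variance t². A complex trait is

    Y = α·L + Σ_k β_k·R_k + ε_Y,

rescaled to unit total variance. The subtype's first principal component is
used as the observable proxy for L, and the per-region residuals after
removing PC1 as proxies for the R_k. Both L and each R_k carry a dense
polygenic genetic basis (independent normal weights over all variants) with
heritabilities h2_L and h2_R; h2_R = 0 recovers the purely environmental
region components of the minimal model. The analytic SNP heritability of an
observed feature is then (h2_L + s²·h2_R)/(1 + s² + t²), which the REML
tests check against.

## Synthetic cohorts

`simulate_genotypes` draws, per chromosome and per haplotype, a latent
Gaussian AR(1) process with lag-one correlation `ld_rho` along the variant
index, thresholds it at each variant's allele frequency (uniform in
`maf_range`), and sums two haplotypes into a dosage. This gives
geometrically decaying adjacent LD with a closed-form handle, independent
chromosomes, and exact reproducibility from a seed. It is an emulation, not
population genetics: there is no recombination map, no population
structure, no relatedness, and allele-frequency/LD joint structure is
simplistic. Defaults (n = 2000, P = 2000, K = 30, maf ∈ [0.05, 0.5],
ld_rho = 0.7, s² = t² = 0.25, h2_L = h2_R = 0.5, α = 0.3, 2 chromosomes)
are the study conditions used throughout the tests; `ld_rho = 0.7` puts the
practically relevant LD range well inside the default covariance bandwidth
of 200 variants. Consequences: passing tests demonstrate the estimators'
internal consistency and calibration under short-range LD and homogeneous
ancestry, not robustness to the long-range LD, stratification, or
assortative-mating artifacts of real biobank data.

## Ridge in the dual form

The primal ridge problem min ‖B − Xw‖² + λ‖w‖² on the standardized n×P
genotype matrix is solved through the matrix push-through identity as

    ŵ(θ) = (θ/P) · Xᵀ (θΣ + (1−θ)Iₙ)⁻¹ B,   Σ = XXᵀ/P,  θ = P/(P+λ),

a single n×n solve independent of P. We carry the explicit 1/P factor that
makes ŵ(θ) exactly equal to the primal solution at λ = P(1−θ)/θ — the
dual/primal equivalence is asserted to 1e-8 across the entire default θ
grid {0.01, 0.05, 0.1, 0.2, …, 0.9, 0.95}. Standardization uses the
population (1/n) standard deviation everywhere, which keeps Σ's expected
diagonal at 1 and makes the equivalence exact rather than approximate.
θ is selected by inner 5-fold cross-validation maximizing out-of-fold
Pearson correlation (the criterion is not pinned down externally; Pearson
matches the elastic-net validation criterion). Fold standardization moments
come from each training split only — reusing full-sample moments leaks
information and biases CV upward. For the calibration studies
(inflation factor, null baseline) where hyperparameter choice is orthogonal
to the question, θ is fixed at 0.1.

Elastic net uses scikit-learn's coordinate descent with mixing α = 0.1,
a 50-point λ path log-spaced from λ_max = max_j |x_jᵀB|/(N·α) down three
decades, λ chosen by Pearson correlation on a random 20% validation split,
and a final refit on all samples.

## REML heritability

The variance-component model y = μ + g + e, g ~ N(0, σ²_g·K), K = XXᵀ/P, is
fit by restricted maximum likelihood in the eigenbasis of the
intercept-projected GRM: one eigendecomposition per cohort, cached, then a
1-D profile likelihood in δ = σ²_e/σ²_g scanned on 100 log-spaced points in
[1e-5, 1e5] and polished by bounded scalar minimization in the winning
bracket. Eigenvalues below 1e-10 are clipped (tiny negative values occur in
finite simulated GRMs) and clipping is logged. Optima at the grid edges are
snapped to h² = 0 or 1 and flagged; se(h²) comes from the numerical second
derivative of the restricted log-likelihood reparameterized in h², a
quadratic approximation that is unreliable at the boundary (flagged
accordingly).

## Banded LD and summary-level association

The reference SNP covariance is computed on standardized dosages
(denominator n_ref), i.e. stored as a correlation matrix with unit
diagonal, and banded per chromosome: entries beyond `bandwidth` (default
200) index positions apart are zero, and between-chromosome covariance is
zero by construction. This matches the scale of weights trained on
standardized genotypes, so the √R̂jj factor in the z-score combination is
exactly 1, and σ̂_k² = ŵᵀR̂ŵ is the reference-panel variance of the predicted
feature. The quadratic form and matrix-vector products run band-aware in
O(P·b). A non-positive σ̂_k² raises — it signals LD misspecification rather
than a recoverable state.

Effect sizes on the summary route are reported on the standardized scale
via β̂_k = z_k/(σ̂_k·√N) with the trait in sd units. The printed combination
Σ ŵ R̂jj b̂ /σ̂² is consistent only when weights, covariance and per-allele
GWAS betas share the raw-dosage scale; summary data do not carry the
per-SNP dosage variances needed to rescale b̂, while the z-based identity is
exact in the same asymptotics as the z-score combination itself. The
implementation is verified against the individual-level regression slope on
simulations rather than against any particular rendering of the formula.

Two-sample discipline matters at desk scale: when the GWAS cohort is the
training cohort itself, ridge weights partially absorb that cohort's
sampling LD, the in-sample variance of X·ŵ exceeds ŵᵀR̂ŵ, and summary
z-scores overshoot individual-level ones by ~10% at n ≈ P. The concordance
tests therefore train on one cohort and associate on a disjoint cohort,
which is also the realistic deployment (GWAS cohorts disjoint from the
imaging training panel).

## Inflation factor Φ and the variance-control correction

When trait and predictor are both polygenic, the null distribution of the
association z is inflated: E[Z²] ≈ 1 + N·h²·Φ, with Φ specific to each
feature. For a dense polygenic null trait, theory gives
Φ = (ŵᵀR̂²ŵ)/(P·ŵᵀR̂ŵ) — of order (mean LD eigenvalue)/P, hence tiny when
predictors spread over very many variants. `estimate_phi` measures it by
simulation: for each (N, h²) grid cell, 1000 polygenic null phenotypes
Y = Xδ + ε (dense normal δ, genetic variance rescaled to exactly h²) are
drawn on a reference cohort disjoint from any GWAS cohort, Y is regressed
on each predicted feature, and the mean χ² is recorded. Φ_k is the
per-feature slope of mean χ² on N·h² with a pooled intercept, shrunk toward
the common slope by method-of-moments empirical Bayes and floored at 0.
Default desk-scale grid: N ∈ {1000, 2000, 4000}, h² ∈ {0.1, 0.3, 0.5, 0.8}.

Corrected p-values follow the variance-control rule
p = P(χ²₁ ≥ z²/√(1 + N·h²·Φ)). Note the square root: if Var(z) is exactly
1 + N·h²·Φ, full calibration would require dividing by the variance itself,
and the square-root form under-corrects by a residual scale √(1+N·h²·Φ).
The rule is therefore accurate precisely in the mild-inflation regime
N·h²·Φ ≪ 1 that genome-wide-dense predictors inhabit. The calibration study
in the acceptance suite is designed in that regime (P = 10⁴ variants,
short-range LD, giving N·h²·Φ ≈ 0.3 at N = 5000, h² = 0.5): large enough
that uncorrected inflation is unambiguous, small enough that the corrected
p-values are uniform to KS at the 1% level. The trait h² entering the
correction is user-supplied configuration; when individual data exist it
can be plugged from the REML estimator.

## Mendelian randomization

Instruments are greedy LD clumps: candidates below the p threshold visited
in ascending p, accepted iff r² ≤ 0.001 (squared Pearson correlation of
standardized reference dosages) with every previously accepted variant
within 10 Mb. IVW is weighted least squares of outcome on exposure betas
through the origin with weights 1/se_out², with multiplicative
random-effects se inflation √(Q/(k−1)) when Cochran's Q exceeds its df.
The weighted median interpolates the 50th weighted percentile of Wald
ratios (inverse-variance ratio weights; seeded parametric bootstrap se,
1000 resamples). Egger adds a free intercept, orients exposure betas
positive, floors the residual se inflation at 1, and tests slope and
intercept on k−2 df. Minimum instruments: 1 (IVW), 3 (median, Egger).

The sign-aware Cauchy combination converts each two-sided p to a signed
one-sided p (q = p/2 for positive estimates, 1 − p/2 for negative), sums
w·tan((0.5−q)π), and folds back two-sided. Identities: equal p with equal
signs combine to the same p; a perfectly discordant pair combines to 1;
with all signs positive it reduces to plain ACAT. This construction is our
own — it satisfies the qualitative requirement of rewarding sign
concordance, but the exact published variant is not available for
comparison and details (weighting, one-sided conventions) may differ.

MR caveats carry over from the underlying estimators: same-sample GWAS for
exposure and outcome biases toward confounding; threshold selection causes
winner's-curse attenuation (visible as IVW estimates a few percent below
the simulated truth at n = 20k); homogeneous instrument strengths leave
Egger poorly identified.

## Numerical and interface choices

- Variant matching is by rsid, falling back to (chrom, pos, allele pair);
  strand-ambiguous A/T and C/G variants are excluded up front
  (`select_variants`), so complement-base rescue is deliberately not
  attempted during harmonization.
- Missing dosages are mean-imputed per variant before standardization, with
  the missing rate logged; monomorphic variants raise with their rsids.
- PCA for the subtype decomposition runs on z-scored columns (prevents
  large-volume regions dominating PC1); loadings are oriented so their mean
  is non-negative, making PC1 a weighted average of regions; only PC1 is
  removed.
- Inverse normalization uses the Blom offset (rank − 3/8)/(n + 1/4) with
  average ranks for ties.
- Head-size scaling multiplies T1 volumetric columns by the per-subject
  scaling factor (toward standard space); diffusion measures pass through.
- Preprocessing order is residualize → decompose → inverse-normalize.
- The weight database stores ridge vectors densely and sparse models by
  their nonzeros; round trips are bitwise.
- Desk-scale problem sizes used by the test suite (n ≤ 5000 per cohort,
  P ≤ 10⁴, K ≤ 30) were chosen so each study completes in minutes on one
  core while keeping every asserted effect several standard errors from its
  threshold.

## Known limitations

- The genotype simulator's LD is strictly short-range AR(1); conclusions
  about bandwidth sufficiency do not transfer to regions like MHC.
- Polygenicity (effective number of independent associations) and genetic
  correlation via LD-score regression are out of scope, as are BGEN input,
  multi-allelic sites, chromosome X, and liftover.
- The square-root variance-control correction under-corrects outside the
  mild-inflation regime (see above); users with very strong inflation
  should treat corrected p-values as upper bounds on significance.
- se(h²) is a curvature approximation; bootstrap or profile intervals are
  not implemented.
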