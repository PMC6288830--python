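# Methods

## Model

The Bayesian engine fits the multi-trait multi-environment mixed model

    Y = X β + Z₁ b₁ + Z₂ b₂ + E

with Y the n×L phenotype matrix over n = J·I (line, environment) cells.
`MN(H, Ω, Σ)` denotes the matrix-variate normal: vec(M) ~ N(vec(H), Σ⊗Ω).
The distributional assumptions are

* b₁ ~ MN(0, G, Σₜ): genotype-by-trait effects, correlated across lines
  through the genomic relationship matrix G and across traits through
  the unstructured genetic covariance Σₜ (L×L);
* b₂ ~ MN(0, Σ_E ⊗ G, Σₜ): genotype-by-environment-by-trait effects,
  with an unstructured environment covariance Σ_E (I×I); the Kronecker
  row covariance requires Z₂'s column for line j in environment i to be
  i·J + j, which the data layer freezes;
* E ~ MN(0, Iₙ, R_e): row-independent residuals with unstructured trait
  covariance R_e.

G is computed literally as W Wᵀ/p from the −1/0/1 marker codes, without
centring by allele frequency (centred variants of the relationship
matrix exist; the uncentred cross-product is used here and documented —
supplying a pre-computed G is also supported, validated for symmetry and
positive semi-definiteness and nudged by ε·I, ε = 1e−8·tr(G)/J, only
when its smallest eigenvalue falls below ε).

### Priors

Flat on β (an optional Gaussian prior with precision τ is available and
used by the Geweke test, which needs proper priors), and inverse-Wishart
IW(ν = dim+2, S = I) on Σₜ, Σ_E and R_e — proper and weakly informative,
prior mean I. All are overridable. ν = dim+2 is the smallest integer df
with a finite prior mean; analyses sensitive to this choice should set
the prior explicitly.

### Full conditionals and the sampler

All blocks are conjugate. Writing the partial residual for each block:

* β: environments decouple because XᵀX is diagonal; row i has Gaussian
  conditional with precision c_i R_e⁻¹ + τI and mean P⁻¹R_e⁻¹(XᵀY_r)ᵢ.
* b₁: the JL-dimensional Gaussian conditional has precision
  Σₜ⁻¹⊗G⁻¹ + R_e⁻¹⊗Z₁ᵀZ₁. In the eigenbasis G = U D Uᵀ (Z₁ᵀZ₁ = I·I_J on
  the complete grid) it factorizes into J independent L×L blocks with
  precision d_k⁻¹Σₜ⁻¹ + I·R_e⁻¹, sampled batched.
* b₂: identically, in the eigenbasis of Σ_E ⊗ G (eigenvalues λᵢ·d_j,
  eigenvectors applied as per-trait J×I reshapes — the Kronecker factors
  are never formed); IJ blocks of size L.
* Σₜ ~ IW(ν + J + IJ, S + b₁ᵀG⁻¹b₁ + b₂ᵀ(Σ_E⊗G)⁻¹b₂) — both random
  effects pool into the genetic trait covariance (the b₂ term only when
  the interaction is in the model).
* Σ_E ~ IW(ν + J·L, S + Q) with Q the Σₜ⁻¹-weighted quadratic form of b₂
  folded per trait into J×I matrices.
* R_e ~ IW(ν + n, S + EᵀE) with E the current residual matrix.

Without the interaction term (`include_gxe=False`), b₂ and Σ_E are
simply absent from the model.

Correctness is certified by tests rather than transcription: each
Gaussian block's empirical draw moments are compared against the same
conditional built densely as a vec/Kronecker multivariate normal; each
inverse-Wishart block against its closed-form conditional mean; and the
whole sampler against a Geweke joint-distribution ("getting it right")
test — forward simulation from the prior versus a successive-conditional
chain, compared on 22 first and second moments with batch-means standard
errors.

### Missing cells: data augmentation

Cells held out for prediction (and any unobserved cells) are handled by
data augmentation: each sweep begins by drawing the missing rows of Y
from their conditional N(x_rβ + z₁ᵣb₁ + z₂ᵣb₂, R_e). The marginal
posterior over parameters given the observed rows is exactly the
posterior that drops those rows from the likelihood, while every block
update keeps its complete-data form — in particular the eigen-rotated
b₁/b₂ updates stay valid, which is what makes the J=100 recovery study
and repeated CV fits affordable. The clamped-covariance check (Gibbs
with covariances fixed at truth versus the closed-form mixed-model
predictor) verifies this scheme is exact up to Monte-Carlo error.
Per-trait partial missingness inside a cell is not supported: CV2 masks
whole cells, and the package enforces that.

Defaults: n_iter = 10 000, burn_in = 5 000, thin = 2. Convergence is the
user's responsibility; `PosteriorChains.split_rhat` reports a
split-chain potential-scale-reduction diagnostic per element. A fixed
`random_state` gives bitwise-identical chains. Predictions for target
cells are posterior means of the model mean Xβ + Z₁b₁ + Z₂b₂; the
posterior-mean predictor is the package's choice of point prediction.

## The dense network

Inputs per cell: I environment one-hots; J genomic columns — row j of
the symmetric eigen square root L_g of G (L_g L_gᵀ = G), so a linear
network on this block reproduces the mixed model's genomic covariance
(a GBLUP-equivalent baseline); optionally the I·J products of
environment indicators with genomic columns as the interaction block.
The marker-to-feature encoding is a design decision of this package.

Architecture: `n_layers` ReLU hidden layers of `units` units, inverted
dropout (rate 0.3 by default) after each hidden layer during training
only, and one linear head with L output units. Loss is the mean squared
error over the L standardized traits; the optimizer is Adam
(lr 1e−3) with mini-batches of min(32, n). Loss/optimizer/batch size are
this package's choices and are exposed as parameters. Responses are
standardized per trait (subtract mean, divide by sample SD with the n−1
denominator, fitted on training rows only) and predictions
back-transformed.

Hyperparameter selection uses one stratification-free 80/20 split of the
training rows: every configuration of the factorial grid is trained on
the inner-train part with the same seed and scored by validation MSE;
ties break toward fewest layers, then units, then epochs. The selected
configuration is refitted on the full training set before test
prediction. `epochs` counts exact full passes — there is no early
stopping, since epochs are themselves tuned. One user seed drives
initialization, batch shuffling, dropout masks and the inner split.

## CV2 and accuracy

m = round(p_testing·N) lines are drawn per partition — rounding half
away from zero, a documented choice where only "0.2·N" is specified —
with replacement iff J < m; one uniform environment per drawn line; the
distinct cells become the test set (duplicate draws collapse).
Partitions are independent. Accuracy is Pearson's correlation per
(trait, environment) stratum per partition, computed per partition and
then averaged (not pooled); the standard error is the SD across
partitions divided by √(#partitions). Strata with fewer than two test
cells or zero variance are reported missing, never as zero.
Heritability-adjusted accuracy is r/√h²; h² values are inputs (the
package does not estimate them), must lie in (0, 1], and the adjusted
value may exceed 1.

## The simulator

Markers: independent loci under Hardy-Weinberg proportions with allele
frequencies uniform on a MAF range (0.1–0.5 by default) — deliberately
simple population genetics with no linkage disequilibrium, no selection
and no pedigree, so G has weak off-diagonal structure unless p is small
relative to J. Effects and residuals are drawn exactly from the model
above; Y is assembled in the data layer's environment-major cell order
and the realized effects are retained, so the reconstruction identity
and second-moment properties are assertable, and realized per-stratum
signal fractions (var(genetic)/var(Y)) provide calibrated h² inputs.
Default β uses distinct small integers per environment-trait so
fixed-effect recovery is visually checkable. Because the simulator
mirrors the Bayesian engine's model, passing tests certify the
machinery, not real-data performance: real GBS panels have LD,
relatedness structure, non-Gaussian residuals and trait architectures
this generator does not emulate.

## Validation-study sizes

The package's own validation suite (tests and `scripts/acceptance.py`)
uses: Geweke at J=5, I=2, L=2 with 50 000 sweeps; credible-interval
coverage at J=100, I=3, L=2, 20 replicates of 6 000-sweep chains
(burn-in 3 000); the CV2 law over 1 000 partitions at J=100, I=3; and
the four-engine comparison at J=50, I=3, L=2 over 10 partitions with
4 000-sweep chains and a single-configuration network grid. The
comparison simulates strong *crossover* genotype-by-environment
interaction: Σ_E with variance 1.5, correlation 0.8 between two similar
environments and −0.4 with the third. Two considerations drive this
design. CV2 predicts a masked cell from the same line's records in
other environments, so interaction effects uncorrelated across
environments would be unpredictable for every engine and would not
probe the interaction term at all; and with uniformly positive
correlations a line's average performance (captured by the main
genotype effect) already carries most of the interaction signal, so
models with and without the term nearly tie. Crossover interaction —
rankings that reverse between environment clusters, the agronomically
critical case — is where modelling Σ_E matters: the line average
misleads, and only the engines that carry the interaction term can
exploit the environment covariance structure.

## Numerical notes and limitations

* GRM eigenvalues are floored at 1e−12 in the sampler; singular G (p < J
  or duplicated genotypes) is handled by the jitter policy above.
* Batched L×L Cholesky factorizations drive all Gaussian block draws; a
  singular posterior precision raises an error suggesting GRM jitter.
* The sampler aborts with the iteration index if any state becomes
  non-finite.
* Scale non-identifiability between Σ_E⊗G and Σₜ in the b₂ prior is
  resolved only by the priors; with very weak data, Σ_E and Σₜ trade
  scale and individual elements should be interpreted jointly.
* Chains store all retained draws in memory including per-cell fitted
  values; at J in the thousands, thin more aggressively.
* No CV1/CV0 schemes, no convolutional/recurrent networks, no VCF/PLINK
  parsing, no pedigree relationship matrices, no heritability
  estimation.
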