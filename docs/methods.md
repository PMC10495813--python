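# Methods

This document describes the statistical models, the numerical choices, the
synthetic-data generator, and the known limitations of `phylofee`.

## 1. Phylogenetic trait model

### Brownian covariance and Pagel's λ

A trait evolving by Brownian motion (BM) along an ultrametric phylogeny
induces, across tips, a multivariate normal distribution with mean μ·1 and
covariance σ²·C, where C_ij is the depth of the most recent common ancestor
of tips i and j (root depth 0). The cophenetic (patristic) distance obeys
d_ij = C_ii + C_jj − 2C_ij.

Pagel's λ ∈ [0, 1] rescales only the off-diagonal of C:

    C(λ) = λ·C + (1 − λ)·diag(C)

λ = 1 is pure BM; λ = 0 makes tips independent. For a trait vector x the
profile log-likelihood at λ plugs in the GLS mean
μ̂ = (1ᵀC(λ)⁻¹x)/(1ᵀC(λ)⁻¹1) and the ML rate σ̂² = rᵀC(λ)⁻¹r/n with
r = x − μ̂·1. λ̂ maximizes this over [0, 1].

**Numerics.** On an ultrametric tree diag(C) = h·I, so C(λ) = λ·C +
(1 − λ)h·I shares C's eigenvectors. `LambdaEngine` eigendecomposes C once
(O(n³)) and evaluates every subsequent likelihood in O(n) in the rotated
basis, making 50-seed recovery studies and 200×199 permutation tests cheap.
Non-ultrametric trees fall back to a Cholesky path with a 1e-10-scaled
ridge retry for near-singular matrices. Optimization is a 21-point grid
pre-scan followed by bounded Brent refinement in the best bracket, which is
robust to the boundary optima at 0 and 1. Constant traits raise
`DegenerateTraitError` rather than returning an arbitrary λ.

### Permutation test

Significance of λ̂ is assessed by shuffling tip labels `n_perm` times and
re-estimating λ. The p-value uses the add-one correction
p = (1 + #{λ̂_perm ≥ λ̂_obs}) / (1 + n_perm), with ties counting against
significance, so p is never 0 and the test is valid (sub-uniform under the
null). Because λ̂ has a point mass at the boundary 0 under the null, null
p-values concentrate at 1; the test is conservative by construction, with
empirical type-I error ≈ 0.05–0.07 at α = 0.05.

### Distance correlation

The phylogeny–phenotype association is the Pearson correlation of the
upper-triangle entries of the cophenetic matrix and the phenotypic distance
matrix (Euclidean distance of z-scored traits; for pairs with missing
traits, the distance over the k shared traits is rescaled by √(p/k), and
pairs sharing fewer than 2 traits are dropped with a warning). The Mantel
permutation test shuffles one matrix's rows and columns jointly, one-sided,
add-one-corrected. The Mantel loop is hand-rolled to give explicit seed
control.

## 2. Phylogenetic imputation

A missing tip m is predicted by the conditional Gaussian (universal
kriging) formula given observed tips o:

    x̂_m  = μ̂ + C_mo C_oo⁻¹ (x_o − μ̂·1)
    var_m = σ̂² [ (C_mm − C_mo C_oo⁻¹ C_om) + (1 − C_mo C_oo⁻¹ 1)² / (1ᵀC_oo⁻¹1) ]

The second variance term propagates the uncertainty of the estimated root
state. This predictor is numerically identical (≤ 1e-8 in tests) to
rerooting the tree at m's attachment node and taking the Felsenstein
pruning ML ancestral state — the imputation literature's
"reroot-and-reconstruct" view. With a single observed tip the rate is
unidentifiable: the observed value is returned with NaN variance.

**LOOCV at taxonomic exclusion radii.** For each focal strain we drop,
before predicting, (i) only the strain itself, (ii) its identical-marker
group, (iii) its conspecifics, (iv) its congeners — mimicking prediction of
progressively less-sampled newcomers. Accuracy is the per-trait Pearson r
between predictions and held-out truth; per-strain error is the mean
absolute error in per-trait SD units, which can be related to each strain's
phylogenetic nearest-neighbour distance (PNND). Foci whose exclusion set
leaves fewer than 2 observed strains are skipped with a warning, not an
error, so a genus that swallows most of the collection cannot abort the
analysis. Imputation accuracy on [0,1]-λ collections increases with the
generating λ (corr ≈ 0.9) and decays with exclusion radius.

## 3. Functional effect equations

Community function F ∈ [0, 1] is the fraction of initial fermentable
sugars consumed. The functional effect of strain i on background B is
ΔF_i(B) = F(B∪{i}) − F(B), and the FEE is the per-strain linear model

    ΔF_i(B) = a_i + b_i·F(B) + θ_i(B).

### Fitting

For each strain, every measured pair (B, B∪{i}) — including the (∅, {i})
monoculture pair, with F(∅) = 0 — contributes one point; replicates enter
through their means. OLS gives (a_i, b_i); σ_i² = SSR/(n−2) with a floor of
1e-4 (on the [0,1] scale) so zero-residual fits cannot produce infinite
lattice weights. Fewer than 3 pairs, or no variance in F(B), is an error;
`fit_all_fees` records such strains in `.failures` instead of aborting.

### Lattice prediction

To predict an unmeasured target community c_t: choose the anchor c₀ as the
largest measured subset of c_t (ties → most replicates → lexicographic).
Nodes are all communities S with c₀ ⊆ S ⊆ c_t plus every other measured
subset of c_t. Every single-addition edge (S, S∪{i}) with a fitted FEE
contributes the equation F(S∪{i}) − (1+b_i)F(S) = a_i, weighted by 1/σ_i.
Measured nodes are fixed at their replicate means; the latent values solve
the resulting sparse weighted least-squares system. Properties verified by
tests:

* in-sample targets return the observed mean exactly;
* a single missing strain reduces to the closed form F(c₀) + a_i + b_i F(c₀);
* the solution is invariant to member ordering and matches a generic
  numerical minimizer of the same weighted objective;
* the raw solution is clipped to [0, 1] (the clip is reported).

### Additive baseline

F_A(c_t) = F({focal}) + Σ_i ΔF_i({focal}) over the non-focal members, using
monoculture and pairwise measurements only. It ignores all background
dependence, and its error grows with community richness while the FEE
model's stays flat — the qualitative signature of strong global (background-
mediated) epistasis.

## 4. Synthetic data generator

### Trees

`simulate_yule_tree` is a hand-written pure-birth simulator (exponential
waiting times, uniform lineage choice), rescaled to height 1. It runs one
extra waiting time beyond the last speciation before fixing the present, so
terminal branches are strictly positive — a chronogram never places a split
exactly at the present, and zero-length cherries would make C singular at
λ = 1. (An off-the-shelf birth–death simulator was rejected for exactly
that artefact: stopping at the n-th birth always leaves a zero-length
cherry.)

### Trait tables and collections

Traits are drawn from MVN(μ, σ²·C(λ)) with per-trait λ sampled from a grid
(default 0, 0.1, …, 1). `simulate_collection` adds strain metadata by
cutting the ultrametric tree at fixed depths below the tips (marker 0.025,
species 0.175, genus 0.45 on a height-1 tree, via single-linkage at
cophenetic threshold 2×depth), so marker ⊆ species ⊆ genus partitions are
nested by construction.

### Community-function landscapes

Ground truth is built bottom-up by a permutation-symmetric FEE recursion:

    F*(S) = clip₀¹( mean over i∈S of [ (1+b_i)·F*(S\{i}) + a_i ] + N(0, τ²) )

Lattice noise τ and measurement noise ε (triplicate observations) are
seeded per composition via a CRC32 of the canonical member key, so any
community's truth is identical regardless of evaluation order.

Per-strain truths (a_i, b_i) are drawn from qualitative strain classes —
mildly positive contributors (a ∈ [0.10, 0.35], b ∈ [−0.5, 0]), strong
negative interactors (a ∈ [−0.10, 0.05], b ∈ [−1.2, −0.6]), and
fermenter-like focal strains (a ∈ [0.80, 0.95], b ∈ [−1.0, −0.8]) — with
the 10-strain pool split half positive / half negative. Uniform draws over
the full (a, b) box were rejected because they push most of the lattice
into clipping at F = 1.

**A known, deliberate property:** the mean-over-parents recursion is
*exactly* FEE-consistent only when all strains share a fixed point
(a_i/b_i constant). With heterogeneous strains the fitted (a, b) are
effective parameters of the realised landscape, biased relative to the
generating ones even at zero noise — although predictive accuracy remains
r ≈ 0.99. Parameter-recovery tests therefore use shared-fixed-point truths;
landscape-prediction tests use the heterogeneous default.

### Experimental design

The simulated experiment mirrors a realistic consortium campaign over 12
strains (10-strain pool + 2 focal fermenters): 16 base backgrounds of sizes
2–5 dealt by greedy minimum-usage selection (per-strain prevalence within
±1, spread ≤ 20%), each augmented with every pool strain (176 backgrounds),
each assayed alone and with each focal strain (528 assays), plus 12
monocultures and 66 pairwise co-cultures — 606 assays, in triplicate,
versus 2¹² − 1 = 4,095 possible consortia.

### What the generator does *not* emulate

* No chemistry: function is an abstract [0, 1] scalar; no sugar, ethanol,
  or pH dynamics, no time courses, no stuck-fermentation mechanism beyond
  negative-slope strains.
* Trait tables and community landscapes are generated independently; the
  12 community strains are not tips of the 60-strain tree.
* Measurement noise is homoscedastic Gaussian; real assays have
  composition-dependent and batch error structure.
* The FEE residual θ_i(B) is not simulated as strain-specific noise by
  default (`per_strain_noise=False`); lattice noise τ plays that role
  symmetrically.

## 5. Defaults and why

| Parameter | Default | Rationale |
|---|---|---|
| tree height | 1 | puts branch lengths, depth cuts and λ on one scale |
| collection size | 60 × 43 | a realistically sized phenotyping campaign |
| permutations | 199–999 | add-one p-value resolution 0.005–0.001 |
| σ² floor (FEE) | 1e-4 | caps lattice edge weights at 100 on the [0,1] scale |
| τ, ε | 0.01 | ~1% functional noise, typical of replicate assays |
| replicates | 3 | triplicate assays |
| base sizes | 2–5 (→ 2–6 augmented) | spans richness where additivity visibly fails |
| depth cuts | 0.025 / 0.175 / 0.45 | produce ~55 / ~26 / ~13 nested groups on 60 tips |

## 6. Limitations

* λ estimation assumes a single trait optimum (no Ornstein–Uhlenbeck
  attraction) and homogeneous rates across the tree.
* Imputation quality is bounded by local sampling density: strains with
  large PNND are predicted poorly no matter the signal (error correlates
  with PNND, r ≈ 0.5 on synthetic collections).
* The lattice predictor assumes the fitted FEEs extrapolate to unmeasured
  backgrounds; strong higher-order interactions not expressible as
  F(B)-dependence would violate it.
* The permutation test's boundary conservatism costs power for traits with
  weak true signal.
* All accuracy claims in the test suite are statements about the synthetic
  generator, not about any real organism or assay.
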