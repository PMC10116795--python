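# Methods

This note describes the statistical machinery implemented in `krv`: the
kernel RV (KRV) association test between a gene-level genotype kernel and a
community-level microbiome kernel, its covariate adjustment, the analytic
permutation null, the kernel constructions, the simulation engine, and the
two-stage microbiome-GWAS scan.

## 1. The KRV coefficient

Given two symmetric kernel matrices `K` (genotype similarity) and `L`
(microbiome similarity) over the same `n` samples, both are double-centered
with `H = I − 11'/n`:

```
K̃ = H K H,   L̃ = H L H
KRV(K, L) = tr(K̃ L̃) / sqrt( tr(K̃ K̃) · tr(L̃ L̃) )
```

The coefficient lies in `[0, 1]` for positive semi-definite kernels and
equals 1 when `K = L` up to scaling. It measures the alignment between the
two sample-similarity structures: large values mean samples that are
genetically similar also carry similar communities.

## 2. Covariate adjustment

Covariates enter through a design matrix `X` (intercept plus columns such as
ancestry principal components). Let `P⊥ = I − X(X'X)⁻¹X'` be the projection
onto the orthogonal complement of the column space of `X`. The adjusted
coefficient projects both kernels:

```
K* = P⊥ K P⊥,   L* = P⊥ L P⊥
KRV_adj(K, L; X) = tr(K* L*) / sqrt( tr(K* K*) · tr(L* L*) )
```

Because `P⊥` annihilates the constant vector whenever `X` contains an
intercept, `K* = K̃` when `X` is intercept-only and the adjusted coefficient
reduces exactly to the unadjusted one. For linear kernels `K = ZZ'` the
projection is equivalent to residualizing every feature column of `Z` on `X`
first (`P⊥ZZ'P⊥ = (P⊥Z)(P⊥Z)'`), which is the classical residual-based
adjustment.

## 3. The permutation null and its analytic approximation

Significance is assessed against the null hypothesis that the community
profiles are exchangeable across samples given the covariate structure of
the *genotype* side. The reference distribution permutes the raw sample
labels of the phenotype kernel: for a permutation matrix `Π`, the permuted
numerator is

```
T(Π) = tr( K* · P⊥ (Π L Π') P⊥ ) = tr( K* · Π L̃ Π' ),
```

where the second equality holds because `P⊥` is idempotent, `tr(AB)` is
invariant under the cyclic shift, and double-centering commutes with
simultaneous row/column permutation once `K*` is already orthogonal to the
constant vector. The practical consequence is that the null moments must be
computed from the pair `(K*, L̃)` — the projected genotype kernel against
the merely *centered* community kernel — not from `(K*, L*)`.

This distinction matters. Conditioning the null on the doubly-projected pair
`(K*, L*)` treats `P⊥ L P⊥` as a fixed matrix to be relabeled, which keeps
both kernels aligned inside the same covariate-orthogonal subspace under
every permutation and understates the null variance; at `n = 200` with one
strong ancestry covariate this inflates the empirical size of a nominal
0.05-level test to roughly 0.07–0.10. Permuting the raw samples and
re-projecting — which is what `T(Π)` above computes in closed form —
restores nominal size. The package therefore reports the adjusted
coefficient of §2 as the test statistic, while p-values are computed from
the exact permutation moments of `T(Π)`. When a residual association with
`X` remains on the community side, those moments overstate the null spread,
so the test errs in the conservative direction.

The first three moments of `T(Π)` under uniform random permutations have
closed forms in eight spectral invariants of each matrix
(`tr W`, `tr W²`, `tr W³`, `(Σᵢⱼ Wᵢⱼ)`-type sums, row-sum quadratics, …),
derived by Möbius inversion over the partition lattice of index multisets
and validated in the test suite against exhaustive enumeration of all `7!`
permutations. The standardized statistic is then referred to a Pearson
Type III (shifted gamma) distribution matched to that mean, variance and
skewness; the approximation is validated against 10⁵-permutation Monte
Carlo oracles for all six community kernels. A direct Monte-Carlo
permutation test (`permutation_pvalue`) is available as a fallback and
oracle.

## 4. Kernels

**Genotype side.** Linear kernel `K = ZZ'` on minor-allele dosages of the
variants in a gene window, or the IBS kernel
`K_ij = Σ_l (2 − |g_il − g_jl|) / (2m)`. Optional per-variant weights are
supported.

**Microbiome side.** Six kernels, each built as distance → Gower transform
→ PSD correction (`microbiome_kernel`):

- Bray-Curtis dissimilarity on rarefied counts.
- Unweighted UniFrac: branch-length fraction of the tree unique to one
  sample's taxa (presence/absence only).
- Weighted UniFrac (normalized form, values in `[0, 1]`).
- Generalized UniFrac with relative-abundance exponent `α` (default 0.5);
  `α = 1` recovers weighted UniFrac exactly.
- CLR-linear: linear kernel on centered-log-ratio-transformed counts with a
  unit pseudo-count (applied to raw, non-rarefied counts).
- PhILR-linear: linear kernel on balance coordinates from a sequential
  binary partition of the phylogeny (orthonormal contrast basis; optional
  branch-length weighting of contrasts).

The Gower transform maps a distance matrix to a centered inner-product
matrix, `−½ H D² H`; for Euclidean distances this equals the centered Gram
matrix of the underlying points. Negative eigenvalues introduced by
non-Euclidean dissimilarities are clipped to zero.

## 5. Simulation engine

Genotypes: two populations of equal size whose allele frequencies diverge
by `F_ST = 0.1` under a Balding-Nichols model (ancestral frequencies
uniform on (0.1, 0.9), Beta-distributed population frequencies, Bernoulli
haplotypes paired into dosages). 300 variants span a 1 Mb region; five are
guaranteed inside an 8 kb test subregion. The adjustment covariate is the
leading principal component of the centered, scaled genotype matrix, which
separates the two populations.

Microbiome: Dirichlet-multinomial counts over 856 taxa at depth 1000 with
overdispersion θ = 0.01 and a fixed long-tailed mean composition (ranked
log-normal weights). A fixed random bifurcating (coalescent-style) tree
supplies phylogeny for the UniFrac and PhILR kernels.

Confounded null scenarios (no causal variant): **T1** multiplies the counts
of the 10 most common taxa by 1.10 in population A (stochastic rounding,
then re-rarefaction), shifting abundances but not presence/absence; **T2**
adds one count to 10 randomly chosen very rare taxa in population A.
Because population membership drives both allele frequencies and the
community shift, an unadjusted abundance-sensitive test rejects spuriously
while the covariate-adjusted test stays at nominal level — and unweighted
UniFrac remains valid even unadjusted under T1.

Power scenarios add a causal effect of a common subregion variant `g` on
top of T1 confounding: **P1** multiplies taxa ranked 11–20 by abundance by
`1 + c·g`; **P2** applies the same multiplicative effect to the members of
a phylogenetic clade holding ≈10% of the composition; **P3** adds `c·g`
counts to 5 randomly chosen rare taxa. The competitor method is a
covariate-adjusted ordinary-least-squares regression of the top community
kernel principal component on the top genotype-kernel principal component.

## 6. Microbiome GWAS pipeline

Variant QC keeps variants with folded MAF ≥ 0.05 and effective minor-allele
count `N_eff = 2 p̂ (1 − p̂) N v ≥ 30`, where `v` is the imputation-quality
variance ratio (1 for hard calls). Gene sets collect variants within
±10 kb windows around annotated genes.

Stage 1 tests every gene (linear kernel on its variants) against the chosen
community kernel with the adjusted KRV, at a Bonferroni threshold of
`0.05 / #genes`. Overlapping significant gene windows are merged into
regions. Stage 2 tests each variant of the significant regions marginally
(single-variant linear kernel, same adjusted KRV) at `0.05 / #variants`
within the stage-2 family. Calibration is monitored with a genomic
inflation factor computed at an upper p-value quantile (default the 10th
percentile), appropriate when a small fraction of true signals would
distort the median-based factor.

Taxa attribution for a top variant proceeds in two steps: (1) regress each
of the leading community-kernel principal components on the variant dosage
with covariates, Benjamini-Hochberg FDR across components; (2) for
components passing FDR, report taxa whose abundance profile correlates with
the component at `|r| ≥ 0.5` (rarefied counts for distance kernels,
CLR values for log-ratio kernels).
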