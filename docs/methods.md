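# Methods

This note records the statistical model implemented by `qrfcca`, the
numerical choices made where the construction was genuinely open, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Genotype coding and the functional view

A gene's diploid calls are coded as minor-allele counts (2 = minor
homozygote, 1 = heterozygote, 0 = major homozygote). The coding always
counts the *minor* allele: columns whose designated allele exceeds
frequency 0.5 are flipped, which keeps the rare/common partition by MAF
coherent downstream. Missing calls are imputed to the per-SNP observed
mean rounded to the nearest of {0, 1, 2}; monomorphic columns are
dropped, and a gene left with no polymorphic column is rejected as
degenerate. Physical positions are mapped affinely to [0, 1].

The genotype profile of individual *i* is then treated as a function
`x_i(t)` of rescaled position. The FPCA is the classic two-step
construction:

1. each profile is smoothed by least squares onto an orthonormal
   Fourier basis evaluated at the SNP positions (`n_basis = min(m, 25)`
   by default; the basis count is a bias/variance knob, and 25 modes
   resolve LD features down to ~1/12 of the gene length);
2. the sample covariance of the coefficient vectors is
   eigen-decomposed. Because the Fourier system is orthonormal on
   [0, 1], the basis Gram matrix is the identity and the coefficient
   eigenvectors are directly the eigenfunction coefficients.

Components are retained up to a cumulative variance proportion
(`variance_target`, default 0.90; a hard cap is available). Scores are
quadrature inner products: the centered profile is linearly interpolated
to an equally spaced 500-point grid and integrated against each
eigenfunction by the trapezoid rule. For trigonometric integrands of
frequency far below the grid resolution the trapezoid rule is exact to
machine precision, which is why the orthonormality of retained
eigenfunctions holds at ~1e-15 under the same quadrature.

No roughness penalty is applied (the least-squares projection onto a
truncated basis already smooths); a genuinely penalized variant would
change little at these basis sizes. Single-SNP genes bypass the FPCA and
route to the single-SNP method.

## Quadratically regularized reduction

For a data matrix A (FPC scores, raw dosages, or traits), the penalized
factorization

    min_{G,H} ‖A − GH‖²_F + μ‖G‖²_F + μ‖H‖²_F

is solved by soft-thresholding the singular values, τ_j = (λ_j − μ)₊,
with G = U diag(τ)^{1/2} kept for the surviving components. Shrinkage
raises the share of the leading singular values monotonically in μ
(property-tested), which is the mechanism that concentrates the
association evidence in few canonical directions.

μ is selected from the spectrum itself: the singular value whose tail
sum (that value through the smallest) is nearest to `tail_fraction`
(default 0.20) of the total singular-value mass; ties break toward the
smaller singular value (less shrinkage), and `tail_fraction = 0`
disables shrinkage entirely. An input whose spectrum collapses entirely
(e.g. a single singular value, which the tail rule then selects as μ)
yields a zero-column reduction and is reported as degenerate.

Inside the pipeline, matrices are column-centered before the SVD so the
reduction acts on variation — the covariance convention the CCA uses.
The bare `svd_factorize` entry point defaults to no centering so that it
computes the plain best rank-l approximation of its argument.

## The canonical correlation test

With reduced views X (n×p) and Y (n×k), canonical correlations are the
singular values of `K = Σ_xx^{-1/2} Σ_xy Σ_yy^{-1/2}` with sample
covariances; inverse square roots go through symmetric
eigen-decomposition with an eigenvalue floor of 1e-12, and a ridge of
1e-8·trace/dim is added (and flagged) when a covariance block is
numerically singular. Correlations are clipped to 1 − 1e-12 to keep the
log-likelihood finite; a clipped (saturated) correlation is flagged.

The likelihood-ratio statistic has three forms:

- `plain`:               T = −N Σ log(1 − λ_i²)
- `bartlett`:            T = −[N − (q + 3)/2] Σ log(1 − λ_i²), q = min(p, k)
- `classical_bartlett`:  T = −[N − (p + k + 3)/2] Σ log(1 − λ_i²)

all referred to χ² with p·k degrees of freedom, where p and k are the
*post-reduction* dimensions. The `bartlett` multiplier reproduces one
printed rendering of the correction; the classical multiplier is
Bartlett's (1939) actual large-sample correction for this statistic.
The default (`auto`) uses the plain form below N = 500 and the classical
correction above, because at the dimensions this pipeline produces
(p ≈ 16, k ≈ 9 at n = 500) only the classical correction keeps the
empirical size near nominal — the suite measures ~0.059 for classical
vs ~0.080 for the (q+3)/2 form at nominal 0.05. The association measure
r = Σ λ_i² = Tr(R²) doubles as a heritability estimate: with a purely
additive genetic trait, r recovers h² (tested at n = 5,000 within 0.03).

Degenerate genes report p-value 1 with a flag rather than NA so that
Bonferroni accounting over a scan stays well defined.

## Phenotype preparation

Traits can be transformed by the rank-based inverse normal transform,
Φ⁻¹((rank − 3/8)/(n + 1/4)) with average ranks for ties (Blom offsets;
the (r − 1/2)/n variant is a parameter), and residualized on shared
covariates by one multivariate least-squares fit with an implicit
intercept (collinear covariate columns are dropped with a warning).
Population-structure principal components are supplied as covariate
columns; their computation is out of scope.

## Synthetic data

The generator emulates the evaluation conditions without any external
downloads:

- **Haplotype pool.** 20,000 haplotypes per gene from a latent-Gaussian
  AR(1) copula (autocorrelation `ld_rho = 0.5`): SNP j is carried when
  the latent variable exceeds Φ⁻¹(1 − MAF_j). Target MAFs are
  log-uniform on (0.0005, 0.01) for the 600 rare SNPs (so very rare
  variants are represented) and uniform on (0.01, 0.5) for the 400
  common SNPs; rare and common positions are interleaved uniformly
  along a 100 kb region. Diploid study samples are drawn from the pool
  anew for each replicate, mirroring a population pool from which
  samples of size n are repeatedly taken. The pool size bounds the
  resolution of very rare MAFs at 1/20,000; at the sample sizes used
  (n ≤ 2,000) this is immaterial.
- **Null traits.** Pairwise correlations drawn uniformly from the
  regime band (low 0.1–0.2, moderate 0.2–0.4, high 0.4–0.7), the matrix
  repaired to positive definite by eigenvalue flooring at 1e-6 and
  diagonal rescaling when needed (the repair is flagged; for K ≤ 15 and
  these bands repairs are rare).
- **Power model.** Y = X(α∘b)diag(t) + E with b_ij ~ Bernoulli(0.02)
  per SNP-trait pair, t_i ~ Bernoulli(0.6/0.4/0.2) for scenarios 1/2/3,
  h_i² ~ U(0.005, 0.015), and sd(α_ij) = √(h_i²/MAF_j) — the
  frequency-inverse effect convention (`sqrt_h2_over_maf`). An
  alternative `printed_matrix` convention (α_ij ~ N(0, h_i²·MAF_j)
  rescaled again by diag(h²)) is implemented for sensitivity analysis;
  the two are never mixed. Residuals have variances 1 − h_i² and the
  regime correlations. The truth record carries b, t, h², the effect
  matrix and the realized genetic component, sufficient to recompute
  realized heritabilities.

What the generator does *not* emulate: real haplotype block structure
(recombination hotspots, allele-frequency–dependent LD), population
stratification, relatedness, genotyping error, and non-normal trait
distributions. Calibration and power results under this generator
therefore validate the statistical machinery under its stated
assumptions; they do not by themselves certify behavior on real cohort
data, where the inverse-normal transform and PC covariates carry the
burden the generator omits.

Experiments use counter-based sub-seeding (`SeedSequence(seed,
spawn_key=(stream, replicate))`), so every replicate has an independent
stream, methods compared within a replicate see identical data (paired
comparisons), and all results are reproducible from (design, seed).

## Problem sizes

Monte-Carlo runs use 2,000 null replicates per type-I cell (5,000 at
nominal 0.01) and 500 power replicates, with the haplotype pool fixed
per experiment and individuals resampled per replicate — sizes chosen so
a full calibration cell resolves a 0.05 rate to ±0.015 at 3 binomial
SEs. At these sizes one type-I cell takes roughly 1–4 minutes on one
CPU.

## Known limitations

- The χ²_{pk} reference is asymptotic; even with the classical Bartlett
  correction the empirical size at n = 500 with ~140 degrees of freedom
  sits near 0.055–0.06 at nominal 0.05. Exact F-approximations (Rao)
  would calibrate better but are outside the implemented scope.
- The μ-selection rule reads "accounts for 20%" as nearest-to-20%; the
  alternative "largest tail ≤ 20%" reading would shrink slightly more.
  The choice is a config field, not a constant.
- FPCA assumes SNP density high enough that a smooth profile is a
  sensible object; for genes with < ~5 SNPs the functional view adds
  little over the raw-dosage methods, which remain available.
- The VCF reader handles biallelic SNPs only; multiallelic records are
  skipped with a warning rather than split.
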