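"""Synthetic genotype and phenotype generators for null and power studies.

Genotypes
---------
A gene is emulated by a pool of haplotypes drawn from a latent-Gaussian
AR(1) copula: SNP j carries a target minor allele frequency ``MAF_j``
(600 rare SNPs with MAF log-uniform in (0.0005, 0.01) and 400 common
SNPs with MAF uniform above 0.01 by default), and a latent AR(1) process
with autocorrelation ``ld_rho`` is thresholded at ``Phi^{-1}(1 - MAF_j)``
so neighbouring SNPs are in linkage disequilibrium.  Diploid individuals
are formed by summing two haplotypes sampled from the pool, mirroring a
population pool from which study samples of size n are drawn anew for
each replicate.

Phenotypes
----------
Under the null, K traits are multivariate normal with unit variances and
pairwise residual correlations drawn uniformly from a regime band: low
(0.1, 0.2), moderate (0.2, 0.4) or high (0.4, 0.7).  Under the
alternative, the additive model

    Y = X (alpha o b) diag(t) + E

gates each SNP-trait pair as causal with probability 0.02 (``b``), each
trait as genetically affected with a per-scenario probability ``t``
(0.6 / 0.4 / 0.2 for scenarios 1 / 2 / 3), draws per-trait heritability
``h^2 ~ U(0.005, 0.015)``, and sets effect sizes inversely related to
allele frequency, ``sd(alpha_ij) = sqrt(h_i^2 / MAF_j)``.  Residuals
have variances ``1 - h_i^2`` and the regime correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .genotypes import GenotypeBlock, code_genotypes
from .scan import ScanConfig, gene_test

__all__ = [
    "SimulationDesign",
    "HaplotypePool",
    "build_haplotype_pool",
    "sample_genotype_block",
    "simulate_genotypes",
    "draw_residual_correlation",
    "simulate_null_phenotypes",
    "simulate_power_phenotypes",
    "run_type1_experiment",
    "run_power_experiment",
]

CORRELATION_REGIMES = {
    "low": (0.1, 0.2),
    "moderate": (0.2, 0.4),
    "high": (0.4, 0.7),
}

SCENARIO_TRAIT_PROB = {1: 0.6, 2: 0.4, 3: 0.2}

EFFECT_CONVENTIONS = ("sqrt_h2_over_maf", "printed_matrix")


@dataclass
class SimulationDesign:
    """All parameters of the generative models for one experiment."""

    n_samples: int = 1000
    n_snps: int = 1000
    n_rare: int = 600
    n_common: int = 400
    rare_maf_range: tuple = (0.0005, 0.01)
    common_maf_range: tuple = (0.01, 0.5)
    ld_rho: float = 0.5
    n_traits: int = 15
    correlation_regime: str = "high"
    scenario: int = 1
    causal_prob: float = 0.02
    h2_range: tuple = (0.005, 0.015)
    effect_convention: str = "sqrt_h2_over_maf"
    n_haplotypes: int = 20000
    region_length: int = 100000
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_snps != self.n_rare + self.n_common:
            raise ValueError("n_snps must equal n_rare + n_common")
        if self.correlation_regime not in CORRELATION_REGIMES:
            raise ValueError(f"unknown regime {self.correlation_regime!r}")
        if self.scenario not in SCENARIO_TRAIT_PROB:
            raise ValueError("scenario must be 1, 2 or 3")
        if self.effect_convention not in EFFECT_CONVENTIONS:
            raise ValueError(f"unknown effect convention {self.effect_convention!r}")
        for lo, hi in (self.rare_maf_range, self.common_maf_range):
            if not (0 < lo < hi <= 0.5):
                raise ValueError("MAF ranges must satisfy 0 < lo < hi <= 0.5")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HaplotypePool:
    """Fixed pool of simulated haplotypes for one gene."""

    haplotypes: np.ndarray  # H x m, int8 in {0, 1}
    positions: np.ndarray
    target_maf: np.ndarray
    is_rare: np.ndarray  # by design (target MAF <= rare_maf_range[1])

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


def _draw_target_mafs(design: SimulationDesign, rng) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = design.rare_maf_range
    rare = np.exp(rng.uniform(np.log(lo), np.log(hi), design.n_rare))
    clo, chi = design.common_maf_range
    common = rng.uniform(clo, chi, design.n_common)
    maf = np.concatenate([rare, common])
    is_rare = np.concatenate(
        [np.ones(design.n_rare, bool), np.zeros(design.n_common, bool)]
    )
    perm = rng.permutation(design.n_snps)  # interleave rare and common along the gene
    return maf[perm], is_rare[perm]


def build_haplotype_pool(design: SimulationDesign, rng) -> HaplotypePool:
    """Generate the AR(1)-copula haplotype pool for one gene."""
    rng = np.random.default_rng(rng)
    maf, is_rare = _draw_target_mafs(design, rng)
    m = design.n_snps
    H = design.n_haplotypes
    rho = design.ld_rho
    if not -1 < rho < 1:
        raise ValueError("ld_rho must lie in (-1, 1)")
    z = np.empty((H, m))
    z[:, 0] = rng.standard_normal(H)
    if m > 1:
        innov = rng.standard_normal((H, m - 1)) * np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    thresholds = stats.norm.ppf(1.0 - maf)
    haps = (z > thresholds[None, :]).astype(np.int8)
    positions = np.linspace(
        1, design.region_length, m
    ).astype(np.int64)
    return HaplotypePool(
        haplotypes=haps, positions=positions, target_maf=maf, is_rare=is_rare
    )


def sample_genotype_block(
    pool: HaplotypePool,
    n: int,
    rng,
    gene_id: str = "simulated_gene",
    variant_mask=None,
) -> GenotypeBlock:
    """Draw n diploid individuals from the pool (two haplotypes each).

    ``variant_mask`` restricts to a SNP subset (e.g. the design-rare
    variants) before coding; monomorphic-in-sample columns are dropped
    by the coding step.
    """
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, pool.haplotypes.shape[0], size=(2, n))
    dosage = pool.haplotypes[idx[0]] + pool.haplotypes[idx[1]]
    positions = pool.positions
    if variant_mask is not None:
        dosage = dosage[:, variant_mask]
        positions = positions[variant_mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return code_genotypes(dosage, positions, gene_id=gene_id)


def simulate_genotypes(design: SimulationDesign, seed=None) -> GenotypeBlock:
    """One-call genotype simulation: build a pool, then sample n diploids."""
    root = np.random.SeedSequence(design.seed if seed is None else seed)
    pool_ss, sample_ss = root.spawn(2)
    pool = build_haplotype_pool(design, np.random.default_rng(pool_ss))
    return sample_genotype_block(
        pool, design.n_samples, np.random.default_rng(sample_ss)
    )


def draw_residual_correlation(K: int, bounds, rng) -> tuple[np.ndarray, bool]:
    """Symmetric correlation matrix with off-diagonals uniform in ``bounds``.

    Repaired to the nearest positive-definite matrix by eigenvalue
    flooring at 1e-6 (then rescaled to unit diagonal); the flag reports
    whether a repair was needed.
    """
    rng = np.random.default_rng(rng)
    lo, hi = bounds
    R = np.eye(K)
    iu = np.triu_indices(K, 1)
    vals = rng.uniform(lo, hi, iu[0].size)
    R[iu] = vals
    R[(iu[1], iu[0])] = vals
    evals, evecs = np.linalg.eigh(R)
    repaired = bool(evals[0] < 1e-6)
    if repaired:
        evals = np.maximum(evals, 1e-6)
        R = (evecs * evals) @ evecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R, repaired


def simulate_null_phenotypes(
    n: int,
    K: int,
    regime: str = "high",
    rng=None,
    heritabilities=None,
):
    """K traits, multivariate normal, independent of any genotypes.

    With ``heritabilities`` given, trait variances are ``1 - h_i^2`` and
    correlations are scaled accordingly (the residual model of the power
    design); otherwise variances are 1.
    """
    rng = np.random.default_rng(rng)
    R, _ = draw_residual_correlation(K, CORRELATION_REGIMES[regime], rng)
    if heritabilities is not None:
        sd = np.sqrt(1.0 - np.asarray(heritabilities, dtype=float))
        cov = R * np.outer(sd, sd)
    else:
        cov = R
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(K))
    return rng.standard_normal((n, K)) @ L.T


def simulate_power_phenotypes(
    block: GenotypeBlock,
    design: SimulationDesign,
    rng=None,
):
    """Traits under the additive genetic model with causal gating.

    Returns ``(Y, truth)`` where ``truth`` records the causal gating
    matrix ``b``, the trait gates ``t``, the heritabilities, the effect
    matrix and the realized genetic component.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(block.dosage, dtype=float)
    maf = np.asarray(block.maf, dtype=float)
    n, q = X.shape
    K = design.n_traits
    h2 = rng.uniform(*design.h2_range, K)
    t = rng.binomial(1, SCENARIO_TRAIT_PROB[design.scenario], K)
    b = rng.binomial(1, design.causal_prob, (q, K))
    if design.effect_convention == "sqrt_h2_over_maf":
        sd = np.sqrt(h2[None, :] / maf[:, None])
        effects = rng.standard_normal((q, K)) * sd * b * t[None, :]
    else:  # printed_matrix: alpha ~ N(0, h_i^2 MAF_j), then diag(h^2) again
        sd = np.sqrt(h2[None, :] * maf[:, None])
        effects = rng.standard_normal((q, K)) * sd * b * t[None, :] * h2[None, :]
    genetic = X @ effects
    eps = simulate_null_phenotypes(
        n, K, design.correlation_regime, rng, heritabilities=h2
    )
    truth = {
        "b": b,
        "t": t,
        "h2": h2,
        "effects": effects,
        "genetic_component": genetic,
        "causal_snps": np.flatnonzero((b * t[None, :]).any(axis=1)),
        "affected_traits": np.flatnonzero(t.astype(bool) & b.any(axis=0)),
    }
    return genetic + eps, truth


# ----------------------------------------------------------------------
# Experiments


def _replicate_seed_seq(seed: int, stream: int, replicate: int) -> np.random.SeedSequence:
    """Counter-based sub-seeding: one independent stream per replicate,
    shared across methods so comparisons are paired."""
    return np.random.SeedSequence(entropy=seed, spawn_key=(stream, replicate))


def _scan_config(design: SimulationDesign, method: str) -> ScanConfig:
    # class restriction is handled upstream via the pool mask
    return ScanConfig(method=method, variant_class="all", seed=design.seed)


def _class_mask(pool: HaplotypePool, variant_class: str):
    if variant_class == "rare":
        return pool.is_rare
    if variant_class == "common":
        return ~pool.is_rare
    return None


def run_type1_experiment(
    design: SimulationDesign,
    methods=("qrfcca",),
    nominal_levels=(0.05, 0.01),
    sample_sizes=None,
    variant_class: str = "rare",
    n_replicates: int | None = None,
    seed: int | None = None,
    progress: bool = False,
):
    """Empirical type-I error rates under the null generative model.

    For each replicate a fresh sample of individuals is drawn from the
    (fixed) haplotype pool and traits are simulated independently of the
    genotypes; the rejection proportion at each nominal level is
    tabulated per method and sample size with its binomial standard
    error.  Returns a tidy DataFrame.
    """
    import pandas as pd

    seed = design.seed if seed is None else seed
    n_rep = design.n_replicates if n_replicates is None else n_replicates
    sizes = [design.n_samples] if sample_sizes is None else list(sample_sizes)
    pool = build_haplotype_pool(
        design, np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    )
    mask = _class_mask(pool, variant_class)
    rows = []
    for n in sizes:
        pvals = {m: np.empty(n_rep) for m in methods}
        for r in range(n_rep):
            rng = np.random.default_rng(_replicate_seed_seq(seed, 1, r + n * 100003))
            block = sample_genotype_block(pool, n, rng, variant_mask=mask)
            Y = simulate_null_phenotypes(
                n, design.n_traits, design.correlation_regime, rng
            )
            for m in methods:
                res = gene_test(block, Y, _scan_config(design, m))
                pvals[m][r] = res.p_value
        for m in methods:
            for level in nominal_levels:
                rate = float(np.mean(pvals[m] <= level))
                rows.append(
                    {
                        "method": m,
                        "sample_size": n,
                        "variant_class": variant_class,
                        "nominal_level": level,
                        "rejection_rate": rate,
                        "se": float(np.sqrt(level * (1 - level) / n_rep)),
                        "n_replicates": n_rep,
                    }
                )
    return pd.DataFrame(rows)


def run_power_experiment(
    design: SimulationDesign,
    methods=("qrfcca",),
    sample_sizes=None,
    alpha: float = 0.05,
    variant_class: str = "all",
    n_replicates: int | None = None,
    seed: int | None = None,
):
    """Empirical power under the additive power model.

    Causal SNPs are drawn among the tested variants each replicate; the
    rejection proportion at ``alpha`` is tabulated per method and sample
    size.  Returns a tidy DataFrame.
    """
    import pandas as pd

    seed = design.seed if seed is None else seed
    n_rep = design.n_replicates if n_replicates is None else n_replicates
    sizes = [design.n_samples] if sample_sizes is None else list(sample_sizes)
    pool = build_haplotype_pool(
        design, np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    )
    mask = _class_mask(pool, variant_class)
    rows = []
    for n in sizes:
        reject = {m: np.zeros(n_rep, dtype=bool) for m in methods}
        for r in range(n_rep):
            rng = np.random.default_rng(_replicate_seed_seq(seed, 2, r + n * 100003))
            block = sample_genotype_block(pool, n, rng, variant_mask=mask)
            Y, _ = simulate_power_phenotypes(block, design, rng)
            for m in methods:
                res = gene_test(block, Y, _scan_config(design, m))
                reject[m][r] = res.p_value <= alpha
        for m in methods:
            power = float(np.mean(reject[m]))
            rows.append(
                {
                    "method": m,
                    "sample_size": n,
                    "variant_class": variant_class,
                    "alpha": alpha,
                    "power": power,
                    "se": float(np.sqrt(max(power * (1 - power), 1e-12) / n_rep)),
                    "n_replicates": n_rep,
                }
            )
    return pd.DataFrame(rows)
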