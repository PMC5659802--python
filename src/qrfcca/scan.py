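"""Genome-scan pipeline: per-gene testing, variant-class partitioning,
multiple-testing correction, and QQ tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genotypes import DegenerateGeneError, GenotypeBlock, code_genotypes
from .model import METHODS, MultiTraitAssociation

__all__ = [
    "ScanConfig",
    "GeneResult",
    "variant_class_mask",
    "gene_test",
    "genome_scan",
    "bonferroni_threshold",
    "qq_table",
]

VARIANT_CLASSES = ("rare", "common", "all")


@dataclass
class ScanConfig:
    """Configuration of a genome scan or simulation experiment.

    MAF cutoffs follow the sequencing-study convention: rare means
    MAF <= ``rare_maf_max`` (default 0.01) and common means
    MAF >= ``common_maf_min`` (default 0.05, leaving 0.01-0.05
    unassigned); ``all`` keeps every polymorphic variant.
    """

    method: str = "qrfcca"
    variant_class: str = "all"
    rare_maf_max: float = 0.01
    common_maf_min: float = 0.05
    variance_target: float = 0.90
    tail_fraction: float = 0.20
    n_basis: int | None = None
    max_fpcs: int | None = None
    statistic_form: str = "auto"
    alpha: float = 0.05
    transform_phenotypes: bool = False
    covariate_columns: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if not self.rare_maf_max < self.common_maf_min:
            raise ValueError("rare_maf_max must be below common_maf_min")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneResult:
    """One row of a genome-scan results table."""

    gene_id: str
    n_snps_used: int
    p_dim: int
    k_dim: int
    statistic: float
    df: int
    p_value: float
    significant_after_bonferroni: bool = False
    flags: str = ""
    chrom: str = ""
    start: int = -1


def variant_class_mask(maf, config: ScanConfig) -> np.ndarray:
    """Boolean mask of SNPs belonging to the configured variant class."""
    maf = np.asarray(maf, dtype=float)
    if config.variant_class == "rare":
        return maf <= config.rare_maf_max
    if config.variant_class == "common":
        return maf >= config.common_maf_min
    return np.ones(maf.size, dtype=bool)


def gene_test(
    block: GenotypeBlock, Y, config: ScanConfig, covariates=None
) -> GeneResult:
    """Test one gene, honoring the variant-class restriction.

    Degenerate genes (no qualifying variants or a reduction collapsing to
    zero columns) return p-value 1 with a flag rather than NA so that
    Bonferroni counting stays well defined.
    """
    try:
        sub = block.restrict(variant_class_mask(block.maf, config))
    except DegenerateGeneError:
        return GeneResult(
            gene_id=block.gene_id,
            n_snps_used=0,
            p_dim=0,
            k_dim=0,
            statistic=0.0,
            df=0,
            p_value=1.0,
            flags="degenerate",
        )
    method = config.method
    if sub.n_snps == 1 and method in ("qrfcca", "qrmcca"):
        method = "qrscca"
    model = MultiTraitAssociation(
        Y,
        sub,
        method=method,
        variance_target=config.variance_target,
        tail_fraction=config.tail_fraction,
        n_basis=config.n_basis,
        max_fpcs=config.max_fpcs,
        statistic_form=config.statistic_form,
        covariates=covariates,
        transform_phenotypes=config.transform_phenotypes,
    )
    res = model.fit()
    return GeneResult(
        gene_id=block.gene_id,
        n_snps_used=res.n_snps_used,
        p_dim=res.p_dim,
        k_dim=res.k_dim,
        statistic=res.statistic,
        df=res.df,
        p_value=res.p_value,
        flags=",".join(res.flags),
    )


def genome_scan(blocks, phenotypes: pd.DataFrame, config: ScanConfig) -> pd.DataFrame:
    """Run ``gene_test`` over an iterable of gene blocks.

    ``phenotypes`` is a sample-indexed DataFrame; trait columns are all
    columns not named in ``config.covariate_columns``.  Each block's rows
    are aligned to the phenotype index by sample id.  Returns a tidy
    results table sorted by (chrom, start, gene_id) with a Bonferroni
    significance column at ``config.alpha``.
    """
    rows = []
    covar_cols = list(config.covariate_columns)
    trait_cols = [c for c in phenotypes.columns if c not in covar_cols]
    if not trait_cols:
        raise ValueError("no trait columns available")
    for block, meta in blocks:
        shared = [s for s in block.sample_ids if s in phenotypes.index]
        if len(shared) < 10:
            raise ValueError(
                f"gene {block.gene_id}: fewer than 10 samples shared with phenotypes"
            )
        order = {s: i for i, s in enumerate(block.sample_ids)}
        idx = np.array([order[s] for s in shared])
        # recode on the shared-sample subset so MAFs (and monomorphic
        # drops) reflect the samples actually tested
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub_block = code_genotypes(
                    block.dosage[idx],
                    block.positions,
                    sample_ids=np.asarray(shared),
                    gene_id=block.gene_id,
                )
        except DegenerateGeneError:
            rows.append(
                asdict(
                    GeneResult(
                        gene_id=block.gene_id,
                        n_snps_used=0,
                        p_dim=0,
                        k_dim=0,
                        statistic=0.0,
                        df=0,
                        p_value=1.0,
                        flags="degenerate",
                        chrom=str(meta.get("chrom", "")),
                        start=int(meta.get("start", -1)),
                    )
                )
            )
            continue
        pheno = phenotypes.loc[shared]
        covar = pheno[covar_cols].to_numpy(float) if covar_cols else None
        result = gene_test(sub_block, pheno[trait_cols], config, covariates=covar)
        result.chrom = str(meta.get("chrom", ""))
        result.start = int(meta.get("start", -1))
        rows.append(asdict(result))
    table = pd.DataFrame(rows)
    if len(table):
        threshold = bonferroni_threshold(len(table), config.alpha)
        table["significant_after_bonferroni"] = table["p_value"] <= threshold
        table = table.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)
    return table


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def qq_table(p_values, band: bool = False) -> pd.DataFrame:
    """Expected vs observed -log10 p-value pairs for a QQ plot.

    Observed p-values are sorted ascending and paired with the uniform
    quantiles (i - 0.5)/n.  With ``band=True`` a 95% band from the beta
    order-statistic law is added.  Zero p-values are clamped to the
    smallest positive float and flagged.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("need at least one finite p-value")
    clamped = p <= 0
    p = np.where(clamped, np.finfo(float).tiny, p)
    order = np.argsort(p)
    obs = -np.log10(p[order])
    n = p.size
    ranks = np.arange(1, n + 1)
    expected = -np.log10((ranks - 0.5) / n)
    out = pd.DataFrame(
        {
            "expected": expected,
            "observed": obs,
            "clamped": clamped[order],
        }
    )
    if band:
        from scipy import stats

        lo = stats.beta.ppf(0.025, ranks, n - ranks + 1)
        hi = stats.beta.ppf(0.975, ranks, n - ranks + 1)
        out["band_low"] = -np.log10(hi)
        out["band_high"] = -np.log10(lo)
    return out
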