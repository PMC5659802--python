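"""Gene-level multi-phenotype association models.

The central object is :class:`MultiTraitAssociation`, a model built from
a phenotype matrix (``endog``) and a gene's genotypes, whose ``fit()``
returns a :class:`MultiTraitAssociationResults` carrying the canonical
correlations, the association measure r, the likelihood-ratio statistic
with its chi-square degrees of freedom and p-value, and a ``summary()``
table.

Method routing (the CCA family):

========  ============================================================
qrfcca    FPCA scores -> regularized reduction of both views -> CCA
fcca      FPCA scores -> CCA (no regularized reduction)
cca       raw dosage -> CCA
qrmcca    regularized reduction of raw dosage and phenotypes -> CCA
qrscca    single SNP vs regularized-reduced phenotypes -> CCA
========  ============================================================

Degrees of freedom are always ``p_dim * k_dim`` for the post-reduction
view dimensions.  A gene whose reduction collapses to zero columns is
reported as degenerate with p-value 1 by convention so that
multiple-testing counts stay well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cca import CCATestResult, canonical_correlations, lrt_statistic
from .factorization import qr_reduce
from .fpca import fit_fpca
from .genotypes import DegenerateGeneError, GenotypeBlock
from .transforms import adjust_covariates, inverse_normal_transform

__all__ = ["MultiTraitAssociation", "MultiTraitAssociationResults", "METHODS"]

METHODS = ("qrfcca", "fcca", "cca", "qrmcca", "qrscca")


@dataclass
class MultiTraitAssociationResults:
    """Fit results of a gene-level multi-phenotype association test."""

    method: str
    statistic: float
    df: int
    p_value: float
    canonical_correlations: np.ndarray
    association_r: float
    wilks_lambda: float
    statistic_form: str
    p_dim: int
    k_dim: int
    nobs: int
    n_snps_used: int
    n_fpcs: int | None
    flags: list = field(default_factory=list)
    model: "MultiTraitAssociation | None" = None

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags

    def summary(self) -> str:
        """Plain-text summary table of the fitted test."""
        lines = [
            "Multi-phenotype gene association test".center(58),
            "=" * 58,
            f"{'Method:':<24}{self.method.upper():>34}",
            f"{'No. observations:':<24}{self.nobs:>34}",
            f"{'SNPs used:':<24}{self.n_snps_used:>34}",
        ]
        if self.n_fpcs is not None:
            lines.append(f"{'FPCs retained:':<24}{self.n_fpcs:>34}")
        lines += [
            f"{'Genotype-view dim (p):':<24}{self.p_dim:>34}",
            f"{'Phenotype-view dim (k):':<24}{self.k_dim:>34}",
            f"{'Statistic form:':<24}{self.statistic_form:>34}",
            "-" * 58,
            f"{'LRT statistic:':<24}{self.statistic:>34.4f}",
            f"{'Degrees of freedom:':<24}{self.df:>34}",
            f"{'P-value:':<24}{self.p_value:>34.4g}",
            f"{'Association r:':<24}{self.association_r:>34.4f}",
            f"{'Wilks lambda:':<24}{self.wilks_lambda:>34.4f}",
        ]
        ccs = ", ".join(f"{c:.3f}" for c in self.canonical_correlations[:6])
        if self.canonical_correlations.size > 6:
            ccs += ", ..."
        lines.append(f"{'Canonical corr.:':<24}{ccs:>34}")
        if self.flags:
            lines.append(f"{'Flags:':<24}{', '.join(self.flags):>34}")
        lines.append("=" * 58)
        return "\n".join(lines)


class MultiTraitAssociation:
    """Association of a gene's variants with multiple correlated traits.

    Parameters
    ----------
    endog : array-like or DataFrame, shape (n, k)
        Phenotype matrix (one trait per column).
    genotypes : GenotypeBlock or array-like, shape (n, m)
        Coded minor-allele dosages for the gene.  A plain array is only
        accepted for the non-functional methods (``cca``, ``qrmcca``,
        ``qrscca``).
    method : str
        One of ``qrfcca``, ``fcca``, ``cca``, ``qrmcca``, ``qrscca``.
    variance_target : float
        Cumulative variance proportion retained by the FPCA.
    tail_fraction : float
        Singular-value tail mass that sets the shrinkage penalty mu.
    n_basis : int, optional
        Fourier basis size for the FPCA (default ``min(m, 25)``).
    max_fpcs : int, optional
        Hard cap on the number of retained FPCs.
    statistic_form : str
        ``plain``, ``bartlett``, ``classical_bartlett`` or ``auto``.
    covariates : array-like, shape (n, c), optional
        Shared covariates; traits are residualized on them before testing.
    transform_phenotypes : bool
        Apply the rank-based inverse normal transform to each trait.
    """

    def __init__(
        self,
        endog,
        genotypes,
        method: str = "qrfcca",
        variance_target: float = 0.90,
        tail_fraction: float = 0.20,
        n_basis: int | None = None,
        max_fpcs: int | None = None,
        statistic_form: str = "auto",
        covariates=None,
        transform_phenotypes: bool = False,
    ):
        method = method.lower()
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        if isinstance(endog, pd.DataFrame):
            self.trait_names = list(endog.columns)
            endog = endog.to_numpy(dtype=float)
        else:
            endog = np.asarray(endog, dtype=float)
            if endog.ndim == 1:
                endog = endog[:, None]
            self.trait_names = [f"y{i}" for i in range(endog.shape[1])]
        if isinstance(genotypes, GenotypeBlock):
            self.block = genotypes
            dosage = genotypes.dosage
        else:
            self.block = None
            dosage = np.asarray(genotypes, dtype=float)
            if dosage.ndim == 1:
                dosage = dosage[:, None]
            if method in ("qrfcca", "fcca"):
                raise ValueError(
                    f"method {method!r} needs a GenotypeBlock with SNP positions"
                )
        if endog.shape[0] != dosage.shape[0]:
            raise ValueError("endog and genotypes must share the sample dimension")
        self.endog = endog
        self.dosage = dosage
        self.method = method
        self.variance_target = variance_target
        self.tail_fraction = tail_fraction
        self.n_basis = n_basis
        self.max_fpcs = max_fpcs
        self.statistic_form = statistic_form
        self.covariates = None if covariates is None else np.asarray(covariates, float)
        self.transform_phenotypes = transform_phenotypes
        self.nobs = endog.shape[0]

    @classmethod
    def from_dataframes(
        cls,
        phenotypes: pd.DataFrame,
        block: GenotypeBlock,
        trait_columns=None,
        covariate_columns=None,
        **kwargs,
    ) -> "MultiTraitAssociation":
        """Build a model from a sample-by-trait DataFrame and a gene block.

        Rows of ``phenotypes`` are aligned to ``block.sample_ids`` (the
        index must contain every block sample).
        """
        pheno = phenotypes.loc[list(block.sample_ids)]
        traits = trait_columns or [
            c for c in pheno.columns if c not in (covariate_columns or [])
        ]
        covar = None
        if covariate_columns:
            covar = pheno[list(covariate_columns)].to_numpy(dtype=float)
        return cls(pheno[list(traits)], block, covariates=covar, **kwargs)

    # ------------------------------------------------------------------
    def _phenotype_view(self, flags: list) -> np.ndarray:
        Y = self.endog
        if self.transform_phenotypes:
            Y = np.column_stack([inverse_normal_transform(col) for col in Y.T])
        if self.covariates is not None:
            Y = adjust_covariates(Y, self.covariates)
        else:
            Y = Y - Y.mean(axis=0)
        return Y

    def _genotype_view(self, flags: list):
        """Return (view matrix, n_fpcs or None) for the routed method."""
        method = self.method
        m = self.dosage.shape[1]
        if method in ("qrfcca", "qrmcca") and m == 1:
            flags.append("single_snp")
            method = "qrscca"
        if method in ("qrfcca", "fcca"):
            fpc = fit_fpca(
                self.block,
                n_basis=self.n_basis,
                variance_target=self.variance_target,
                max_components=self.max_fpcs,
            )
            scores = fpc.scores
            if method == "qrfcca":
                scores = qr_reduce(scores, self.tail_fraction)
            return scores, fpc.n_components
        if method == "qrmcca":
            return qr_reduce(self.dosage, self.tail_fraction), None
        if method == "qrscca":
            if m != 1:
                raise ValueError("qrscca expects a single-SNP gene")
            return self.dosage - self.dosage.mean(axis=0), None
        # plain cca
        return self.dosage - self.dosage.mean(axis=0), None

    def _degenerate_result(self, flags: list) -> MultiTraitAssociationResults:
        flags = flags + ["degenerate"]
        return MultiTraitAssociationResults(
            method=self.method,
            statistic=0.0,
            df=0,
            p_value=1.0,
            canonical_correlations=np.zeros(0),
            association_r=0.0,
            wilks_lambda=1.0,
            statistic_form=self.statistic_form,
            p_dim=0,
            k_dim=0,
            nobs=self.nobs,
            n_snps_used=self.dosage.shape[1],
            n_fpcs=None,
            flags=flags,
            model=self,
        )

    def fit(self) -> MultiTraitAssociationResults:
        """Run the routed pipeline and test the association."""
        flags: list = []
        Y = self._phenotype_view(flags)
        try:
            X_view, n_fpcs = self._genotype_view(flags)
        except DegenerateGeneError:
            return self._degenerate_result(flags)
        if self.method in ("qrfcca", "qrmcca", "qrscca"):
            Y_view = qr_reduce(Y, self.tail_fraction)
        else:
            Y_view = Y
        if X_view.shape[1] == 0 or Y_view.shape[1] == 0:
            return self._degenerate_result(flags)
        lams, _, _, cca_flags = canonical_correlations(X_view, Y_view)
        res: CCATestResult = lrt_statistic(
            lams,
            self.nobs,
            X_view.shape[1],
            Y_view.shape[1],
            form=self.statistic_form,
            flags=flags + cca_flags,
        )
        return MultiTraitAssociationResults(
            method=self.method,
            statistic=res.statistic,
            df=res.df,
            p_value=res.p_value,
            canonical_correlations=res.canonical_correlations,
            association_r=res.association_r,
            wilks_lambda=res.wilks_lambda,
            statistic_form=res.statistic_form,
            p_dim=res.p,
            k_dim=res.k,
            nobs=self.nobs,
            n_snps_used=self.dosage.shape[1],
            n_fpcs=n_fpcs,
            flags=res.flags,
            model=self,
        )
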