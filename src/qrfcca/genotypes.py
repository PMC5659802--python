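"""Genotype coding for gene-based association analysis.

A gene's raw diploid calls become a :class:`GenotypeBlock`: an ``n x m``
minor-allele-count matrix together with SNP positions rescaled to [0, 1],
the representation consumed by the functional PCA of genotype profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeBlock", "DegenerateGeneError", "code_genotypes"]


class DegenerateGeneError(ValueError):
    """Raised when a gene carries no usable genetic variation."""


@dataclass
class GenotypeBlock:
    """Coded genotypes for one gene.

    Attributes
    ----------
    gene_id : str
        Gene or region label.
    sample_ids : ndarray of str
        Sample labels, one per row of ``dosage``.
    positions : ndarray of int
        Physical bp coordinates, strictly increasing, one per SNP.
    rescaled_positions : ndarray of float
        Positions affinely mapped to [0, 1] (0 and 1 at the gene ends
        when there are at least two SNPs).
    dosage : ndarray
        ``n x m`` minor-allele counts, entries in {0, 1, 2}.
    maf : ndarray of float
        Per-SNP minor allele frequency in (0, 0.5].
    """

    gene_id: str
    sample_ids: np.ndarray
    positions: np.ndarray
    rescaled_positions: np.ndarray
    dosage: np.ndarray
    maf: np.ndarray
    flags: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def restrict(self, mask) -> "GenotypeBlock":
        """Return a new block keeping only the SNP columns in ``mask``."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        if idx.size == 0:
            raise DegenerateGeneError(
                f"gene {self.gene_id}: no SNPs left after restriction"
            )
        pos = self.positions[idx]
        return GenotypeBlock(
            gene_id=self.gene_id,
            sample_ids=self.sample_ids,
            positions=pos,
            rescaled_positions=_rescale(pos),
            dosage=self.dosage[:, idx],
            maf=self.maf[idx],
            flags=list(self.flags),
        )


def _rescale(positions: np.ndarray) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if positions.size == 1:
        return np.zeros(1)
    span = positions[-1] - positions[0]
    return (positions - positions[0]) / span


def code_genotypes(
    raw_calls,
    positions,
    sample_ids=None,
    gene_id: str = "gene",
) -> GenotypeBlock:
    """Code diploid calls as minor-allele counts (2 = minor homozygote,
    1 = heterozygote, 0 = major homozygote).

    Parameters
    ----------
    raw_calls : array-like, shape (n, m)
        Per-sample counts of one designated allele (e.g. the VCF ALT
        allele), values in {0, 1, 2}; missing entries as NaN or any
        negative value.
    positions : array-like of int
        Physical coordinates of the m variants, strictly increasing.
    sample_ids : sequence of str, optional
        Defaults to ``s0..s{n-1}``.
    gene_id : str
        Label for the gene.

    Notes
    -----
    Missing calls are imputed to the per-SNP observed dosage mean rounded
    to the nearest of {0, 1, 2}.  Columns whose designated allele is the
    major allele are flipped so dosage always counts the *minor* allele.
    Monomorphic columns are dropped; a gene with no polymorphic column
    raises :class:`DegenerateGeneError`.
    """
    calls = np.asarray(raw_calls, dtype=float)
    if calls.ndim != 2:
        raise ValueError("raw_calls must be a 2-D (samples x SNPs) array")
    n, m = calls.shape
    positions = np.asarray(positions)
    if positions.shape != (m,):
        raise ValueError("positions length must match the number of SNP columns")
    if m > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")
    if sample_ids is None:
        sample_ids = np.array([f"s{i}" for i in range(n)])
    else:
        sample_ids = np.asarray(sample_ids)

    missing = ~np.isfinite(calls) | (calls < 0)
    calls = np.where(missing, np.nan, calls)
    if np.nanmax(calls, initial=0.0) > 2 or calls.shape[0] == 0:
        raise ValueError("calls must be diploid allele counts in {0, 1, 2}")

    # mean-impute missing entries, rounded back onto {0, 1, 2}
    if missing.any():
        col_mean = np.nanmean(calls, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        fill = np.clip(np.rint(col_mean), 0, 2)
        calls = np.where(missing, fill[None, :], calls)

    freq = calls.mean(axis=0) / 2.0
    flip = freq > 0.5
    dosage = np.where(flip[None, :], 2.0 - calls, calls)
    maf = np.where(flip, 1.0 - freq, freq)

    poly = maf > 0
    flags = []
    if not poly.all():
        dosage = dosage[:, poly]
        positions = positions[poly]
        maf = maf[poly]
    if dosage.shape[1] == 0:
        raise DegenerateGeneError(f"gene {gene_id}: degenerate gene (all monomorphic)")
    if dosage.shape[1] == 1:
        flags.append("single_snp")
        warnings.warn(
            f"gene {gene_id}: single polymorphic SNP; functional coding degenerates "
            "to a single-SNP profile",
            stacklevel=2,
        )

    return GenotypeBlock(
        gene_id=gene_id,
        sample_ids=sample_ids,
        positions=np.asarray(positions),
        rescaled_positions=_rescale(positions),
        dosage=dosage,
        maf=maf,
        flags=flags,
    )
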