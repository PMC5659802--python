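"""Quadratically regularized matrix factorization (soft-thresholded SVD).

The low-rank factorization ``A ~ G H`` with a quadratic (Frobenius)
penalty ``mu`` on both factors,

    min_{G,H}  ||A - G H||_F^2 + mu ||G||_F^2 + mu ||H||_F^2,

is solved in closed form by soft-thresholding the singular values of A:
``tau_j = (lambda_j - mu)_+`` with ``G = U_l diag(tau)^{1/2}`` and
``H = diag(tau)^{1/2} V_l'``.  Shrinking the singular spectrum raises the
share of the leading components, which is the mechanism the association
test exploits on both the genotype-score and phenotype views.

The penalty is chosen from the data: ``mu`` is set to the singular value
whose tail sum (that value through the smallest) accounts for a target
fraction (default 20%) of the total singular-value mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RegularizedFactorization",
    "svd_factorize",
    "select_mu",
    "soft_threshold",
    "qr_reduce",
]


@dataclass
class RegularizedFactorization:
    """SVD of a data matrix plus soft-thresholded singular values.

    ``reduced_scores`` is ``G = U diag(tau)^{1/2}`` restricted to the
    components surviving the threshold (``rank_kept`` columns).
    """

    singular_values: np.ndarray  # lambda_1 >= ... >= lambda_r > 0
    left_vectors: np.ndarray  # n x r
    right_vectors: np.ndarray  # q x r
    mu: float
    thresholded: np.ndarray  # tau_j = (lambda_j - mu)_+
    rank_kept: int
    reduced_scores: np.ndarray  # n x rank_kept
    centered: bool
    column_mean: np.ndarray
    degenerate: bool = False

    @property
    def rank(self) -> int:
        return self.singular_values.size

    def approximation(self) -> np.ndarray:
        """The (thresholded) low-rank reconstruction G H (+ column means)."""
        k = self.rank_kept
        GH = (self.left_vectors[:, :k] * self.thresholded[:k]) @ self.right_vectors[
            :, :k
        ].T
        if self.centered:
            GH = GH + self.column_mean
        return GH


def svd_factorize(
    A, l: int | None = None, center: bool = False
) -> RegularizedFactorization:
    """Best rank-``l`` factorization of A via the SVD (no shrinkage, mu = 0).

    ``center=True`` removes column means first so the factorization acts
    on variation (the convention used inside the association pipeline).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("A must be a 2-D matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError("A contains NaN or Inf")
    col_mean = A.mean(axis=0)
    work = A - col_mean if center else A
    U, s, Vt = np.linalg.svd(work, full_matrices=False)
    tol = max(work.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    if l is not None:
        if not 1 <= l <= min(A.shape):
            raise ValueError("l must satisfy 1 <= l <= min(n, q)")
        r = min(r, l)
    s = s[:r]
    U = U[:, :r]
    V = Vt[:r].T
    return RegularizedFactorization(
        singular_values=s,
        left_vectors=U,
        right_vectors=V,
        mu=0.0,
        thresholded=s.copy(),
        rank_kept=r,
        reduced_scores=U * np.sqrt(s),
        centered=center,
        column_mean=col_mean,
        degenerate=r == 0,
    )


def select_mu(singular_values, tail_fraction: float = 0.20) -> float:
    """Pick the penalty mu as the singular value whose tail sum is nearest
    to ``tail_fraction`` of the total singular-value mass.

    Ties are broken toward the smaller singular value (less shrinkage).
    ``tail_fraction = 0`` disables shrinkage (mu = 0).
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0:
        return 0.0
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("singular values must be nonincreasing")
    if not 0 <= tail_fraction < 1:
        raise ValueError("tail_fraction must lie in [0, 1)")
    total = s.sum()
    if total <= 0:
        return 0.0
    if tail_fraction == 0:
        return 0.0
    tails = np.cumsum(s[::-1])[::-1] / total  # tails[m] = sum_{j>=m} / total
    dev = np.abs(tails - tail_fraction)
    # argmin over reversed order returns the largest index among ties
    m = s.size - 1 - int(np.argmin(dev[::-1]))
    return float(s[m])


def soft_threshold(
    fact: RegularizedFactorization, mu: float
) -> RegularizedFactorization:
    """Apply ``tau_j = (lambda_j - mu)_+`` and rebuild the reduced scores."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    s = fact.singular_values
    tau = np.maximum(s - mu, 0.0)
    kept = int(np.sum(s > mu))
    reduced = fact.left_vectors[:, :kept] * np.sqrt(tau[:kept])
    return replace(
        fact,
        mu=float(mu),
        thresholded=tau,
        rank_kept=kept,
        reduced_scores=reduced,
        degenerate=kept == 0,
    )


def qr_reduce(
    A,
    tail_fraction: float = 0.20,
    l: int | None = None,
    center: bool = True,
) -> np.ndarray:
    """Quadratically regularized reduction of a data matrix.

    Composition SVD -> mu selection -> soft threshold; returns the
    surviving score columns ``G = U diag(tau)^{1/2}``.  A zero-column
    result signals a degenerate (untestable) input to the caller.
    """
    fact = svd_factorize(A, l=l, center=center)
    mu = select_mu(fact.singular_values, tail_fraction)
    return soft_threshold(fact, mu).reduced_scores
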