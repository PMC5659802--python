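"""Canonical correlation analysis and the likelihood-ratio association test.

For views X (n x p) and Y (n x k) with sample covariance blocks
Sxx, Sxy, Syy, the canonical correlations ``lambda_1 >= ... >= lambda_q``
(q = min(p, k)) are the singular values of

    K = Sxx^{-1/2} Sxy Syy^{-1/2},

equivalently the square roots of the eigenvalues of
``R^2 = Syy^{-1/2} Syx Sxx^{-1} Sxy Syy^{-1/2}``.  The association
measure is ``r = sum lambda_i^2 = Tr(R^2)`` (equal to narrow-sense
heritability when the genotype view carries all trait variance), Wilks'
criterion is ``Lambda = prod(1 - lambda_i^2)``, and independence of the
two views is tested with

    T = -N sum log(1 - lambda_i^2)                       (plain)
    T = -[N - (q + 3)/2] sum log(1 - lambda_i^2)         (bartlett)

referred to a chi-square with p*k degrees of freedom.  The "bartlett"
multiplier is implemented as printed in the source method; the classical
large-sample correction -[N - (p + k + 3)/2] is available as
``classical_bartlett``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CCATestResult",
    "canonical_correlations",
    "association_measure",
    "lrt_statistic",
    "cca_test",
]

LAMBDA_CLIP = 1.0 - 1e-12
_EIG_FLOOR = 1e-12
_RIDGE_EPS = 1e-8

VALID_FORMS = ("plain", "bartlett", "classical_bartlett", "auto")


@dataclass
class CCATestResult:
    """Canonical correlations and the likelihood-ratio test for one gene."""

    canonical_correlations: np.ndarray
    association_r: float
    wilks_lambda: float
    statistic: float
    statistic_form: str
    df: int
    p_value: float
    N: int
    p: int
    k: int
    flags: list = field(default_factory=list)

    @property
    def q(self) -> int:
        return min(self.p, self.k)


def _inv_sqrt(S: np.ndarray, flags: list) -> np.ndarray:
    """Symmetric inverse square root with ridge stabilization."""
    dim = S.shape[0]
    tr = np.trace(S)
    evals = np.linalg.eigvalsh(S)
    if evals[0] < 1e-10 * max(tr / dim, 1e-300):
        S = S + np.eye(dim) * (_RIDGE_EPS * tr / dim)
        flags.append("ridge_stabilized")
    evals, evecs = np.linalg.eigh(S)
    evals = np.maximum(evals, _EIG_FLOOR)
    return (evecs / np.sqrt(evals)) @ evecs.T


def canonical_correlations(X, Y, center: bool = True):
    """Canonical correlations and canonical vectors of two views.

    Returns ``(lams, A, B, flags)`` where the columns of A (p x q) and
    B (k x q) are the canonical loading vectors ``Sxx^{-1/2} U`` and
    ``Syy^{-1/2} V``, and ``lams`` is clipped to [0, 1 - 1e-12].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with the same number of rows")
    n, p = X.shape
    k = Y.shape[1]
    flags: list = []
    if n <= max(p, k):
        flags.append("n_le_dim")
    if center:
        X = X - X.mean(axis=0)
        Y = Y - Y.mean(axis=0)
    denom = n - 1
    Sxx = X.T @ X / denom
    Syy = Y.T @ Y / denom
    Sxy = X.T @ Y / denom
    Wx = _inv_sqrt(Sxx, flags)
    Wy = _inv_sqrt(Syy, flags)
    K = Wx @ Sxy @ Wy
    U, lams, Vt = np.linalg.svd(K)
    q = min(p, k)
    lams = np.clip(lams[:q], 0.0, LAMBDA_CLIP)
    A = Wx @ U[:, :q]
    B = Wy @ Vt[:q].T
    return lams, A, B, flags


def association_measure(lams) -> float:
    """Association measure r = sum of squared canonical correlations."""
    lams = np.asarray(lams, dtype=float)
    return float(np.sum(lams**2))


def resolve_form(form: str, N: int) -> str:
    if form not in VALID_FORMS:
        raise ValueError(f"unknown statistic form {form!r}")
    if form == "auto":
        return "classical_bartlett" if N >= 500 else "plain"
    return form


def lrt_statistic(
    lams, N: int, p: int, k: int, form: str = "auto", flags=None
) -> CCATestResult:
    """Likelihood-ratio test of no association from canonical correlations."""
    if N < 2:
        raise ValueError("N must be at least 2")
    flags = list(flags) if flags else []
    lams = np.asarray(lams, dtype=float)
    if np.any(lams >= 1.0):
        flags.append("saturated")
        lams = np.clip(lams, 0.0, LAMBDA_CLIP)
    form = resolve_form(form, N)
    q = min(p, k)
    log_terms = np.log1p(-(lams**2))
    if form == "plain":
        mult = float(N)
    elif form == "bartlett":
        mult = N - (q + 3) / 2.0
    else:  # classical_bartlett
        mult = N - (p + k + 3) / 2.0
    statistic = float(-mult * np.sum(log_terms))
    df = p * k
    p_value = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return CCATestResult(
        canonical_correlations=lams,
        association_r=association_measure(lams),
        wilks_lambda=float(np.exp(np.sum(log_terms))),
        statistic=statistic,
        statistic_form=form,
        df=df,
        p_value=p_value,
        N=N,
        p=p,
        k=k,
        flags=flags,
    )


def cca_test(X, Y, form: str = "auto", center: bool = True) -> CCATestResult:
    """Convenience wrapper: canonical correlations then the LRT."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    lams, _, _, flags = canonical_correlations(X, Y, center=center)
    return lrt_statistic(
        lams, X.shape[0], X.shape[1], Y.shape[1], form=form, flags=flags
    )
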