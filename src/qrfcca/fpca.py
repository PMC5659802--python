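"""Functional principal component analysis of genotype profiles.

Each individual's genotype across a gene is treated as a function
``x_i(t)`` of rescaled genomic position ``t`` in [0, 1] (minor-allele
count at each SNP).  The profile is expanded on orthonormal
eigenfunctions ``beta_j``:

    x_i(t) = sum_j  xi_ij  beta_j(t),        xi_ij = int x_i(t) beta_j(t) dt

and the functional principal component (FPC) scores ``xi_ij`` become the
low-dimensional genotype features carrying the gene's linkage
disequilibrium structure.

The fit is the classic two-step construction: (i) smooth each profile by
least squares onto a Fourier basis evaluated at the SNP positions;
(ii) eigen-decompose the sample covariance of the basis coefficients.
Because the Fourier system is orthonormal on [0, 1] the basis Gram matrix
is the identity, so coefficient-space eigenvectors are directly the
eigenfunction coefficients.  Scores are evaluated by trapezoid quadrature
of the (linearly interpolated) centered profiles against the
eigenfunctions on an equally spaced grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import DegenerateGeneError, GenotypeBlock

__all__ = ["FPCModel", "fourier_basis", "fit_fpca", "fpc_scores"]

DEFAULT_GRID_SIZE = 500
DEFAULT_MAX_BASIS = 25


def fourier_basis(t, n_basis: int) -> np.ndarray:
    """Evaluate the first ``n_basis`` orthonormal Fourier functions on [0,1].

    phi_0 = 1, phi_{2j-1} = sqrt(2) sin(2 pi j t), phi_{2j} = sqrt(2) cos(2 pi j t).
    """
    t = np.asarray(t, dtype=float)
    out = np.empty((t.size, n_basis))
    out[:, 0] = 1.0
    for b in range(1, n_basis):
        j = (b + 1) // 2
        if b % 2 == 1:
            out[:, b] = np.sqrt(2.0) * np.sin(2 * np.pi * j * t)
        else:
            out[:, b] = np.sqrt(2.0) * np.cos(2 * np.pi * j * t)
    return out


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


def _interp_matrix(grid: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Dense linear-interpolation operator from values at ``knots`` to ``grid``.

    Outside the knot range the interpolant is held constant (np.interp
    convention).
    """
    m = knots.size
    L = np.zeros((grid.size, m))
    if m == 1:
        L[:, 0] = 1.0
        return L
    idx = np.clip(np.searchsorted(knots, grid, side="right") - 1, 0, m - 2)
    left = knots[idx]
    right = knots[idx + 1]
    frac = np.clip((grid - left) / (right - left), 0.0, 1.0)
    rows = np.arange(grid.size)
    L[rows, idx] = 1.0 - frac
    L[rows, idx + 1] = frac
    return L


@dataclass
class FPCModel:
    """Fitted FPCA for one gene.

    ``eigenfunction_coefs`` holds the Fourier-coefficient vectors of the
    retained eigenfunctions (``n_basis x J``); ``eigenfunctions`` are
    their values on the quadrature ``grid`` (``grid_size x J``).
    ``eigenvalues`` are all positive covariance eigenvalues (decreasing),
    of which the first J are retained; ``variance_explained`` are the
    corresponding proportions of the total.  ``scores`` is the ``n x J``
    matrix of quadrature FPC scores of the training block.
    """

    eigenfunction_coefs: np.ndarray
    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    scores: np.ndarray
    n_basis: int
    grid: np.ndarray
    mean_profile: np.ndarray
    knots: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[1]


def fit_fpca(
    block: GenotypeBlock,
    n_basis: int | None = None,
    variance_target: float = 0.90,
    grid_size: int = DEFAULT_GRID_SIZE,
    max_components: int | None = None,
) -> FPCModel:
    """Fit the two-step FPCA of a gene's genotype profiles.

    Parameters
    ----------
    block : GenotypeBlock
        Coded genotypes (n samples x m SNPs, m >= 2).
    n_basis : int, optional
        Number of Fourier basis functions; default ``min(m, 25)``.
        Values above m are clipped with a warning.
    variance_target : float
        Retain the smallest J components whose cumulative variance
        proportion reaches this target.
    grid_size : int
        Quadrature grid resolution on [0, 1].
    max_components : int, optional
        Hard cap on J (e.g. 1 to mimic a single-FPC analysis).

    Raises
    ------
    DegenerateGeneError
        If the genotype profiles carry no variation.
    """
    X = np.asarray(block.dosage, dtype=float)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("FPCA needs at least 2 samples and 2 SNPs")
    if n_basis is None:
        n_basis = min(m, DEFAULT_MAX_BASIS)
    elif n_basis > m:
        warnings.warn(
            f"n_basis={n_basis} exceeds the number of SNPs ({m}); clipping to {m}",
            stacklevel=2,
        )
        n_basis = m

    t = np.asarray(block.rescaled_positions, dtype=float)
    Phi = fourier_basis(t, n_basis)  # m x B
    # least-squares smoothing coefficients, one row per sample
    coefs, *_ = np.linalg.lstsq(Phi, X.T, rcond=None)
    C = coefs.T  # n x B
    Cc = C - C.mean(axis=0)

    # Fourier basis is orthonormal on [0,1]: Gram matrix = identity, so the
    # covariance operator eigenproblem reduces to the coefficient covariance.
    S = (Cc.T @ Cc) / (n - 1)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 1e-12:
        raise DegenerateGeneError(
            f"gene {block.gene_id}: degenerate gene (no genotype variation)"
        )
    keep = evals > 1e-10 * total
    evals = evals[keep]
    evecs = evecs[:, keep]
    var_explained = evals / total

    cum = np.cumsum(var_explained)
    J = int(np.searchsorted(cum, min(variance_target, cum[-1]) - 1e-12) + 1)
    if max_components is not None:
        J = min(J, max_components)
    J = max(J, 1)

    grid = np.linspace(0.0, 1.0, grid_size)
    E = evecs[:, :J]
    B_grid = fourier_basis(grid, n_basis) @ E

    model = FPCModel(
        eigenfunction_coefs=E,
        eigenfunctions=B_grid,
        eigenvalues=evals,
        variance_explained=var_explained,
        scores=np.empty((0, J)),
        n_basis=n_basis,
        grid=grid,
        mean_profile=X.mean(axis=0),
        knots=t,
    )
    model.scores = fpc_scores(model, block)
    return model


def fpc_scores(model: FPCModel, block: GenotypeBlock) -> np.ndarray:
    """FPC scores ``xi_ij = int (x_i(t) - xbar(t)) beta_j(t) dt``.

    The centered genotype profile is linearly interpolated from the SNP
    positions to the model grid and the integral is evaluated by the
    trapezoid rule.  Equivalent, by associativity, to one matrix product
    with the precomposed interpolation/quadrature operator.
    """
    t = np.asarray(block.rescaled_positions, dtype=float)
    if t.shape != model.knots.shape or not np.allclose(t, model.knots):
        raise ValueError("block SNP positions do not match the fitted model grid")
    X = np.asarray(block.dosage, dtype=float)
    Xc = X - model.mean_profile[None, :]
    L = _interp_matrix(model.grid, t)  # grid x m
    w = _trapezoid_weights(model.grid)
    M = L.T @ (w[:, None] * model.eigenfunctions)  # m x J
    return Xc @ M
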