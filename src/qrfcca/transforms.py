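"""Phenotype transformations: rank-based inverse normal and covariate
residualization."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["inverse_normal_transform", "adjust_covariates"]


def inverse_normal_transform(y, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform of one trait.

    value = Phi^{-1}((rank - c) / (n + 1 - 2c)) with average ranks for
    ties.  The default offset c = 3/8 is the Blom convention; c = 0.5
    gives the (rank - 1/2)/n variant.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a 1-D trait vector")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant trait cannot be transformed")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def adjust_covariates(Y, C, add_intercept: bool = True) -> np.ndarray:
    """Residualize traits on shared covariates by multivariate least squares.

    All traits are regressed on the same design (intercept prepended by
    default); the residual matrix replaces the phenotypes downstream.
    Collinear covariate columns are dropped with a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != Y.shape[0]:
        raise ValueError("Y and C must have the same number of rows")
    n = Y.shape[0]
    if add_intercept:
        C = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # drop collinear columns greedily, keeping the earliest independent set
        keep = []
        for j in range(C.shape[1]):
            trial = C[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
        warnings.warn(
            f"dropping {C.shape[1] - len(keep)} collinear covariate column(s)",
            stacklevel=2,
        )
        C = C[:, keep]
    if n <= C.shape[1]:
        raise ValueError("need more samples than covariates")
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return Y - C @ beta
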