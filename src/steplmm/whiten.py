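"""Whitening transform: reduce GLS association testing to OLS.

With V = sigma2_g K + sigma2_e I, any factor L with L'L = V^{-1} satisfies
L V L' = I, so regressing L y on L [X | z] is an ordinary least-squares
problem whose statistics equal the mixed-model GLS statistics at fixed
variance components. Two equivalent factors are provided:

* the inverse of the lower Cholesky factor of V (triangular, built here);
* the eigen factor diag(d)^{-1/2} U' used by the stepwise engine, which
  reuses the kinship decomposition and costs only a diagonal scaling per
  re-estimate of the variance components.

Orientation of the factor is irrelevant to every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .geno_io import GenotypeMatrix
from .kinship import Kinship
from .varcomp import VarianceComponents

__all__ = ["Whitener", "build_V", "make_whitener", "whiten_genotypes"]


@dataclass
class Whitener:
    """Holds L with L'L = V^{-1} and the transformed phenotypes/covariates."""

    L: np.ndarray
    y_star: np.ndarray
    X_star: np.ndarray
    vc: VarianceComponents | None = None


def build_V(kinship: Kinship, vc: VarianceComponents, W: np.ndarray | None = None) -> np.ndarray:
    """Phenotypic covariance V = sigma2_g W K W' + sigma2_e I."""
    if W is None:
        V = vc.sigma2_g * kinship.K + vc.sigma2_e * np.eye(kinship.n)
    else:
        W = np.asarray(W, dtype=float)
        V = vc.sigma2_g * (W @ kinship.K @ W.T) + vc.sigma2_e * np.eye(W.shape[0])
    if not np.isfinite(V).all():
        raise FloatingPointError("non-finite entries in V")
    return V


def make_whitener(
    V: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    vc: VarianceComponents | None = None,
) -> Whitener:
    """Factor V^{-1} = L'L via Cholesky and transform y and X.

    L is the inverse of the lower-triangular Cholesky factor C of V
    (obtained by triangular solve), so L is lower-triangular and
    L'L = C'^{-1} C^{-1} = V^{-1}.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    try:
        C = scipy.linalg.cholesky(V, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Cholesky of V failed; consider a larger kinship bending epsilon"
        ) from exc
    L = scipy.linalg.solve_triangular(C, np.eye(V.shape[0]), lower=True)
    y_star = scipy.linalg.solve_triangular(C, y, lower=True)
    X_star = scipy.linalg.solve_triangular(C, X, lower=True)
    return Whitener(L=L, y_star=y_star, X_star=X_star, vc=vc)


def whiten_genotypes(L: np.ndarray, G: GenotypeMatrix | np.ndarray, block: int = 512) -> np.ndarray:
    """Transform dosage columns: returns L @ M computed in column blocks.

    Only ``n x block`` transformed columns are materialized at a time beyond
    the output array; the result is identical to the whole-matrix product.
    """
    M = G.dosages.astype(float) if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    if block < 1:
        raise ValueError("block must be >= 1")
    n, m = M.shape
    out = np.empty((n, m))
    for start in range(0, m, block):
        stop = min(start + block, m)
        out[:, start:stop] = L @ M[:, start:stop]
    return out
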