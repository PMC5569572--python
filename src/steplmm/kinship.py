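"""Realized genomic relationship matrix (GRM) and its spectral decomposition.

K is built as the centered cross-product of dosages over ``2 * sum p(1-p)``
(VanRaden method 1), using observed post-filter allele frequencies. The
eigendecomposition is computed once per dataset and reused by every REML
call, since adding SNP fixed effects changes the design, not K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .geno_io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["Kinship", "compute_grm", "bend", "write_kinship", "read_kinship"]

BEND_LADDER = (0.0, 1e-6, 1e-4, 1e-2)
EIG_FLOOR = 1e-8


@dataclass
class Kinship:
    """Symmetric PSD relationship matrix with cached spectral decomposition.

    ``K = eigenvectors @ diag(eigenvalues) @ eigenvectors.T`` after bending;
    eigenvalues are non-increasing and strictly positive so K is invertible.
    """

    K: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    epsilon_bend: float
    sample_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def inverse(self) -> np.ndarray:
        """K^{-1} = U diag(1/w) U' from the stored decomposition."""
        U, w = self.eigenvectors, self.eigenvalues
        return (U / w) @ U.T

    def solve(self, B: np.ndarray) -> np.ndarray:
        U, w = self.eigenvectors, self.eigenvalues
        return U @ ((U.T @ B).T / w).T


def compute_grm(G: GenotypeMatrix, sample_ids: list[str] | None = None) -> Kinship:
    """GRM from dosages: K = Mc Mc' / (2 sum p(1-p)), Mc centered by 2p.

    For an unrelated HWE population the diagonal averages near 1. The matrix
    is bent (minimal diagonal shift) if its smallest eigenvalue is <= 1e-8.
    """
    if G.has_missing:
        raise ValueError("impute missing genotypes before building the GRM")
    p = G.dosages.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs to build a GRM")
    M = G.dosages[:, poly].astype(float)
    pp = p[poly]
    M -= 2.0 * pp
    denom = 2.0 * float(np.sum(pp * (1.0 - pp)))
    K = (M @ M.T) / denom
    K = 0.5 * (K + K.T)
    return bend(K, floor=EIG_FLOOR, sample_ids=sample_ids or list(G.sample_ids))


def bend(K: np.ndarray, floor: float = EIG_FLOOR, sample_ids: list[str] | None = None) -> Kinship:
    """Add the smallest ladder epsilon to diag(K) so min eigenvalue > floor."""
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("K must be symmetric")
    w, U = scipy.linalg.eigh(K)
    for eps in BEND_LADDER:
        if w[0] + eps > floor:
            break
    else:
        eps = float(floor - w[0] + BEND_LADDER[-1])
        logger.warning("bending ladder exhausted; using epsilon=%.3g", eps)
    if eps > 0:
        K = K + eps * np.eye(K.shape[0])
        w = w + eps
        logger.info("bent K with epsilon=%.1e (min eigenvalue was %.3g)", eps, w[0] - eps)
    order = np.argsort(w)[::-1]
    return Kinship(
        K=K,
        eigenvalues=w[order],
        eigenvectors=U[:, order],
        epsilon_bend=float(eps),
        sample_ids=sample_ids,
    )


def write_kinship(kin: Kinship, path) -> Path:
    """Export K as a TSV matrix with sample ids as header row and column."""
    ids = kin.sample_ids or [f"s{i}" for i in range(kin.n)]
    df = pd.DataFrame(kin.K, index=ids, columns=ids)
    path = Path(path)
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_kinship(path) -> Kinship:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return bend(df.to_numpy(dtype=float), sample_ids=[str(s) for s in df.index])
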