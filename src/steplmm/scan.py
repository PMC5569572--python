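"""Genome-wide single-SNP association on whitened data.

After whitening, errors have identity covariance, so adding one SNP column
to the OLS regression of y* on X* changes the deviance by exactly the drop
in residual sum of squares: LRT = RSS0 - RSS1, chi-square with 1 df. The
scan residualizes y* and all SNP columns against X* once (QR projection),
so each SNP costs O(n). Ranking by LRT is equivalent to ranking by the
squared marginal t statistic (or the F test): they are monotone transforms
of each other on a fixed design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .whiten import Whitener

__all__ = ["ScanResult", "scan_all", "scan_arrays", "pick_most_significant"]

COLLINEAR_TOL = 1e-8


@dataclass
class ScanResult:
    """Marginal association of one SNP on the whitened scale."""

    snp_index: int
    beta_hat: float
    lrt: float
    p_value: float
    rss0: float
    rss1: float
    skipped: bool = False
    chrom: str | None = None
    pos_bp: int | None = None


def scan_arrays(
    y_star: np.ndarray,
    X_star: np.ndarray,
    M_star: np.ndarray,
    exclude: set[int] | frozenset[int] = frozenset(),
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Vectorized scan core.

    Returns (beta, lrt, rss0, rss1, skipped) over all columns of M_star;
    excluded or X*-collinear columns get lrt = 0 and skipped = True.
    """
    Q, _ = np.linalg.qr(X_star)
    y_res = y_star - Q @ (Q.T @ y_star)
    rss0 = float(y_res @ y_res)
    M_res = M_star - Q @ (Q.T @ M_star)
    zz = np.einsum("ij,ij->j", M_res, M_res)
    zy = M_res.T @ y_res
    col_norm = np.sqrt(np.einsum("ij,ij->j", M_star, M_star))
    skipped = np.sqrt(np.maximum(zz, 0.0)) <= COLLINEAR_TOL * np.maximum(col_norm, 1.0)
    if exclude:
        skipped = skipped.copy()
        skipped[list(exclude)] = True
    safe_zz = np.where(skipped, 1.0, zz)
    beta = np.where(skipped, 0.0, zy / safe_zz)
    lrt = np.where(skipped, 0.0, zy * zy / safe_zz)
    lrt = np.maximum(lrt, 0.0)
    rss1 = rss0 - lrt
    return beta, lrt, rss0, rss1, skipped


def scan_all(
    wh: Whitener,
    M_star: np.ndarray,
    exclude: set[int] | frozenset[int] = frozenset(),
    chrom: np.ndarray | None = None,
    pos_bp: np.ndarray | None = None,
) -> list[ScanResult]:
    """Single-SNP OLS scan of y* on [X*, m*_j] for every non-excluded SNP j."""
    beta, lrt, rss0, rss1, skipped = scan_arrays(wh.y_star, wh.X_star, M_star, exclude)
    p = scipy.stats.chi2.sf(lrt, df=1)
    p = np.where(skipped, 1.0, p)
    return [
        ScanResult(
            snp_index=j,
            beta_hat=float(beta[j]),
            lrt=float(lrt[j]),
            p_value=float(p[j]),
            rss0=rss0,
            rss1=float(rss1[j]),
            skipped=bool(skipped[j]),
            chrom=None if chrom is None else str(chrom[j]),
            pos_bp=None if pos_bp is None else int(pos_bp[j]),
        )
        for j in range(M_star.shape[1])
    ]


def pick_most_significant(results: list[ScanResult]) -> ScanResult:
    """Largest LRT among non-skipped SNPs; ties go to smaller (chrom, pos),
    then smaller index. With all statistics zero the tie-break winner is
    returned (the eBIC gate decides whether it enters)."""
    candidates = [r for r in results if not r.skipped]
    if not candidates:
        raise ValueError("no candidate SNPs to pick from")

    def key(r: ScanResult):
        chrom = r.chrom if r.chrom is not None else ""
        pos = r.pos_bp if r.pos_bp is not None else r.snp_index
        return (-r.lrt, chrom, pos, r.snp_index)

    return min(candidates, key=key)
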