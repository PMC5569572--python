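"""REML variance components via the spectral decomposition of K.

With one phenotypic record per individual (W = I) and K = U diag(lam) U',
rotating y and the fixed design by U' makes the covariance diagonal,
``sigma2_g * lam_i + sigma2_e``, so REML reduces to a one-dimensional
profile likelihood in the variance ratio ``delta = sigma2_e / sigma2_g``.
The profile is scanned on a grid over log10(delta) in [-5, 5] and refined
by bounded minimization, mirroring the EMMA strategy.

Model selection downstream needs likelihoods comparable across fixed-effect
sets; REML likelihoods are not. We therefore also report the ML
log-likelihood evaluated at the REML variance estimates with GLS fixed
effects (``logL_ml``), which is what eBIC consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .kinship import Kinship

logger = logging.getLogger(__name__)

__all__ = ["MixedModelSpec", "VarianceComponents", "estimate_varcomp", "heritability_poly"]

LOG10_DELTA_BOUNDS = (-5.0, 5.0)
GRID_POINTS = 100
XTOL = 1e-6
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixedModelSpec:
    """y = X b + Z q + g + e with g ~ N(0, K sigma2_g), e ~ N(0, I sigma2_e).

    Z holds the dosage columns of the currently selected SNPs (may be empty).
    The per-individual incidence W is the identity (one record each).
    """

    y: np.ndarray
    X: np.ndarray
    kinship: Kinship
    Z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.Z is None:
            self.Z = np.empty((n, 0))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[0] != n or self.X.shape[0] != n or self.kinship.n != n:
            raise ValueError("inconsistent sample dimension across y, X, Z, K")
        F = self.fixed_design()
        if np.linalg.matrix_rank(F) < F.shape[1]:
            raise ValueError("[X | Z] is rank deficient")

    def fixed_design(self) -> np.ndarray:
        return np.hstack([self.X, self.Z])

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_beta(self) -> int:
        return self.X.shape[1]

    @property
    def n_qtn(self) -> int:
        return self.Z.shape[1]


@dataclass
class VarianceComponents:
    """REML estimates of the polygenic and residual variances.

    ``lam`` is the MME variance ratio sigma2_e / sigma2_g; ``logL_ml`` is
    the ML log-likelihood at these variance estimates with GLS fixed
    effects, used by the eBIC model-selection criterion.
    """

    sigma2_g: float
    sigma2_e: float
    lam: float
    logL_reml: float
    logL_ml: float
    at_boundary: bool = False
    log10_delta: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma2_g) and np.isfinite(self.sigma2_e)):
            raise ValueError("non-finite variance components")
        if self.sigma2_g < 0 or self.sigma2_e <= 0:
            raise ValueError("variance components out of range")


def heritability_poly(vc: VarianceComponents) -> float:
    """Null-model (polygenic) heritability sigma2_g / (sigma2_g + sigma2_e)."""
    total = vc.sigma2_g + vc.sigma2_e
    if total <= 0:
        raise ValueError("both variance components are zero")
    return vc.sigma2_g / total


# ---------------------------------------------------------------------------
# profile likelihood in the rotated basis


def _weighted_fit(F_rot: np.ndarray, y_rot: np.ndarray, w: np.ndarray):
    """GLS in the rotated basis with weights w_i = 1 / (lam_i + delta).

    Returns (beta, weighted RSS, logdet of F' W F).
    """
    sw = np.sqrt(w)
    Fw = F_rot * sw[:, None]
    yw = y_rot * sw
    beta, _, rank, _ = np.linalg.lstsq(Fw, yw, rcond=None)
    if rank < F_rot.shape[1]:
        raise np.linalg.LinAlgError("singular rotated design")
    r = yw - Fw @ beta
    rss = float(r @ r)
    sign, logdet = np.linalg.slogdet(Fw.T @ Fw)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular rotated design")
    return beta, rss, logdet


def _reml_negloglik(log10_delta: float, lam: np.ndarray, y_rot: np.ndarray,
                    F_rot: np.ndarray, logdet_FtF: float) -> float:
    delta = 10.0 ** log10_delta
    n, p = F_rot.shape
    w = 1.0 / (lam + delta)
    try:
        _, rss, logdet_FWF = _weighted_fit(F_rot, y_rot, w)
    except np.linalg.LinAlgError:
        return np.inf
    if rss <= 0 or not np.isfinite(rss):
        return np.inf
    df = n - p
    sigma2_g = rss / df
    ll = -0.5 * (
        df * (_LOG2PI + np.log(sigma2_g) + 1.0)
        - np.sum(np.log(w))
        + logdet_FWF
        - logdet_FtF
    )
    return -ll


def _ml_loglik_at(sigma2_g: float, sigma2_e: float, lam: np.ndarray,
                  y_rot: np.ndarray, F_rot: np.ndarray) -> float:
    """ML log-likelihood with GLS fixed effects at fixed variances."""
    d = sigma2_g * lam + sigma2_e
    w = 1.0 / d
    beta, rss, _ = _weighted_fit(F_rot, y_rot, w)
    n = y_rot.shape[0]
    return -0.5 * (n * _LOG2PI + float(np.sum(np.log(d))) + rss)


def estimate_varcomp_rotated(
    lam: np.ndarray,
    y_rot: np.ndarray,
    F_rot: np.ndarray,
    grid_points: int = GRID_POINTS,
    bounds: tuple[float, float] = LOG10_DELTA_BOUNDS,
) -> VarianceComponents:
    """Profile REML given already-rotated data (fast path for the stepwise loop)."""
    n, p = F_rot.shape
    if n <= p + 1:
        raise ValueError("too few observations for REML with this design")
    if lam.max() - lam.min() < 1e-8:
        raise ValueError("K is (close to) a scaled identity: variance ratio not identifiable")
    _, rss_ols, _, _ = np.linalg.lstsq(F_rot, y_rot, rcond=None)
    yss = float(y_rot @ y_rot)
    if rss_ols.size and float(rss_ols[0]) <= 1e-12 * max(yss, 1.0):
        raise ValueError(
            "degenerate model: phenotype is an (almost) exact linear combination "
            "of the fixed effects; residual variance is zero"
        )
    sign, logdet_FtF = np.linalg.slogdet(F_rot.T @ F_rot)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "singular rotated design: columns of [X | Z] are linearly dependent"
        )
    grid = np.linspace(bounds[0], bounds[1], grid_points)
    vals = np.array([_reml_negloglik(g, lam, y_rot, F_rot, logdet_FtF) for g in grid])
    if not np.isfinite(vals).any():
        raise FloatingPointError("REML likelihood non-finite over the whole delta grid")
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_points - 1)]
    res = scipy.optimize.minimize_scalar(
        _reml_negloglik,
        bounds=(lo, hi),
        args=(lam, y_rot, F_rot, logdet_FtF),
        method="bounded",
        options={"xatol": XTOL},
    )
    log10_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    neg_ll = min(float(res.fun), float(vals[i]))
    at_boundary = log10_delta <= bounds[0] + 1e-3 or log10_delta >= bounds[1] - 1e-3
    if at_boundary:
        logger.info("REML optimum at delta-bracket boundary (log10 delta = %.2f)", log10_delta)
    delta = 10.0 ** log10_delta
    w = 1.0 / (lam + delta)
    _, rss, _ = _weighted_fit(F_rot, y_rot, w)
    sigma2_g = rss / (n - p)
    sigma2_e = delta * sigma2_g
    logL_ml = _ml_loglik_at(sigma2_g, sigma2_e, lam, y_rot, F_rot)
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        lam=delta,
        logL_reml=-neg_ll,
        logL_ml=logL_ml,
        at_boundary=at_boundary,
        log10_delta=log10_delta,
    )


def estimate_varcomp(spec: MixedModelSpec, **kwargs) -> VarianceComponents:
    """REML estimates of (sigma2_g, sigma2_e) for the given fixed-effect set.

    Rotates y and [X | Z] by the eigenvectors of K and maximizes the
    one-dimensional profile REML in delta = sigma2_e / sigma2_g.
    """
    U = spec.kinship.eigenvectors
    lam = spec.kinship.eigenvalues
    y_rot = U.T @ spec.y
    F_rot = U.T @ spec.fixed_design()
    return estimate_varcomp_rotated(lam, y_rot, F_rot, **kwargs)
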