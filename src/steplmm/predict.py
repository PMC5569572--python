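"""Genomic prediction and variance accounting.

A fitted model decomposes the breeding value of individual j as
GEBV_j = (Z q)_j + g_j: the detected-QTL part plus the polygenic BLUP.
Z columns are the selected-SNP dosages centered by twice the allele
frequency, so q is an allele-substitution effect and the QTL variance
formula sigma2_qi = 2 p_i (1 - p_i) q_i^2 is consistent with the coding
(centering only shifts the intercept). Total heritability combines the
detected-QTL and residual-polygenic variances:
h^2 = (sigma2_q + sigma2_g) / (sigma2_q + sigma2_g + sigma2_e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geno_io import GenotypeMatrix, PhenotypeTable
from .kinship import Kinship
from .stepwise import ModelState, Panel, StepConfig, StepTrace, step_fit
from .varcomp import MixedModelSpec

__all__ = [
    "PredictionResult",
    "qtl_variance",
    "total_h2",
    "predict_training",
    "predict_new",
    "gblup_fit",
    "expected_accuracy",
]


@dataclass
class PredictionResult:
    """GEBVs with their QTL/polygenic decomposition and variance shares."""

    gebv: np.ndarray
    gebv_qtl: np.ndarray
    gebv_poly: np.ndarray
    sigma2_q: float
    sigma2_g: float
    sigma2_e: float
    h2_total: float
    h2_q_share: float
    sample_ids: list[str] | None = None


def qtl_variance(maf, effects) -> float:
    """Total QTL variance sum_i 2 p_i (1 - p_i) q_i^2.

    ``2p(1-p)`` is symmetric in p vs 1-p, so either the minor or the ALT
    allele frequency may be supplied.
    """
    p = np.asarray(maf, dtype=float)
    q = np.asarray(effects, dtype=float)
    if p.shape != q.shape:
        raise ValueError("maf and effects length mismatch")
    return float(np.sum(2.0 * p * (1.0 - p) * q * q))


def total_h2(sigma2_q: float, sigma2_g: float, sigma2_e: float) -> float:
    """Heritability (sigma2_q + sigma2_g) / (sigma2_q + sigma2_g + sigma2_e)."""
    if min(sigma2_q, sigma2_g, sigma2_e) < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma2_q + sigma2_g + sigma2_e
    if total <= 0:
        raise ValueError("all variance components are zero")
    return (sigma2_q + sigma2_g) / total


def _result_from(state: ModelState, Z: np.ndarray, sample_ids=None) -> PredictionResult:
    gebv_qtl = Z @ state.q_hat if state.n_qtn else np.zeros(state.n_obs)
    gebv_poly = state.g_hat
    s2q = qtl_variance(state.alt_freq_selected, state.q_hat) if state.n_qtn else 0.0
    s2g, s2e = state.vc.sigma2_g, state.vc.sigma2_e
    h2 = total_h2(s2q, s2g, s2e)
    return PredictionResult(
        gebv=gebv_qtl + gebv_poly,
        gebv_qtl=gebv_qtl,
        gebv_poly=gebv_poly,
        sigma2_q=s2q,
        sigma2_g=s2g,
        sigma2_e=s2e,
        h2_total=h2,
        h2_q_share=s2q / (s2q + s2g + s2e),
        sample_ids=sample_ids,
    )


def predict_training(state: ModelState, spec: MixedModelSpec) -> PredictionResult:
    """GEBV = Z q + g for the training individuals of a fitted model."""
    if spec.n_qtn != state.n_qtn:
        raise ValueError("spec.Z does not match the fitted selected-SNP set")
    return _result_from(state, spec.Z)


def predict_training_panel(state: ModelState, panel: Panel) -> PredictionResult:
    """Convenience form of :func:`predict_training` using a Panel's coding."""
    Z = panel.Mc[:, state.selected] if state.n_qtn else np.empty((state.n_obs, 0))
    return _result_from(state, Z, sample_ids=list(panel.G.sample_ids))


def predict_new(
    state: ModelState,
    kinship_full: Kinship,
    new_ids: list[str],
    Z_new: np.ndarray,
) -> np.ndarray:
    """GEBVs for unphenotyped individuals.

    The polygenic part is the kinship regression
    K_{new,train} K_{train,train}^{-1} g_train (the conditional expectation
    under the fitted model); the QTL part is Z_new q. ``kinship_full`` must
    span training + new individuals with ids; training rows are those not
    named in ``new_ids``, in their stored order (matching g_train).
    """
    if kinship_full.sample_ids is None:
        raise ValueError("kinship_full must carry sample ids")
    ids = kinship_full.sample_ids
    missing = [s for s in new_ids if s not in set(ids)]
    if missing:
        raise ValueError(f"new ids absent from kinship: {missing[:3]}")
    new_set = set(new_ids)
    idx_train = [i for i, s in enumerate(ids) if s not in new_set]
    pos = {s: i for i, s in enumerate(ids)}
    idx_new = [pos[s] for s in new_ids]
    if len(idx_train) != state.g_hat.shape[0]:
        raise ValueError("training block of kinship does not match fitted model size")
    K = kinship_full.K
    K_tt = K[np.ix_(idx_train, idx_train)]
    K_nt = K[np.ix_(idx_new, idx_train)]
    poly = K_nt @ np.linalg.solve(K_tt, state.g_hat)
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    qtl = Z_new @ state.q_hat if state.n_qtn else np.zeros(len(idx_new))
    return poly + qtl


def gblup_fit(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    config: StepConfig | None = None,
    panel: Panel | None = None,
) -> tuple[PredictionResult, ModelState, StepTrace]:
    """GBLUP baseline: the null model (no SNP fixed effects), REML + BLUP."""
    base = config or StepConfig()
    cfg = StepConfig(gamma=base.gamma, alpha_drop=base.alpha_drop,
                     max_iter=base.max_iter, max_qtn=0)
    state, trace = step_fit(G, pheno, cfg, panel=panel)
    if panel is None:
        panel = Panel(G)
    return predict_training_panel(state, panel), state, trace


def expected_accuracy(beta: float, h2: float, Me: float, N: int) -> float:
    """Deterministic prediction-accuracy formula
    r = sqrt(beta h^2 / (beta h^2 + Me / N)), with beta the share of genetic
    variance captured by detected QTL."""
    if N <= 0:
        raise ValueError("N must be positive")
    if Me < 0:
        raise ValueError("Me must be >= 0")
    bh2 = beta * h2
    denom = bh2 + Me / N
    if denom <= 0:
        return 0.0
    return float(np.sqrt(bh2 / denom))
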