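"""Stepwise linear mixed model engine: forward inclusion of SNPs gated by
eBIC, backward elimination by Student's t, and Henderson mixed-model
equations for the final solutions.

The loop: (1) REML under the current model; (2) whiten with the kinship
eigendecomposition (diagonal scaling in the rotated basis); (3) single-SNP
scan of the remaining candidates; (4) tentatively add the top SNP and keep
it only if the model eBIC drops below the best accepted value, otherwise
stop; (5) t-test the previously selected SNPs and drop the least
significant one if it fails the alpha_drop level (the SNP added in the same
iteration is exempt once); repeat. A dropped SNP may re-enter later; such
re-entries are flagged in the trace.

eBIC (extended BIC): -2 logL + k ln n + 2 gamma ln C(p, k), where p is the
number of candidate SNPs after MAF filtering and -2 logL is the ML
log-likelihood evaluated at the REML variance estimates (REML likelihoods
are not comparable across fixed-effect sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import gammaln

from .geno_io import GenotypeMatrix, PhenotypeTable
from .kinship import Kinship, compute_grm
from .varcomp import MixedModelSpec, VarianceComponents, estimate_varcomp_rotated

logger = logging.getLogger(__name__)

__all__ = [
    "StepConfig",
    "Panel",
    "ModelState",
    "StepTrace",
    "solve_mme",
    "t_test_model_snps",
    "ebic",
    "step_fit",
    "write_outputs",
]


@dataclass
class StepConfig:
    """Tunable knobs of the stepwise fit."""

    gamma: float = 1.0          # eBIC model-space penalty weight
    alpha_drop: float = 0.05    # two-sided level of the backward t test
    max_iter: int = 100         # hard cap on add/drop iterations
    max_qtn: int | None = None  # 0 forces the null (GBLUP) model

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.alpha_drop < 1.0:
            raise ValueError("alpha_drop must lie in (0, 1)")


class Panel:
    """Per-genotype-panel precomputation shared across traits and scenarios.

    Holds the GRM eigendecomposition, the 2p-centered dosage matrix Mc, and
    its rotation U' Mc — the expensive pieces that do not depend on the
    phenotype or on which SNPs are currently selected.
    """

    def __init__(self, G: GenotypeMatrix, kinship: Kinship | None = None):
        self.G = G
        self.kinship = kinship if kinship is not None else compute_grm(G)
        self.alt_freq = G.dosages.mean(axis=0) / 2.0
        self.Mc = G.dosages.astype(float) - 2.0 * self.alt_freq
        self.M_rot = self.kinship.eigenvectors.T @ self.Mc

    @property
    def n_candidates(self) -> int:
        return self.G.n_snps


@dataclass
class ModelState:
    """The accepted model: selected SNPs with all estimates attached."""

    selected: list[int]
    b_hat: np.ndarray
    q_hat: np.ndarray
    g_hat: np.ndarray
    vc: VarianceComponents
    ebic: float
    minus2logL: float
    C22_diag: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    n_obs: int
    n_beta: int
    n_candidates: int
    gamma: float
    alt_freq_selected: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_qtn(self) -> int:
        return len(self.selected)

    @property
    def df_t(self) -> int:
        return self.n_obs - self.n_beta - self.n_qtn


@dataclass
class StepRecord:
    iteration: int
    action: str  # add | drop | stop
    snp_index: int | None
    ebic: float
    minus2logL: float
    sigma2_g: float
    sigma2_e: float
    reentry: bool = False


@dataclass
class StepTrace:
    records: list[StepRecord] = field(default_factory=list)

    def append(self, rec: StepRecord) -> None:
        self.records.append(rec)

    def accepted_ebics(self) -> list[float]:
        return [r.ebic for r in self.records if r.action in ("add", "drop")]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "action": r.action,
                    "snp_index": -1 if r.snp_index is None else r.snp_index,
                    "ebic": r.ebic,
                    "minus2logL": r.minus2logL,
                    "sigma2_g": r.sigma2_g,
                    "sigma2_e": r.sigma2_e,
                    "reentry": r.reentry,
                }
                for r in self.records
            ]
        )


# ---------------------------------------------------------------------------
# mixed model equations


def solve_mme(spec: MixedModelSpec, vc: VarianceComponents):
    """Solve Henderson's mixed model equations for the current model.

    The coefficient matrix stacks blocks for b, q and g (with I + lambda
    K^{-1} in the polygenic block, W = I). Returns (b_hat, q_hat, g_hat,
    C22_diag) where C22_diag is the diagonal of the q-block of the inverse
    coefficient matrix, used for the t tests.
    """
    if not np.isfinite(vc.lam) or vc.lam <= 0:
        raise ValueError("solve_mme requires finite positive lambda = sigma2_e / sigma2_g")
    X, Z, y = spec.X, spec.Z, spec.y
    n, nb, nq = spec.n, spec.n_beta, spec.n_qtn
    F = spec.fixed_design()
    Kinv = spec.kinship.inverse()
    LHS = np.block([
        [F.T @ F, F.T],
        [F, np.eye(n) + vc.lam * Kinv],
    ])
    rhs = np.concatenate([F.T @ y, y])
    try:
        Cinv = np.linalg.inv(LHS)
    except np.linalg.LinAlgError as exc:
        dep = _dependent_columns(F)
        raise np.linalg.LinAlgError(
            f"singular mixed model equations; dependent fixed columns: {dep}"
        ) from exc
    sol = Cinv @ rhs
    b_hat = sol[:nb]
    q_hat = sol[nb:nb + nq]
    g_hat = sol[nb + nq:]
    C22_diag = np.diag(Cinv)[nb:nb + nq].copy()
    return b_hat, q_hat, g_hat, C22_diag


def _dependent_columns(F: np.ndarray) -> list[int]:
    _, R = np.linalg.qr(F)
    d = np.abs(np.diag(R))
    return np.flatnonzero(d <= 1e-10 * max(d.max(), 1.0)).tolist()


def t_test_model_snps(state: ModelState) -> tuple[np.ndarray, np.ndarray]:
    """Student's t for each in-model SNP: t = q / sqrt(sigma2_e * C22_jj),
    two-sided p with df = n_obs - n_beta - n_qtn."""
    if state.n_qtn == 0:
        return np.empty(0), np.empty(0)
    if np.any(state.C22_diag <= 0):
        raise FloatingPointError("non-positive diagonal in C22")
    t = state.q_hat / np.sqrt(state.vc.sigma2_e * state.C22_diag)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=state.df_t)
    return t, p


def ebic(minus2logL: float, k: int, n: int, p: int, gamma: float = 1.0) -> float:
    """Extended BIC: -2 logL + k ln n + 2 gamma ln C(p, k)."""
    if k > p:
        raise ValueError("model size k exceeds candidate count p")
    if n <= 1:
        raise ValueError("need n > 1")
    log_choose = gammaln(p + 1) - gammaln(k + 1) - gammaln(p - k + 1)
    return float(minus2logL + k * np.log(n) + 2.0 * gamma * log_choose)


# ---------------------------------------------------------------------------
# fast in-loop estimators (rotated basis; equal to solve_mme, see tests)


def _gls_blup_rotated(lam, U, y_rot, X_rot, Z_rot, vc):
    """Fixed effects by GLS, polygenic BLUP, and Var(q_hat) in one pass.

    Identities used: the fixed-effect block of the MME inverse satisfies
    sigma2_e * C_ff = (F' V^{-1} F)^{-1}, and the BLUP is
    g = sigma2_g K V^{-1} (y - F beta); both are diagonal operations after
    rotation by the eigenvectors of K.
    """
    F_rot = np.hstack([X_rot, Z_rot]) if Z_rot.size else X_rot
    nb = X_rot.shape[1]
    d = vc.sigma2_g * lam + vc.sigma2_e
    w = 1.0 / d
    Fw = F_rot * w[:, None]
    A = Fw.T @ F_rot            # F' V^{-1} F
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (Fw.T @ y_rot)
    r_rot = y_rot - F_rot @ beta
    g_rot = vc.sigma2_g * lam * w * r_rot
    g_hat = U @ g_rot
    C22_diag = np.diag(Ainv)[nb:] / vc.sigma2_e
    return beta[:nb], beta[nb:], g_hat, C22_diag


def _t_and_p(q_hat, C22_diag, sigma2_e, df):
    t = q_hat / np.sqrt(sigma2_e * C22_diag)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=df)
    return t, p


# ---------------------------------------------------------------------------
# the stepwise loop


def step_fit(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    config: StepConfig | None = None,
    panel: Panel | None = None,
) -> tuple[ModelState, StepTrace]:
    """Run the full stepwise fit and return the accepted model plus trace.

    ``G`` must already be imputed and MAF-filtered; ``pheno`` rows must be
    aligned to ``G.sample_ids``. A precomputed :class:`Panel` may be passed
    to share the GRM eigendecomposition across traits on the same genotypes.
    """
    config = config or StepConfig()
    if panel is None:
        panel = Panel(G)
    elif panel.G is not G and panel.G.n_snps != G.n_snps:
        raise ValueError("panel was built on a different genotype matrix")
    n = pheno.n
    if n != G.n_individuals:
        raise ValueError("phenotype rows do not match genotype rows")
    U = panel.kinship.eigenvectors
    lam = panel.kinship.eigenvalues
    y_rot = U.T @ pheno.y
    X_rot = U.T @ pheno.X
    nb = pheno.n_beta
    p_cand = panel.n_candidates
    from .scan import scan_arrays  # local import avoids a cycle

    def refit(sel: list[int]) -> tuple[VarianceComponents, float, float]:
        Z_rot = panel.M_rot[:, sel] if sel else np.empty((n, 0))
        F_rot = np.hstack([X_rot, Z_rot])
        vc = estimate_varcomp_rotated(lam, y_rot, F_rot)
        m2ll = -2.0 * vc.logL_ml
        return vc, m2ll, ebic(m2ll, len(sel), n, p_cand, config.gamma)

    selected: list[int] = []
    ever_dropped: set[int] = set()
    vc, m2ll, ebic_curr = refit(selected)
    best_ebic = ebic_curr
    trace = StepTrace()
    stop_reason = "ebic"

    max_adds = p_cand if config.max_qtn is None else config.max_qtn
    iteration = 0
    while iteration < config.max_iter and len(selected) < max_adds:
        iteration += 1
        if n - nb - (len(selected) + 1) <= 1:
            logger.warning("stopping: no residual degrees of freedom left")
            stop_reason = "df"
            break
        # whiten with current variance components (diagonal in rotated basis)
        s = 1.0 / np.sqrt(vc.sigma2_g * lam + vc.sigma2_e)
        y_star = y_rot * s
        Z_rot = panel.M_rot[:, selected] if selected else np.empty((n, 0))
        X_star = np.hstack([X_rot, Z_rot]) * s[:, None]
        M_star = panel.M_rot * s[:, None]
        _, lrt, _, _, skipped = scan_arrays(y_star, X_star, M_star, exclude=set(selected))
        if skipped.all():
            stop_reason = "no-candidates"
            break
        top = _argmax_with_tiebreak(lrt, skipped, panel.G)
        # tentative add, gated on the best accepted eBIC
        vc_try, m2ll_try, ebic_try = refit(selected + [top])
        if not ebic_try < best_ebic:
            stop_reason = "ebic"
            break
        selected.append(top)
        vc, m2ll, ebic_curr = vc_try, m2ll_try, ebic_try
        best_ebic = min(best_ebic, ebic_curr)
        trace.append(StepRecord(iteration, "add", top, ebic_curr, m2ll,
                                vc.sigma2_g, vc.sigma2_e, reentry=top in ever_dropped))
        # backward elimination: t-test all but the freshly added SNP
        if len(selected) > 1:
            Z_rot = panel.M_rot[:, selected]
            _, q_hat, _, C22 = _gls_blup_rotated(lam, U, y_rot, X_rot, Z_rot, vc)
            df = n - nb - len(selected)
            t, pvals = _t_and_p(q_hat, C22, vc.sigma2_e, df)
            testable = np.arange(len(selected) - 1)  # exclude the just-added
            failing = testable[pvals[testable] > config.alpha_drop]
            if failing.size:
                worst = failing[np.argmin(np.abs(t[failing]))]
                dropped = selected.pop(int(worst))
                ever_dropped.add(dropped)
                vc, m2ll, ebic_curr = refit(selected)
                best_ebic = min(best_ebic, ebic_curr)
                trace.append(StepRecord(iteration, "drop", dropped, ebic_curr, m2ll,
                                        vc.sigma2_g, vc.sigma2_e))
    else:
        if iteration >= config.max_iter:
            logger.warning("stepwise loop hit max_iter=%d", config.max_iter)
            stop_reason = "max_iter"
    trace.append(StepRecord(iteration, "stop", None, ebic_curr, m2ll,
                            vc.sigma2_g, vc.sigma2_e))
    logger.info("stepwise done: %d SNPs selected (%s)", len(selected), stop_reason)

    # final solutions (Step 7): fixed effects, QTL effects, polygenic BLUPs
    Z_rot = panel.M_rot[:, selected] if selected else np.empty((n, 0))
    b_hat, q_hat, g_hat, C22 = _gls_blup_rotated(lam, U, y_rot, X_rot, Z_rot, vc)
    state = ModelState(
        selected=list(selected),
        b_hat=b_hat,
        q_hat=q_hat,
        g_hat=g_hat,
        vc=vc,
        ebic=ebic_curr,
        minus2logL=m2ll,
        C22_diag=C22,
        t_stats=np.empty(0),
        p_values=np.empty(0),
        n_obs=n,
        n_beta=nb,
        n_candidates=p_cand,
        gamma=config.gamma,
        alt_freq_selected=panel.alt_freq[selected] if selected else np.empty(0),
    )
    state.t_stats, state.p_values = t_test_model_snps(state)
    return state, trace


def _argmax_with_tiebreak(lrt: np.ndarray, skipped: np.ndarray, G: GenotypeMatrix) -> int:
    best = np.max(np.where(skipped, -np.inf, lrt))
    ties = np.flatnonzero(~skipped & (lrt >= best - 0.0))
    if ties.size == 1:
        return int(ties[0])
    order = sorted(ties, key=lambda j: (str(G.chrom[j]), int(G.pos_bp[j]), int(j)))
    return int(order[0])


# ---------------------------------------------------------------------------
# result writers


def write_outputs(state: ModelState, trace: StepTrace, G: GenotypeMatrix, prefix) -> dict[str, Path]:
    """Write <prefix>.qtl.tsv, <prefix>.trace.tsv and <prefix>.varcomp.txt."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    se = np.sqrt(state.vc.sigma2_e * state.C22_diag) if state.n_qtn else np.empty(0)
    qtl = pd.DataFrame(
        {
            "snp_id": [G.snp_ids[j] for j in state.selected],
            "chrom": [str(G.chrom[j]) for j in state.selected],
            "pos_bp": [int(G.pos_bp[j]) for j in state.selected],
            "allele": [G.alleles[j][1] for j in state.selected],
            "q_hat": state.q_hat,
            "se": se,
            "t": state.t_stats,
            "p": state.p_values,
        }
    )
    paths = {
        "qtl": prefix.with_suffix(".qtl.tsv"),
        "trace": prefix.with_suffix(".trace.tsv"),
        "varcomp": prefix.with_suffix(".varcomp.txt"),
    }
    qtl.to_csv(paths["qtl"], sep="\t", index=False, float_format="%.6g")
    trace.to_dataframe().to_csv(paths["trace"], sep="\t", index=False, float_format="%.6g")
    with open(paths["varcomp"], "w") as fh:
        fh.write(f"sigma2_g\t{state.vc.sigma2_g:.10g}\n")
        fh.write(f"sigma2_e\t{state.vc.sigma2_e:.10g}\n")
        fh.write(f"lambda\t{state.vc.lam:.10g}\n")
        fh.write(f"logL_reml\t{state.vc.logL_reml:.10g}\n")
        fh.write(f"logL_ml\t{state.vc.logL_ml:.10g}\n")
        fh.write(f"ebic\t{state.ebic:.10g}\n")
        fh.write(f"n_qtn\t{state.n_qtn}\n")
    return paths
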