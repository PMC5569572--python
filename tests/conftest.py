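import numpy as np
import pytest

from steplmm import Panel, filter_maf, simulate_genotypes, simulate_trait


@pytest.fixture(scope="session")
def small_panel():
    """Shared small genotype panel (n=120, m=300) with precomputed GRM."""
    G = simulate_genotypes(120, 300, seed=11)
    G = filter_maf(G, 0.05)
    return Panel(G)


@pytest.fixture(scope="session")
def small_dataset(small_panel):
    """Trait on the small panel: 10 QTL, h2 = 0.5."""
    return simulate_trait(small_panel.G, n_qtl=10, h2=0.5, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def dense_reml_loglik(y, F, K, sigma2_g, sigma2_e):
    """Independent dense-matrix REML log-likelihood (standard MVN form).

    logL_R = -1/2 [ (n-p) log 2pi + log|V| + log|F'V^-1 F| - log|F'F|
                    + (y - F b)' V^-1 (y - F b) ]   with b the GLS estimate.
    """
    n, p = F.shape
    V = sigma2_g * K + sigma2_e * np.eye(n)
    Vinv = np.linalg.inv(V)
    A = F.T @ Vinv @ F
    b = np.linalg.solve(A, F.T @ Vinv @ y)
    r = y - F @ b
    _, logdetV = np.linalg.slogdet(V)
    _, logdetA = np.linalg.slogdet(A)
    _, logdetFtF = np.linalg.slogdet(F.T @ F)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi) + logdetV + logdetA - logdetFtF + float(r @ Vinv @ r)
    )


def dense_ml_loglik(y, F, K, sigma2_g, sigma2_e):
    """Dense ML log-likelihood with GLS fixed effects at fixed variances."""
    n = y.shape[0]
    V = sigma2_g * K + sigma2_e * np.eye(n)
    Vinv = np.linalg.inv(V)
    b = np.linalg.solve(F.T @ Vinv @ F, F.T @ Vinv @ y)
    r = y - F @ b
    _, logdetV = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi) + logdetV + float(r @ Vinv @ r))
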