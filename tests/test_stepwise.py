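import math

import numpy as np
import pytest

from steplmm import (
    MixedModelSpec,
    Panel,
    StepConfig,
    VarianceComponents,
    bend,
    ebic,
    filter_maf,
    simulate_genotypes,
    simulate_polygenic_trait,
    solve_mme,
    step_fit,
    t_test_model_snps,
)
from steplmm.geno_io import PhenotypeTable
from steplmm.stepwise import write_outputs


def vc_of(s2g, s2e):
    return VarianceComponents(sigma2_g=s2g, sigma2_e=s2e, lam=s2e / s2g,
                              logL_reml=0.0, logL_ml=0.0)


@pytest.fixture(scope="module")
def toy_spec(small_panel, small_dataset):
    n = 8
    G = small_panel.G.take_samples(np.arange(n))
    from steplmm import compute_grm

    kin = compute_grm(G)
    rng = np.random.default_rng(9)
    y = rng.standard_normal(n)
    X = np.ones((n, 1))
    Z = G.centered_dosages([3, 7])
    return MixedModelSpec(y=y, X=X, Z=Z, kinship=kin)


class TestSolveMme:
    def test_large_lambda_approaches_ols(self, toy_spec):
        vc = vc_of(1.0, 1e8)  # lambda = 1e8: polygenic term vanishes
        b, q, g, _ = solve_mme(toy_spec, vc)
        F = toy_spec.fixed_design()
        ols = np.linalg.lstsq(F, toy_spec.y, rcond=None)[0]
        fixed = np.concatenate([b, q])
        np.testing.assert_allclose(fixed, ols, rtol=1e-4)
        assert np.max(np.abs(g)) < 1e-4 * max(np.max(np.abs(ols)), 1.0)

    def test_matches_gls_plus_blup_closed_form(self, toy_spec):
        vc = vc_of(0.8, 1.2)
        b, q, g, C22 = solve_mme(toy_spec, vc)
        K = toy_spec.kinship.K
        n = toy_spec.n
        V = vc.sigma2_g * K + vc.sigma2_e * np.eye(n)
        Vinv = np.linalg.inv(V)
        F = toy_spec.fixed_design()
        A = F.T @ Vinv @ F
        beta = np.linalg.solve(A, F.T @ Vinv @ toy_spec.y)
        np.testing.assert_allclose(np.concatenate([b, q]), beta, atol=1e-8)
        g_oracle = vc.sigma2_g * K @ Vinv @ (toy_spec.y - F @ beta)
        np.testing.assert_allclose(g, g_oracle, atol=1e-8)
        # sigma2_e * C22 equals the GLS covariance of q_hat
        cov_q = np.linalg.inv(A)[toy_spec.n_beta:, toy_spec.n_beta:]
        np.testing.assert_allclose(vc.sigma2_e * C22, np.diag(cov_q), atol=1e-8)

    def test_zero_phenotype_gives_zero_solutions(self, toy_spec):
        spec = MixedModelSpec(y=np.zeros(toy_spec.n), X=toy_spec.X, Z=toy_spec.Z,
                              kinship=toy_spec.kinship)
        b, q, g, _ = solve_mme(spec, vc_of(1.0, 1.0))
        assert np.max(np.abs(np.concatenate([b, q, g]))) < 1e-12

    def test_infinite_lambda_rejected(self, toy_spec):
        with pytest.raises(ValueError):
            solve_mme(toy_spec, VarianceComponents(sigma2_g=0.0, sigma2_e=1.0,
                                                   lam=np.inf, logL_reml=0.0, logL_ml=0.0))


class TestTTest:
    def mk_state(self, q_hat, C22, s2e, n_obs, n_beta):
        from steplmm.stepwise import ModelState

        k = len(q_hat)
        return ModelState(
            selected=list(range(k)), b_hat=np.zeros(n_beta), q_hat=np.asarray(q_hat, float),
            g_hat=np.zeros(n_obs), vc=vc_of(1.0, s2e), ebic=0.0, minus2logL=0.0,
            C22_diag=np.asarray(C22, float), t_stats=np.empty(0), p_values=np.empty(0),
            n_obs=n_obs, n_beta=n_beta, n_candidates=k, gamma=1.0,
        )

    def test_zero_effect_gives_zero_t_and_p_one(self):
        state = self.mk_state([0.0], [0.5], 1.0, 50, 1)
        t, p = t_test_model_snps(state)
        assert t[0] == 0.0 and p[0] == pytest.approx(1.0)

    def test_df_is_n_minus_beta_minus_qtn(self):
        state = self.mk_state([1.0, 0.5, 0.2], [0.1, 0.1, 0.1], 1.0, 100, 2)
        assert state.df_t == 95

    def test_matches_classical_ols_t_in_no_polygene_limit(self, rng):
        n = 60
        kin = bend(np.eye(n) + 1e-6 * np.diag(np.arange(n) / n))
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        X = np.ones((n, 1))
        spec = MixedModelSpec(y=y, X=X, Z=x[:, None], kinship=kin)
        s2e_ols = None
        F = np.column_stack([X, x])
        beta, rss, _, _ = np.linalg.lstsq(F, y, rcond=None)
        s2 = rss[0] / (n - 2)
        t_ols = beta[1] / np.sqrt(s2 * np.linalg.inv(F.T @ F)[1, 1])
        vc = vc_of(s2 / 1e8, s2)  # lambda = 1e8
        _, q, _, C22 = solve_mme(spec, vc)
        t_mme = q[0] / np.sqrt(vc.sigma2_e * C22[0])
        assert t_mme == pytest.approx(t_ols, abs=1e-3 * abs(t_ols))

    def test_nonpositive_c22_raises(self):
        state = self.mk_state([1.0], [0.0], 1.0, 50, 1)
        with pytest.raises(FloatingPointError):
            t_test_model_snps(state)


class TestEbic:
    def test_k_zero_is_bare_deviance(self):
        assert ebic(123.4, 0, 100, 5000) == pytest.approx(123.4)

    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(10.0, 3, 200, 1000, gamma=0.0) == pytest.approx(10.0 + 3 * math.log(200))

    def test_log_choose_matches_exact_integer_arithmetic(self):
        # ln C(1e5, 3) computed exactly with Python integers
        val = ebic(1000.0, 3, 3000, 10**5, gamma=1.0)
        expected = 1000.0 + 3 * math.log(3000) + 2.0 * math.log(math.comb(10**5, 3))
        assert val == pytest.approx(expected, rel=1e-12)

    def test_k_above_p_rejected(self):
        with pytest.raises(ValueError):
            ebic(0.0, 5, 10, 3)


def make_5qtl_dataset(seed, n=500, m=1000):
    """Five strong QTL, each explaining ~10% of phenotypic variance."""
    rng = np.random.default_rng(seed)
    G = filter_maf(simulate_genotypes(n, m, seed=seed), 0.05)
    causal = np.sort(rng.choice(G.n_snps, 5, replace=False))
    q = np.ones(5)
    tbv = G.dosages[:, causal].astype(float) @ q
    y = tbv + rng.normal(0, np.sqrt(2.0), n)
    return G, causal, y


class TestStepFit:
    def test_recovers_strong_qtl_exactly(self):
        found, exact = 0, 0
        for rep in range(3):
            G, causal, y = make_5qtl_dataset(seed=300 + rep)
            pheno = PhenotypeTable(y=y, X=np.ones((len(y), 1)),
                                   covariate_names=["intercept"],
                                   sample_ids=list(G.sample_ids))
            state, trace = step_fit(G, pheno)
            if set(state.selected) == set(causal.tolist()):
                exact += 1
            found += len(set(state.selected) & set(causal.tolist()))
            # trace invariant: accepted-model eBIC strictly decreases
            ebics = trace.accepted_ebics()
            assert all(b < a for a, b in zip(ebics, ebics[1:]))
            # every SNP in the final model is significant at alpha_drop
            assert (state.p_values <= 0.05).all()
        assert exact >= 2
        assert found >= 13

    def test_null_polygenic_trait_selects_nothing(self):
        G = filter_maf(simulate_genotypes(300, 600, seed=41), 0.05)
        panel = Panel(G)
        ds = simulate_polygenic_trait(panel, h2_poly=0.3, seed=42)
        state, trace = step_fit(G, ds.phenotype_table(), panel=panel)
        assert state.n_qtn == 0
        assert trace.records[-1].action == "stop"

    def test_forced_null_model(self, small_panel, small_dataset):
        cfg = StepConfig(max_qtn=0)
        state, _ = step_fit(small_panel.G, small_dataset.phenotype_table(),
                            cfg, panel=small_panel)
        assert state.selected == []
        assert state.g_hat.shape == (small_panel.kinship.n,)

    def test_single_step_equals_dense_gls_single_locus_fit(self):
        """With gamma=0 and one forced inclusion, the fit reproduces the
        single-locus mixed model solved densely at the same variances."""
        G, causal, y = make_5qtl_dataset(seed=55, n=80, m=120)
        pheno = PhenotypeTable(y=y, X=np.ones((80, 1)),
                               covariate_names=["intercept"],
                               sample_ids=list(G.sample_ids))
        cfg = StepConfig(gamma=0.0, max_qtn=1)
        state, _ = step_fit(G, pheno, cfg)
        assert state.n_qtn == 1
        panel = Panel(G)
        j = state.selected[0]
        spec = MixedModelSpec(y=y, X=pheno.X, Z=panel.Mc[:, [j]], kinship=panel.kinship)
        V = state.vc.sigma2_g * panel.kinship.K + state.vc.sigma2_e * np.eye(80)
        Vinv = np.linalg.inv(V)
        F = spec.fixed_design()
        beta = np.linalg.solve(F.T @ Vinv @ F, F.T @ Vinv @ y)
        assert state.q_hat[0] == pytest.approx(beta[-1], abs=1e-8)

    def test_fast_path_agrees_with_mme(self, small_panel, small_dataset):
        """The rotated-basis estimates used inside the loop equal the literal
        mixed-model-equation solutions."""
        state, _ = step_fit(small_panel.G, small_dataset.phenotype_table(),
                            panel=small_panel)
        assert state.n_qtn >= 1
        pheno = small_dataset.phenotype_table()
        spec = MixedModelSpec(y=pheno.y, X=pheno.X,
                              Z=small_panel.Mc[:, state.selected],
                              kinship=small_panel.kinship)
        b, q, g, C22 = solve_mme(spec, state.vc)
        np.testing.assert_allclose(state.b_hat, b, atol=1e-7)
        np.testing.assert_allclose(state.q_hat, q, atol=1e-7)
        np.testing.assert_allclose(state.g_hat, g, atol=1e-6)
        np.testing.assert_allclose(state.C22_diag, C22, atol=1e-7)

    def test_writes_output_files(self, tmp_path, small_panel, small_dataset):
        state, trace = step_fit(small_panel.G, small_dataset.phenotype_table(),
                                panel=small_panel)
        paths = write_outputs(state, trace, small_panel.G, tmp_path / "run")
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
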