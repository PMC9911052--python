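import numpy as np
import pytest
from scipy.optimize import minimize

from ghatpy.effects import fit_bayesc, fit_rrblup


def _simulate_trait(rng, n, m, n_qtl, h2):
    Z = rng.binomial(2, rng.uniform(0.1, 0.9, size=m), size=(n, m))
    Z = Z.astype(float)
    beta = np.zeros(m)
    qtl = rng.choice(m, size=n_qtl, replace=False)
    beta[qtl] = rng.standard_normal(n_qtl)
    g = Z @ beta
    g = (g - g.mean()) / g.std() * np.sqrt(h2)
    y = g + rng.standard_normal(n) * np.sqrt(1 - h2)
    return Z, y, beta


class TestRRBlup:
    def test_constant_phenotype_gives_zero_effects(self, rng):
        Z = rng.integers(0, 3, size=(10, 4)).astype(float)
        with pytest.warns(UserWarning, match="zero variance"):
            eff = fit_rrblup(Z, np.full(10, 3.0))
        np.testing.assert_array_equal(eff.alpha, 0.0)
        assert eff.params["s2_u"] == 0.0

    def test_fixed_lambda_matches_explicit_ridge_solve(self, rng):
        """At a fixed variance ratio the BLUP equals the closed-form ridge
        solution on centered genotypes."""
        Z = rng.integers(0, 3, size=(5, 3)).astype(float)
        y = rng.standard_normal(5)
        lam = 2.5
        eff = fit_rrblup(Z, y, lam=lam)
        Zc = Z - Z.mean(axis=0)
        yc = y - y.mean()
        oracle = np.linalg.solve(Zc.T @ Zc + lam * np.eye(3), Zc.T @ yc)
        np.testing.assert_allclose(eff.alpha, oracle, atol=1e-10)

    def test_reml_matches_generic_restricted_likelihood_optimizer(self,
                                                                  rng):
        """The spectral REML agrees with a dense two-parameter restricted
        likelihood optimization to high precision."""
        n, m = 40, 12
        Z, y, _ = _simulate_trait(rng, n, m, n_qtl=6, h2=0.6)
        eff = fit_rrblup(Z, y)
        Zc = Z - Z.mean(axis=0)
        K = Zc @ Zc.T
        X = np.ones((n, 1))

        def neg_reml(params):
            s2u, s2e = np.exp(params)
            H = s2u * K + s2e * np.eye(n)
            Hi = np.linalg.inv(H)
            XtHiX = X.T @ Hi @ X
            beta = np.linalg.solve(XtHiX, X.T @ Hi @ y)
            r = y - X @ beta
            _, ld_h = np.linalg.slogdet(H)
            _, ld_x = np.linalg.slogdet(XtHiX)
            return 0.5 * (ld_h + ld_x + r @ Hi @ r)

        best = None
        for start in ([0.0, 0.0], [-2.0, 0.0], [0.0, -2.0]):
            res = minimize(neg_reml, start, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-12,
                                    "maxiter": 5000})
            if best is None or res.fun < best.fun:
                best = res
        s2u_o, s2e_o = np.exp(best.x)
        assert eff.params["s2_u"] == pytest.approx(s2u_o, rel=1e-5,
                                                   abs=1e-6)
        assert eff.params["s2_e"] == pytest.approx(s2e_o, rel=1e-5,
                                                   abs=1e-6)

    def test_scale_equivariance(self, rng):
        Z, y, _ = _simulate_trait(rng, 60, 30, n_qtl=10, h2=0.5)
        a1 = fit_rrblup(Z, y).alpha
        a2 = fit_rrblup(Z, 3.0 * y).alpha
        np.testing.assert_allclose(a2, 3.0 * a1, rtol=1e-6, atol=1e-9)

    def test_orientation_flip_affects_only_that_marker(self, rng):
        Z, y, _ = _simulate_trait(rng, 60, 30, n_qtl=10, h2=0.5)
        Zf = Z.copy()
        Zf[:, 4] = 2.0 - Zf[:, 4]
        a = fit_rrblup(Z, y).alpha
        af = fit_rrblup(Zf, y).alpha
        assert af[4] == pytest.approx(-a[4], rel=1e-6)
        keep = np.arange(30) != 4
        np.testing.assert_allclose(af[keep], a[keep], rtol=1e-6, atol=1e-9)

    def test_cg_path_matches_spectral_path(self, rng):
        """The matrix-free large-n solver reproduces the exact spectral
        BLUP at the same variance ratio."""
        Z, y, _ = _simulate_trait(rng, 300, 80, n_qtl=20, h2=0.5)
        exact = fit_rrblup(Z, y, lam=7.0, reml_max_n=None).alpha
        via_cg = fit_rrblup(Z.astype(np.float32), y, lam=7.0,
                            reml_max_n=100).alpha
        np.testing.assert_allclose(via_cg, exact, rtol=5e-3, atol=1e-4)

    def test_effect_accuracy_increases_with_sample_size(self, rng):
        """Estimated effects correlate positively with the truth, more so
        at larger n (seed-fixed simulation property)."""
        cors = []
        for n in (100, 400):
            Z, y, beta = _simulate_trait(np.random.default_rng(7), n, 150,
                                         n_qtl=150, h2=0.5)
            a = fit_rrblup(Z, y).alpha
            cors.append(np.corrcoef(a, beta)[0, 1])
        assert cors[0] > 0
        assert cors[1] > cors[0]

    def test_phenotyped_subset_estimation(self, rng):
        """Effects can be fitted on a phenotyped subset of the genotyped
        samples (modern-phenotypes design) via the table interface."""
        import pandas as pd
        from ghatpy.datatypes import GenotypeMatrix

        Z, y, _ = _simulate_trait(rng, 50, 20, n_qtl=5, h2=0.8)
        g = GenotypeMatrix(samples=[f"s{i}" for i in range(50)],
                           markers=[f"m{j}" for j in range(20)],
                           dosages=Z)
        pheno = pd.DataFrame({"sample": [f"s{i}" for i in range(30)],
                              "trait": "t1", "value": y[:30]})
        eff = fit_rrblup(g, pheno, trait="t1")
        assert len(eff) == 20
        assert np.isfinite(eff.alpha).all()
        with pytest.raises(ValueError, match="overlap"):
            bad = pheno.assign(sample=[f"x{i}" for i in range(30)])
            fit_rrblup(g, bad, trait="t1")


class TestBayesC:
    def test_pi_one_short_circuits_to_zero(self, rng):
        Z, y, _ = _simulate_trait(rng, 30, 10, n_qtl=3, h2=0.5)
        eff = fit_bayesc(Z, y, pi=1.0, iters=200, burnin=50)
        np.testing.assert_array_equal(eff.alpha, 0.0)
        np.testing.assert_array_equal(eff.inclusion_prob, 0.0)

    def test_invalid_arguments(self, rng):
        Z, y, _ = _simulate_trait(rng, 30, 10, n_qtl=3, h2=0.5)
        with pytest.raises(ValueError, match="pi"):
            fit_bayesc(Z, y, pi=1.5)
        with pytest.raises(ValueError, match="burnin"):
            fit_bayesc(Z, y, iters=100, burnin=100)

    def test_seed_reproducibility(self, rng):
        Z, y, _ = _simulate_trait(rng, 60, 30, n_qtl=10, h2=0.5)
        a1 = fit_bayesc(Z, y, iters=400, burnin=100, seed=5).alpha
        a2 = fit_bayesc(Z, y, iters=400, burnin=100, seed=5).alpha
        np.testing.assert_array_equal(a1, a2)

    def test_pi_zero_approaches_ridge_solution(self, rng):
        """With every marker kept in the model the posterior mean tracks
        the REML ridge solution closely."""
        Z, y, _ = _simulate_trait(np.random.default_rng(11), 200, 100,
                                  n_qtl=50, h2=0.7)
        ridge = fit_rrblup(Z, y).alpha
        bayes = fit_bayesc(Z, y, pi=0.0, iters=3000, burnin=500,
                           seed=3).alpha
        assert np.corrcoef(ridge, bayes)[0, 1] > 0.95

    def test_large_qtl_rank_high_in_inclusion_probability(self):
        """Five large-effect QTL among many markers land in the top decile
        of posterior inclusion probability in nearly all replicates."""
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            n, m = 250, 800
            Z = rng.binomial(2, rng.uniform(0.2, 0.8, m),
                             size=(n, m)).astype(float)
            beta = np.zeros(m)
            qtl = rng.choice(m, 5, replace=False)
            beta[qtl] = rng.choice([-1.0, 1.0], 5)
            g = Z @ beta
            y = g + rng.standard_normal(n) * g.std() * 0.5
            eff = fit_bayesc(Z, y, pi=0.95, iters=800, burnin=200,
                             seed=rep)
            cutoff = np.quantile(eff.inclusion_prob, 0.9)
            if (eff.inclusion_prob[qtl] >= cutoff).all():
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_scale_equivariance_approximate(self, rng):
        Z, y, _ = _simulate_trait(np.random.default_rng(21), 150, 60,
                                  n_qtl=20, h2=0.7)
        a1 = fit_bayesc(Z, y, pi=0.5, iters=2000, burnin=500, seed=9).alpha
        a2 = fit_bayesc(Z, 5.0 * y, pi=0.5, iters=2000, burnin=500,
                        seed=9).alpha
        ratio = np.linalg.norm(a2) / np.linalg.norm(a1)
        assert ratio == pytest.approx(5.0, rel=0.1)
        assert np.corrcoef(a1, a2)[0, 1] > 0.98
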