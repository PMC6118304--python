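"""Tests for the eigen-rotated Gibbs sampler and its building blocks."""

import numpy as np
import pandas as pd
import pytest

import gepred as gp
from gepred._exceptions import DegenerateDataError, InputError, NumericalError


def dense_kernel(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(str(i) for i in range(len(values)))
    return gp.Kernel(values, labels)


class TestEigenDecompose:
    def test_identity_retains_all_unit_eigenvalues(self):
        basis = gp.eigen_decompose(dense_kernel(np.eye(4)))
        assert basis.rank == 4
        np.testing.assert_allclose(basis.blocks[0][2], np.ones(4))
        U = basis.blocks[0][1]
        np.testing.assert_allclose(U.T @ U, np.eye(4), atol=1e-10)

    def test_rank_one_ones_matrix_retains_single_eigenvalue(self):
        basis = gp.eigen_decompose(dense_kernel(np.ones((3, 3))), tol=1e-10)
        assert basis.rank == 1
        np.testing.assert_allclose(basis.blocks[0][2], [3.0])

    def test_block_spectra_match_dense_decomposition(self, rng):
        A = rng.normal(size=(3, 6))
        B = rng.normal(size=(2, 6))
        full = np.zeros((5, 5))
        full[:3, :3] = A @ A.T
        full[3:, 3:] = B @ B.T
        bd = gp.Kernel(full, tuple("abcde"), structure="block_diagonal",
                       block_sizes=(3, 2))
        basis = gp.eigen_decompose(bd)
        block_spectrum = np.sort(
            np.concatenate([s for _, _, s in basis.blocks])
        )
        dense_spectrum = np.sort(np.linalg.eigvalsh(full))[-len(block_spectrum):]
        np.testing.assert_allclose(block_spectrum, dense_spectrum, rtol=1e-10)

    def test_zero_matrix_yields_empty_basis(self):
        basis = gp.eigen_decompose(dense_kernel(np.zeros((3, 3))))
        assert basis.rank == 0

    def test_reconstruction(self, markers_small):
        K = gp.gb_kernel(markers_small)
        basis = gp.eigen_decompose(K)
        np.testing.assert_allclose(basis.reconstruct(), K.values,
                                   atol=1e-8 * np.abs(K.values).max())


class TestDefaultPriors:
    def test_stated_arithmetic_single_term(self):
        # var(y)=1, R2=0.5, one term with unit mean diagonal, nu=3:
        # Sc_u = Sc_e = 0.5 * 5/3
        y = np.array([0.0, 1.0, 2.0])  # sample variance exactly 1
        env = np.array(["e1"] * 3)
        gid = np.array(["a", "b", "c"])
        ks = gp.KernelSet(entries={"G": dense_kernel(np.eye(3))},
                          model_tag="MM", env=env, gid=gid, ne=(3,))
        pri = gp.default_priors(y, ks, R2=0.5)
        assert pri.Sc_u["G"] == pytest.approx(0.5 * 5 / 3, rel=1e-12)
        assert pri.Sc_e == pytest.approx(0.5 * 5 / 3, rel=1e-12)

    def test_equal_mean_diagonals_give_equal_scales(self):
        y = np.array([0.0, 1.0, 2.0])
        env = np.array(["e1"] * 3)
        gid = np.array(["a", "b", "c"])
        ks = gp.KernelSet(
            entries={"G": dense_kernel(np.eye(3)), "A": dense_kernel(np.eye(3))},
            model_tag="MM", env=env, gid=gid, ne=(3,),
        )
        pri = gp.default_priors(y, ks, R2=0.4)
        assert pri.Sc_u["G"] == pri.Sc_u["A"]

    def test_degenerate_r2_and_constant_y_rejected(self, kset_mds):
        y = np.ones(kset_mds.n_records)
        with pytest.raises(DegenerateDataError):
            gp.default_priors(y, kset_mds)
        y2 = np.arange(kset_mds.n_records, dtype=float)
        with pytest.raises(InputError):
            gp.default_priors(y2, kset_mds, R2=0.0)


class TestSampleRotatedEffects:
    def test_zero_variance_gives_exactly_zero(self, rng):
        basis = gp.eigen_decompose(dense_kernel(np.eye(5)))
        b, u = gp.sample_rotated_effects(rng.normal(size=5), basis, 0.0, 1.0, rng)
        assert np.all(b == 0.0) and np.all(u == 0.0)

    def test_data_dominate_when_signal_variance_large(self, rng):
        basis = gp.eigen_decompose(dense_kernel(np.eye(4)))
        resid = np.array([3.0, -2.0, 1.0, 0.5])
        n_rep = 2000
        draws = np.mean(
            [gp.sample_rotated_effects(resid, basis, 1e8, 1.0, rng)[1]
             for _ in range(n_rep)], axis=0,
        )
        # draw sd -> sqrt(var_e) = 1 in this limit, so SE = 1/sqrt(n_rep)
        np.testing.assert_allclose(draws, resid, atol=5 / np.sqrt(n_rep))

    def test_monte_carlo_mean_matches_ridge_oracle(self, rng):
        # E[u | resid] = var_u K (var_u K + var_e I)^{-1} resid
        n = 20
        A = rng.normal(size=(n, 2 * n))
        K = A @ A.T / (2 * n)
        var_u, var_e = 1.3, 0.7
        resid = rng.normal(size=n)
        expected = var_u * K @ np.linalg.solve(var_u * K + var_e * np.eye(n), resid)
        basis = gp.eigen_decompose(dense_kernel(K))
        draws = np.zeros(n)
        n_rep = 20000
        for _ in range(n_rep):
            draws += gp.sample_rotated_effects(resid, basis, var_u, var_e, rng)[1]
        draws /= n_rep
        # per-coordinate MC standard error bound from the conditional variances
        mc_se = np.sqrt(var_u * np.diag(K).max() / n_rep)
        np.testing.assert_allclose(draws, expected, atol=5 * mc_se)

    def test_dimension_mismatch_raises(self, rng):
        basis = gp.eigen_decompose(dense_kernel(np.eye(4)))
        with pytest.raises(InputError):
            gp.sample_rotated_effects(np.zeros(5), basis, 1.0, 1.0, rng)


class TestSampleVariance:
    def test_prior_draws_have_analytic_mean(self, rng):
        # with no data the draw is nu*Sc/chi2(nu); E = nu*Sc/(nu-2)
        nu, Sc = 5.0, 2.0
        draws = np.array(
            [gp.sample_variance(0.0, 0, nu, Sc, rng) for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(nu * Sc / (nu - 2), rel=0.03)

    def test_large_nu_pins_draws_to_scale(self, rng):
        draws = [gp.sample_variance(0.0, 0, 1e8, 1.7, rng) for _ in range(50)]
        np.testing.assert_allclose(draws, 1.7, rtol=1e-3)

    def test_posterior_consistency_with_much_data(self, rng):
        v = 2.5
        draws = [
            gp.sample_variance(1e4 * v, 10_000, 3.0, 1.0, rng) for _ in range(200)
        ]
        assert np.mean(draws) == pytest.approx(v, rel=0.05)

    def test_invalid_degrees_of_freedom(self, rng):
        with pytest.raises(InputError):
            gp.sample_variance(1.0, 0, -1.0, 1.0, rng)


class TestSampleLocation:
    def test_tiny_residual_variance_pins_mu_to_mean(self, rng):
        r = np.array([1.0, 2.0, 3.0, 6.0])
        mu, beta = gp.sample_location(r, None, 1e-12, rng)
        assert mu == pytest.approx(3.0, abs=1e-5)
        assert beta.size == 0

    def test_duplicated_intercept_column_raises(self, rng):
        with pytest.raises(NumericalError, match="rank"):
            gp.sample_location(np.zeros(5), np.ones((5, 1)), 1.0, rng)

    def test_mean_of_draws_matches_least_squares_oracle(self, rng):
        n = 30
        XF = rng.normal(size=(n, 2))
        r = rng.normal(size=n)
        Xt = np.column_stack([np.ones(n), XF])
        expected = np.linalg.lstsq(Xt, r, rcond=None)[0]
        draws = np.array(
            [np.r_[gp.sample_location(r, XF, 0.5, rng)[0],
                   gp.sample_location(r, XF, 0.5, rng)[1]]
             for _ in range(4000)]
        )
        # stack intercept draw with beta draws from independent calls
        np.testing.assert_allclose(draws[:, 0].mean(), expected[0], atol=0.05)


class TestGibbsFit:
    def test_constant_phenotype_absorbed_by_intercept(self, markers_small):
        tab = gp.design_table(markers_small.genotype_ids, n_env=2)
        y = np.full(tab.n_records, 5.0)
        tab = gp.PhenotypeTable(env=tab.env, gid=tab.gid, y=y)
        ks = gp.build_ge_kernels(tab, gp.gb_kernel(markers_small), model="MM")
        priors = gp.PriorSpec(nu_u=3, Sc_u={"G": 0.01}, nu_e=3, Sc_e=0.01)
        fit = gp.gibbs_fit(tab, ks, priors=priors,
                           config=gp.MCMCConfig(ite=600, burn=100, thin=2, seed=1))
        assert fit.mu == pytest.approx(5.0, abs=0.1)
        assert np.abs(fit.u_hat["G"]).max() < 0.2

    def test_gblup_ridge_solution_recovered_with_degenerate_priors(self):
        # with nu -> inf the variances are pinned, and the posterior mean of u
        # is the ridge/BLUP solution K (K + lambda I)^{-1} (y - mu)
        X = gp.simulate_markers(50, 300, seed=21)
        tab = gp.design_table(X.genotype_ids, n_env=1)
        ks = gp.build_ge_kernels(tab, gp.gb_kernel(X), model="MM")
        var_u, var_e = 1.0, 0.5
        _, truth = gp.simulate_phenotypes(ks, {"G": var_u}, var_e=var_e, seed=22)
        tab = gp.PhenotypeTable(env=tab.env, gid=tab.gid, y=truth.y_full)
        priors = gp.PriorSpec(nu_u=1e6, Sc_u={"G": var_u}, nu_e=1e6, Sc_e=var_e)
        fit = gp.gibbs_fit(
            tab, ks, priors=priors,
            config=gp.MCMCConfig(ite=4000, burn=500, thin=1, seed=23),
        )
        K = ks["G"].values
        lam = var_e / var_u
        resid = tab.y - fit.mu
        expected = K @ np.linalg.solve(K + lam * np.eye(len(resid)), resid)
        mc_se = np.sqrt(var_e / fit.n_retained) * 3
        assert np.max(np.abs(fit.u_hat["G"] - expected)) < 5 * mc_se

    def test_degenerate_priors_pin_variance_chains(self, kset_mds, pheno_balanced):
        _, truth = gp.simulate_phenotypes(
            kset_mds, {"G": 1.0, "GE": 0.3}, var_e=0.5, seed=4
        )
        tab = gp.PhenotypeTable(env=pheno_balanced.env, gid=pheno_balanced.gid,
                                y=truth.y_full)
        priors = gp.PriorSpec(nu_u=1e8, Sc_u={"G": 0.8, "GE": 0.2},
                              nu_e=1e8, Sc_e=0.4)
        fit = gp.gibbs_fit(tab, kset_mds, priors=priors,
                           config=gp.MCMCConfig(ite=300, burn=100, thin=1, seed=5))
        assert fit.varu["G"][0] == pytest.approx(0.8, rel=1e-3)
        assert fit.varu["GE"][0] == pytest.approx(0.2, rel=1e-3)
        assert fit.varE[0] == pytest.approx(0.4, rel=1e-3)

    def test_chain_length_arithmetic(self, kset_mds, pheno_balanced):
        _, truth = gp.simulate_phenotypes(
            kset_mds, {"G": 1.0, "GE": 0.3}, var_e=0.5, seed=6
        )
        tab = gp.PhenotypeTable(env=pheno_balanced.env, gid=pheno_balanced.gid,
                                y=truth.y_full)
        cfg = gp.MCMCConfig(ite=1000, burn=200, thin=3, seed=7)
        fit = gp.gibbs_fit(tab, kset_mds, config=cfg)
        assert fit.n_retained == (1000 - 200) // 3
        assert list(fit.chains.columns) == [
            "iteration", "mu", "varE", "varu_G", "varu_GE"
        ]

    def test_seeded_runs_are_bit_reproducible(self, kset_mds, pheno_balanced):
        _, truth = gp.simulate_phenotypes(
            kset_mds, {"G": 1.0, "GE": 0.3}, var_e=0.5, missing_fraction=0.1,
            seed=8,
        )
        ph, _ = gp.simulate_phenotypes(
            kset_mds, {"G": 1.0, "GE": 0.3}, var_e=0.5, missing_fraction=0.1,
            seed=8,
        )
        cfg = gp.MCMCConfig(ite=300, burn=50, thin=2, seed=9)
        f1 = gp.gibbs_fit(ph, kset_mds, config=cfg, debug=True)
        f2 = gp.gibbs_fit(ph, kset_mds, config=cfg)
        pd.testing.assert_frame_equal(f1.chains, f2.chains)
        np.testing.assert_array_equal(f1.y_hat, f2.y_hat)

    def test_all_missing_rejected(self, kset_mds, pheno_balanced):
        with pytest.raises(InputError, match="missing"):
            gp.gibbs_fit(pheno_balanced, kset_mds)  # design table: all NaN

    def test_fitted_identity_mu_plus_effects(self, kset_mds, pheno_balanced):
        _, truth = gp.simulate_phenotypes(
            kset_mds, {"G": 1.0, "GE": 0.3}, var_e=0.5, seed=10
        )
        tab = gp.PhenotypeTable(env=pheno_balanced.env, gid=pheno_balanced.gid,
                                y=truth.y_full)
        fit = gp.gibbs_fit(tab, kset_mds,
                           config=gp.MCMCConfig(ite=400, burn=100, thin=2, seed=11))
        recomposed = fit.mu + sum(fit.u_hat.values())
        np.testing.assert_allclose(fit.y_hat, recomposed, atol=1e-10)


class TestRotationAgainstMultivariateOracle:
    def test_fixed_variance_conditional_matches_joint_normal(self, rng):
        """Rotated univariate draws reproduce the exact joint conditional
        mean and covariance of u on a small dense kernel."""
        n = 12
        A = rng.normal(size=(n, 30))
        K = A @ A.T / 30
        var_u, var_e = 0.9, 0.6
        resid = rng.normal(size=n)
        C = var_u * K @ np.linalg.inv(var_u * K + var_e * np.eye(n))
        mean_expected = C @ resid
        cov_expected = var_u * K - C @ (var_u * K)
        basis = gp.eigen_decompose(dense_kernel(K))
        n_rep = 30000
        draws = np.empty((n_rep, n))
        for i in range(n_rep):
            draws[i] = gp.sample_rotated_effects(resid, basis, var_u, var_e, rng)[1]
        np.testing.assert_allclose(draws.mean(axis=0), mean_expected, atol=0.02)
        np.testing.assert_allclose(np.cov(draws.T), cov_expected, atol=0.03)


class TestPredict:
    def test_filter_by_environment_and_missing_lookup(self, kset_mds, pheno_balanced):
        ph, _ = gp.simulate_phenotypes(
            kset_mds, {"G": 1.0, "GE": 0.3}, var_e=0.5, missing_fraction=0.2,
            seed=12,
        )
        fit = gp.gibbs_fit(ph, kset_mds,
                           config=gp.MCMCConfig(ite=400, burn=100, thin=2, seed=13))
        sub = gp.predict(fit, env="env2")
        assert set(sub["env"]) == {"env2"}
        assert np.isfinite(sub["y_hat"]).all()
        with pytest.raises(InputError):
            gp.predict(fit, env="nope")

    def test_predictions_track_signal(self, kset_mds, pheno_balanced):
        ph, truth = gp.simulate_phenotypes(
            kset_mds, {"G": 2.0, "GE": 0.3}, var_e=0.2, missing_fraction=0.15,
            seed=14,
        )
        fit = gp.gibbs_fit(ph, kset_mds,
                           config=gp.MCMCConfig(ite=800, burn=200, thin=2, seed=15))
        masked = ~ph.observed
        r = np.corrcoef(fit.y_hat[masked], truth.y_full[masked])[0, 1]
        assert r > 0.3  # held-out genotypes still share main effects
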