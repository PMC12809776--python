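import numpy as np
import pytest
from scipy import stats as sps

from dmscore.model import (
    McmcConfig,
    ModelSpec,
    check_convergence,
    fit,
    lfsr,
    log_joint,
    log_likelihood,
    prior_mean_beta,
)
from dmscore.preprocess import naive_scores


class TestLogLikelihood:
    def test_mean_arithmetic(self):
        # beta=2, T=2, t=1, b=0.1 -> mean 1.1; at t=0 the mean is b alone
        x = np.arange(3) / 2
        mean = 2.0 * x + 0.1
        assert mean[1] == pytest.approx(1.1)
        assert mean[0] == pytest.approx(0.1)

    def test_matches_dense_normal_logpdf(self):
        rng = np.random.default_rng(0)
        V, T, R = 7, 3, 2
        m = rng.normal(size=(V, T + 1, R))
        beta = rng.normal(size=V)
        b = rng.normal(size=V)
        gmap = rng.integers(0, 2, size=V)
        eps = np.array([0.3, 0.7])
        ours = log_likelihood(m, beta, b, eps, gmap, T)
        x = np.arange(T + 1) / T
        oracle = 0.0
        for v in range(V):
            for t in range(T + 1):
                for r in range(R):
                    oracle += sps.norm.logpdf(
                        m[v, t, r], beta[v] * x[t] + b[v], eps[gmap[v]]
                    )
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.zeros((1, 2, 1)), np.zeros(1), np.zeros(1),
                           np.array([0.0]), np.zeros(1, dtype=int), 1)


class TestPriorMean:
    def test_model3_arithmetic(self):
        mean = prior_mean_beta(
            np.array([-1.0]), np.array([-2.0]), np.array([0.5]),
            np.array([0]), np.array([0]), model_id=3,
        )
        assert mean[0] == pytest.approx(-2.0)

    def test_rho_one_reduces_to_model2(self):
        rng = np.random.default_rng(1)
        phi, nu = rng.normal(size=4), rng.normal(size=5)
        pmap = rng.integers(0, 4, size=20)
        amap = rng.integers(0, 5, size=20)
        m3 = prior_mean_beta(phi, nu, np.ones(4), pmap, amap, 3)
        m2 = prior_mean_beta(phi, nu, None, pmap, amap, 2)
        np.testing.assert_allclose(m3, m2)

    def test_synonymous_structural_zero(self, small_sim):
        assay, truth, scheme = small_sim
        nu = truth.nu
        assert nu[scheme.syn_group] == 0.0
        syn = (assay.variants["mclass"] == "synonymous").to_numpy()
        mean = prior_mean_beta(truth.phi, nu, truth.rho, assay.pmap,
                               scheme.amap, 3)
        np.testing.assert_allclose(
            mean[syn], truth.phi[assay.control_group]
        )


class TestLfsr:
    def test_counting(self):
        draws = np.array([[1.0, -1.0, 1.0], [2.0, 1.0, 1.0],
                          [3.0, -2.0, 1.0], [4.0, 2.0, -1.0]])
        np.testing.assert_allclose(lfsr(draws), [0.0, 0.5, 0.25])


class TestNesting:
    def test_log_joint_identities_on_fixture(self, small_sim):
        """Pinning rho to 1 reproduces the global-substitution model's
        density; pinning nu to 0 reproduces the position-only model."""
        assay, truth, scheme = small_sim
        rng = np.random.default_rng(0)
        n_pos = len(assay.position_labels)
        params = {
            "beta": rng.normal(size=assay.n_variants),
            "b": rng.normal(size=assay.n_variants),
            "phi": rng.normal(size=n_pos),
            "sigma2": rng.uniform(0.1, 1.0, n_pos),
            "eps": rng.uniform(0.1, 0.5, int(assay.gmap.max()) + 1),
            "z": rng.normal(size=scheme.n_free - 1),
            "rho": np.ones(n_pos),
        }
        lj3 = log_joint(assay, scheme, ModelSpec(3), params,
                        include_hyperpriors=False)
        lj2 = log_joint(assay, scheme, ModelSpec(2), params,
                        include_hyperpriors=False)
        assert lj3 == pytest.approx(lj2, abs=1e-8)

        params["z"] = np.zeros(scheme.n_free - 1)
        params["rho"] = rng.uniform(0.0, 1.0, n_pos)
        lj3b = log_joint(assay, scheme, ModelSpec(3), params,
                         include_hyperpriors=False)
        lj1 = log_joint(assay, None, ModelSpec(1), params,
                        include_hyperpriors=False)
        assert lj3b == pytest.approx(lj1, abs=1e-8)


class TestFit:
    def test_support_constraints_every_draw(self, default_fit):
        assay, truth, scheme, result = default_fit
        assert np.all(result.pooled("sigma2") > 0)
        assert np.all(result.pooled("eps") > 0)
        rho = result.pooled("rho")
        assert np.all((rho >= 0) & (rho <= 1))
        nu = result.pooled("nu")
        assert np.all(nu[:, scheme.syn_group] == 0.0)
        weighted = nu[:, scheme.free] @ scheme.w
        assert np.abs(weighted).max() < 1e-8

    def test_parameter_recovery(self, default_fit):
        from dmscore.simulate import recovery_report

        assay, truth, scheme, result = default_fit
        report = recovery_report(truth, result, assay)
        assert report["phi"]["pearson"] > 0.9
        assert report["beta"]["pearson"] > 0.9
        assert report["rho"]["pearson"] > 0.5
        assert report["nu"]["pearson"] > 0.8

    def test_shrinkage_toward_prior_mean(self, default_fit):
        """Posterior score of a variant sits between its raw least-squares
        slope and the prior mean (hierarchical shrinkage)."""
        assay, truth, scheme, result = default_fit
        ols = naive_scores(assay)
        beta_hat = result.mean("beta")
        prior = result.prior_mean_per_variant()
        moved = np.abs(beta_hat - prior) <= np.abs(ols - prior) + 1e-9
        assert moved.mean() > 0.9

    def test_seed_reproducibility(self, small_sim):
        assay, truth, scheme = small_sim
        mc = McmcConfig(seed=11, chains=2, warmup=100, samples=100)
        r1 = fit(assay, scheme, ModelSpec(3), mc)
        r2 = fit(assay, scheme, ModelSpec(3), mc)
        np.testing.assert_array_equal(r1.draws["beta"], r2.draws["beta"])

    def test_model2_and_model1_paths(self, small_sim):
        assay, truth, scheme = small_sim
        mc = McmcConfig(seed=12, chains=2, warmup=150, samples=150)
        r1 = fit(assay, None, ModelSpec(1), mc)
        assert "nu" not in r1.draws and "rho" not in r1.draws
        r2 = fit(assay, scheme, ModelSpec(2), mc)
        assert "nu" in r2.draws and "rho" not in r2.draws

    def test_missing_scheme_rejected(self, small_sim):
        assay, truth, scheme = small_sim
        with pytest.raises(ValueError, match="GroupingScheme"):
            fit(assay, None, ModelSpec(3), McmcConfig(seed=1))


class TestConvergence:
    def _result_from_chains(self, chains, default_fit):
        from dmscore.model import PosteriorResult

        assay, truth, scheme, result = default_fit
        return PosteriorResult(
            draws={"beta": chains, "phi": chains, "sigma2": np.abs(chains) + 1,
                   "eps": np.abs(chains) + 1},
            model_id=1, pmap=assay.pmap, amap=None, gmap=assay.gmap,
            position_labels=assay.position_labels, group_labels=None,
            control_group=assay.control_group, pseudo_groups=[],
            variant_ids=["v"],
        )

    def test_identical_chains_rhat_one(self, default_fit):
        rng = np.random.default_rng(0)
        one = rng.normal(size=(1, 400, 1))
        chains = np.repeat(one, 4, axis=0)
        result = self._result_from_chains(chains, default_fit)
        report = check_convergence(result, rhat_max=1.05)
        assert "beta" not in report["flagged"]

    def test_disjoint_chains_flagged(self, default_fit):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 400, 1)) + np.arange(4)[:, None, None] * 10
        result = self._result_from_chains(chains, default_fit)
        report = check_convergence(result, rhat_max=1.05)
        assert 0 in report["flagged"]["beta"]

    def test_recovery_fixture_converges(self, default_fit):
        assay, truth, scheme, result = default_fit
        report = check_convergence(result, rhat_max=1.1)
        assert report["max_rhat"] < 1.1
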