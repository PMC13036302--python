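"""Sampler kernels: exact conditionals, conjugacy, diagnostics, protocol."""

import numpy as np
import pytest
from scipy import stats

import msoccupancy as mo
from msoccupancy._kernels import (
    _det_ll_pair_np,
    _log_q0_np,
    _occ_ll_pair_np,
    det_ll_pair,
    log_q0,
    occ_ll_pair,
)
from msoccupancy.sampler import GibbsSampler, McmcConfig, init_state

from conftest import build_draws, build_model_data


@pytest.fixture
def single_cell():
    """1 species, 1 station, 1 occasion, y=0, psi=p=0.5 at zero params."""
    return build_model_data(np.array([[[0]]]))


class TestInit:
    def test_respects_data_constraints(self):
        y = np.zeros((2, 4, 2), dtype=np.int8)
        y[0, 0, 0] = 1  # species 0 detected at station 0 (area 0)
        data = build_model_data(y, area=[0, 0, 1, 1])
        rng = np.random.default_rng(0)
        params, hypers, latent = init_state(data, rng)
        assert latent.z[0, 0] == 1
        assert latent.w[0, 0] == 1
        # w=0 areas have all-zero z
        for k in range(2):
            for a in range(2):
                if latent.w[k, a] == 0:
                    assert latent.z[k, data.area_idx == a].sum() == 0

    def test_deterministic_given_seed(self, single_cell):
        a = init_state(single_cell, np.random.default_rng(5))
        b = init_state(single_cell, np.random.default_rng(5))
        assert np.array_equal(a[2].z, b[2].z)
        assert np.array_equal(a[2].w, b[2].w)


class TestLatentConditionals:
    def test_z_posterior_exact_third(self, single_cell):
        # psi=p=0.5, y=0: P(z=1) = 0.25/0.75 = 1/3
        s = GibbsSampler(single_cell, McmcConfig(seed=0),
                         rng=np.random.default_rng(8))
        s.latent.w[:] = 1
        n = 30000
        hits = sum(int(s.update_z().z[0, 0]) for _ in range(n))
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(hits / n - 1 / 3) < 3 * se

    def test_z_forced_by_detection_and_w(self):
        y = np.zeros((1, 2, 1), dtype=np.int8)
        y[0, 0, 0] = 1
        data = build_model_data(y, area=[0, 1])
        s = GibbsSampler(data, McmcConfig(seed=0),
                         rng=np.random.default_rng(0))
        s.latent.w[0] = [1, 0]
        for _ in range(50):
            z = s.update_z().z
            assert z[0, 0] == 1   # detection forces z=1
            assert z[0, 1] == 0   # excluded community forces z=0

    def test_z_vanishes_with_psi(self, single_cell):
        s = GibbsSampler(single_cell, McmcConfig(seed=0),
                         rng=np.random.default_rng(1))
        s.latent.w[:] = 1
        s.params.beta0[:] = -30.0  # psi -> 0
        assert all(s.update_z().z[0, 0] == 0 for _ in range(200))

    def test_w_posterior_three_sevenths(self, single_cell):
        # Omega=0.5, 1 site, 1 occasion, psi=p=0.5, y=0:
        # L1 = 0.5*0.5 + 0.5 = 0.75 -> P(w=1) = 0.375/0.875 = 3/7
        s = GibbsSampler(single_cell, McmcConfig(seed=0),
                         rng=np.random.default_rng(2))
        s.hypers.omega = 0.5
        n = 30000
        hits = 0
        for _ in range(n):
            hits += int(s.update_w().w[0, 0])
        se = np.sqrt((3 / 7) * (4 / 7) / n)
        assert abs(hits / n - 3 / 7) < 3 * se

    def test_w_forced_by_detection_and_omega(self):
        y = np.zeros((1, 2, 1), dtype=np.int8)
        y[0, 0, 0] = 1
        data = build_model_data(y, area=[0, 1])
        s = GibbsSampler(data, McmcConfig(seed=0),
                         rng=np.random.default_rng(3))
        assert all(s.update_w().w[0, 0] == 1 for _ in range(50))
        s.hypers.omega = 1 - 1e-12  # degenerate prior: w = 1 always
        assert all(s.update_w().w[0, 1] == 1 for _ in range(50))


class TestConjugateUpdates:
    def test_omega_matches_beta_posterior(self):
        prior = mo.PriorConfig()
        rng = np.random.default_rng(4)
        w = np.zeros((28, 2), dtype=np.int8)
        w[:17, 0] = 1
        w[:12, 1] = 1  # sum w = 29 of 56
        s = int(w.sum())
        draws = np.array([mo.sample_omega(w, prior, rng)
                          for _ in range(3000)])
        ref = stats.beta(prior.omega_shape1 + s,
                         prior.omega_shape2 + w.size - s)
        assert stats.kstest(draws, ref.cdf).pvalue > 0.01

    def test_omega_all_included_shape(self):
        # all w=1 with 28 species x 2 areas -> beta(56.001, 1): draws
        # concentrate just below 1
        prior = mo.PriorConfig()
        rng = np.random.default_rng(5)
        w = np.ones((28, 2), dtype=np.int8)
        draws = np.array([mo.sample_omega(w, prior, rng)
                          for _ in range(2000)])
        ref = stats.beta(56.001, 1.0)
        assert stats.kstest(draws, ref.cdf).pvalue > 0.01

    def test_mu_conditional_matches_normal_normal_algebra(self, single_cell):
        s = GibbsSampler(single_cell, McmcConfig(seed=0),
                         rng=np.random.default_rng(6))
        x = np.array([0.4, 0.9, 1.3, 0.2, 0.7])
        sigma = 0.5
        v0 = s.prior.mean_sd ** 2
        var = 1 / (1 / v0 + len(x) / sigma ** 2)
        mean = var * x.sum() / sigma ** 2
        draw = s._update_group(x, s.rng)
        mus = np.array([draw(0.0, sigma)[0] for _ in range(4000)])
        assert mus.mean() == pytest.approx(mean, abs=4 * np.sqrt(var / 4000))
        assert mus.std() == pytest.approx(np.sqrt(var), rel=0.1)

    def test_sigma_slice_respects_support(self, single_cell):
        s = GibbsSampler(single_cell, McmcConfig(seed=0),
                         rng=np.random.default_rng(7))
        draw = s._update_group(np.array([8.0, -8.0, 9.0]), s.rng)
        sig = 1.0
        for _ in range(300):
            _, sig = draw(0.0, sig)
            assert 0.0 < sig <= s.prior.sigma_upper


class TestCoefficientUpdates:
    def test_flat_likelihood_samples_the_prior(self):
        # all effort masked: alpha1's conditional is its normal prior
        data = build_model_data(np.zeros((3, 2, 2), dtype=np.int8),
                                effort_days=np.zeros((2, 2), dtype=int))
        s = GibbsSampler(data, McmcConfig(seed=0, prop_sd_init=1.0),
                         rng=np.random.default_rng(9))
        s.hypers.mu_alpha1 = 0.7
        s.hypers.sigma_alpha1 = 0.5
        vals = []
        for t in range(4000):
            s.update_coefficients(adapt=t < 500)
            if t >= 500:
                vals.append(s.params.alpha1.copy())
        vals = np.array(vals).ravel()
        n_eff = vals.size / 10  # generous autocorrelation discount
        assert vals.mean() == pytest.approx(
            0.7, abs=3 * 0.5 / np.sqrt(n_eff))
        assert vals.std() == pytest.approx(0.5, rel=0.15)

    def test_zero_proposal_sd_rejected(self):
        with pytest.raises(ValueError, match="proposal SD"):
            McmcConfig(prop_sd_init=0.0)


class TestKernelEquivalence:
    """Compiled kernels agree with the pure-numpy formulations."""

    def test_all_three_kernels(self):
        rng = np.random.default_rng(12)
        K, I, J = 4, 7, 3
        yf = (rng.random((K, I, J)) < 0.3).astype(float)
        eff = rng.random((I, J)) < 0.9
        yf *= eff
        z = (rng.random((K, I)) < 0.7).astype(np.int8)
        day = rng.normal(size=(I, J))
        a0c, a0n = rng.normal(size=(2, K, I))
        a1c, a1n = rng.normal(size=(2, K, I)) * 0.3
        group = rng.integers(0, 4, I).astype(np.int64)
        for got, want in zip(
            det_ll_pair(yf, eff, z, a0c, a0n, a1c, a1n, day, group, 4),
            _det_ll_pair_np(yf, eff, z, a0c, a0n, a1c, a1n, day, group, 4),
        ):
            assert np.allclose(got, want, atol=1e-9)
        lp_cur, lp_new = rng.normal(size=(2, K, I))
        elig = (rng.random((K, I)) < 0.8).astype(np.int8)
        for got, want in zip(
            occ_ll_pair(z, elig, lp_cur, lp_new, group, 4),
            _occ_ll_pair_np(z, elig, lp_cur, lp_new, group, 4),
        ):
            assert np.allclose(got, want, atol=1e-9)
        assert np.allclose(log_q0(eff, a0c, a1c, day),
                           _log_q0_np(eff, a0c, a1c, day), atol=1e-9)


class TestProtocol:
    def test_retained_draw_arithmetic(self):
        cfg = McmcConfig(n_chains=2, n_iter=1000, n_adapt=100, thin=10)
        assert mo.n_retained(cfg) == 200
        assert McmcConfig().n_retained_per_chain == 7500

    def test_same_seed_bit_identical(self):
        y = np.zeros((2, 3, 2), dtype=np.int8)
        y[0, 0, 0] = 1
        data = build_model_data(y, area=[0, 0, 1])
        cfg = McmcConfig(n_chains=2, n_iter=100, n_adapt=50, thin=5, seed=77)
        d1 = mo.run_mcmc(data, cfg)
        d2 = mo.run_mcmc(data, cfg)
        for name in d1.params:
            assert np.array_equal(d1.params[name], d2.params[name])
        assert np.array_equal(d1.ft_rep, d2.ft_rep)

    def test_retained_draws_are_finite(self, small_fit):
        _, _, draws = small_fit
        for name, arr in draws.params.items():
            assert np.all(np.isfinite(arr)), name


class TestRhat:
    def test_constant_chains_flagged_not_failed(self):
        draws = build_draws(n=50)
        draws.params = {k: np.concatenate([v, v])
                        for k, v in draws.params.items()}
        tab = mo.rhat(draws, include_species=False)
        assert (tab["rhat"] == 1.0).all()
        assert tab["zero_variance"].all()
        assert not tab.loc[~tab["zero_variance"], "flagged"].any()

    def test_stationary_vs_disjoint_chains(self):
        rng = np.random.default_rng(13)
        good = build_draws(n=400)
        good.params["omega"] = rng.uniform(0.3, 0.7, (1, 400))
        # fake a second chain from the same stationary distribution
        for d, shift in ((good, 0.0),):
            pass
        stacked = {k: np.concatenate([v, v[:, rng.permutation(400)]])
                   for k, v in good.params.items()}
        good2 = build_draws(n=400)
        good2.params = stacked
        good2.site_richness = np.zeros((2, 400, 4), np.int16)
        good2.ft_obs = np.zeros((2, 400))
        good2.ft_rep = np.zeros((2, 400))
        tab = mo.rhat(good2, include_species=False)
        assert tab.loc["omega", "rhat"] < 1.05

        bad = build_draws(n=400)
        arr = np.concatenate([
            rng.normal(-10, 1, (1, 400)), rng.normal(10, 1, (1, 400))])
        bad.params = {k: np.concatenate([v, v]) for k, v in bad.params.items()}
        bad.params["mu.alpha1"] = arr
        bad.site_richness = np.zeros((2, 400, 4), np.int16)
        bad.ft_obs = np.zeros((2, 400))
        bad.ft_rep = np.zeros((2, 400))
        tab = mo.rhat(bad, include_species=False)
        assert tab.loc["mu.alpha1", "rhat"] > 1.1
        assert tab.loc["mu.alpha1", "flagged"]

    def test_single_chain_is_an_error(self):
        draws = build_draws(n=50)
        draws.params = {k: v[:1] for k, v in draws.params.items()}
        with pytest.raises(ValueError, match="2 chains"):
            mo.rhat(draws)


class TestPersistence:
    def test_save_load_roundtrip(self, small_fit, tmp_path):
        _, _, draws = small_fit
        path = tmp_path / "draws.npz"
        mo.save_draws(draws, path)
        back = mo.load_draws(path)
        for name in draws.params:
            assert np.array_equal(draws.params[name], back.params[name])
        assert np.array_equal(draws.site_richness, back.site_richness)
        assert back.meta["species_index"] == draws.meta["species_index"]
        assert np.allclose(back.meta["standardization"].sd,
                           draws.meta["standardization"].sd)

    def test_long_frame_shape(self, small_fit):
        _, _, draws = small_fit
        df = mo.draws_long_frame(draws)
        n_scalars = len(draws.flat_params(include_species=False))
        assert len(df) == n_scalars * draws.n_total
        assert set(df.columns) == {"chain", "draw", "parameter", "value"}
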