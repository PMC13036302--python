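"""Posterior summaries: closed-form cases and invariants on a real fit."""

import numpy as np
import pytest
from scipy.special import expit

import msoccupancy as mo

from conftest import build_draws


class TestSpeciesOccupancy:
    def test_point_mass_intercepts(self):
        draws = build_draws(beta0=np.log(3.0))
        tab = mo.species_occupancy_at_mean(draws)
        assert np.allclose(tab["psi_mean"], 0.75)
        assert np.allclose(tab["psi_lo85"], 0.75)
        assert np.allclose(tab["psi_hi85"], 0.75)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(0)
        n = 4000
        b = rng.normal(-0.4, 0.8, (1, n, 1, 2))
        draws = build_draws(n=n, n_species=1, beta0=b)
        tab = mo.species_occupancy_at_mean(draws)
        want = expit(b[0, :, 0, 0]).mean()
        se = expit(b[0, :, 0, 0]).std() / np.sqrt(n)
        assert tab.loc[tab.area == "UAX", "psi_mean"].iloc[0] == pytest.approx(
            want, abs=3 * se)

    def test_intervals_ordered_and_nested(self, small_fit):
        _, _, draws = small_fit
        tab = mo.species_occupancy_at_mean(draws)
        assert (tab["psi_lo85"] <= tab["psi_lo66"] + 1e-12).all()
        assert (tab["psi_lo66"] <= tab["psi_hi66"] + 1e-12).all()
        assert (tab["psi_hi66"] <= tab["psi_hi85"] + 1e-12).all()
        assert tab["psi_mean"].between(0, 1).all()


class TestCommunityOccupancy:
    def test_average_over_included_species(self):
        b = np.zeros((2, 2))
        b[0] = np.log(0.2 / 0.8)  # psi = 0.2
        b[1] = np.log(0.6 / 0.4)  # psi = 0.6
        draws = build_draws(n_species=2, beta0=b)
        tab = mo.mean_community_occupancy(draws)
        assert np.allclose(tab["mean"], 0.4, atol=1e-12)

    def test_empty_community_draws_excluded(self):
        draws = build_draws(n_species=2, w=np.zeros((2, 2)))
        tab = mo.mean_community_occupancy(draws)
        assert (tab["n_draws_excluded"] == draws.n_total).all()
        assert tab["mean"].isna().all()

    def test_bounded_by_species_range_per_draw(self, small_fit):
        _, _, draws = small_fit
        psi = mo.psi_at_mean_draws(draws)
        w = draws.stacked("w")
        tab, per_area = mo.mean_community_occupancy(draws, return_draws=True)
        for a, area in enumerate(mo.AREAS):
            inc = w[:, :, a] > 0
            valid = inc.any(axis=1)
            mins = np.where(inc[valid], psi[valid, :, a], np.inf).min(axis=1)
            maxs = np.where(inc[valid], psi[valid, :, a], -np.inf).max(axis=1)
            avg = per_area[area]
            assert np.all(avg >= mins - 1e-12)
            assert np.all(avg <= maxs + 1e-12)


class TestAccessOdds:
    def test_closed_forms(self):
        # beta1 * hours / SD = ln 2  ->  +100%
        draws = build_draws(beta1=np.log(2.0), access_sd=6.0)
        tab = mo.access_odds_change(draws, hours=6.0)
        assert np.allclose(tab["pct_change"], 100.0)
        # beta1 = 0.5, SD = 6, hours = 6 -> exp(0.5) - 1 = +64.9%
        draws = build_draws(beta1=0.5, access_sd=6.0)
        tab = mo.access_odds_change(draws, hours=6.0)
        assert np.allclose(tab["pct_change"],
                           (np.exp(0.5) - 1) * 100, atol=1e-9)
        draws = build_draws(beta1=0.0)
        assert np.allclose(
            mo.access_odds_change(draws)["pct_change"], 0.0)

    def test_invariant_to_restandardization(self):
        # the raw-hours odds ratio must not depend on the access SD used
        # for standardization: beta1 rescales inversely
        for sd in (2.0, 6.0, 11.0):
            slope_std = 0.12 * sd  # same raw-scale effect
            tab = mo.access_odds_change(
                build_draws(beta1=slope_std, access_sd=sd), hours=6.0)
            assert np.allclose(tab["pct_change"],
                               (np.exp(0.12 * 6) - 1) * 100, atol=1e-9)

    def test_nonpositive_hours_rejected(self):
        with pytest.raises(ValueError):
            mo.access_odds_change(build_draws(), hours=0.0)


class TestProbHigher:
    def test_tie_split_is_half(self):
        draws = build_draws(beta0=0.3)  # identical in both areas
        tab = mo.prob_higher_in_area(draws)
        assert np.allclose(tab["pr_higher_mranp"], 0.5)
        assert (tab["classification"] == "indeterminate").all()

    def test_disjoint_and_partial_overlap(self):
        n = 1000
        b = np.zeros((1, n, 1, 2))
        b[..., 1] = 1.0  # MRANP always larger
        tab = mo.prob_higher_in_area(build_draws(n=n, n_species=1, beta0=b))
        assert tab["pr_higher_mranp"].iloc[0] == 1.0
        assert tab["classification"].iloc[0] == "higher"
        b = np.zeros((1, n, 1, 2))
        b[0, :700, 0, 1] = 0.5  # larger in exactly 70% of draws
        b[0, 700:, 0, 1] = -0.5
        tab = mo.prob_higher_in_area(build_draws(n=n, n_species=1, beta0=b))
        assert tab["pr_higher_mranp"].iloc[0] == pytest.approx(0.70)
        assert tab["classification"].iloc[0] == "higher"


class TestContrasts:
    def test_logistic_closed_form(self):
        # slope 1 over standardized range [-2, 2] at beta0=0:
        # delta = logit^-1(2) - logit^-1(-2) ~ 0.762
        draws = build_draws(beta1=1.0)
        tab, dom = mo.covariate_effect_contrasts(draws)
        acc = tab[(tab.covariate == "access")]
        assert np.allclose(acc["delta_psi_mean"],
                           expit(2) - expit(-2), atol=1e-12)
        hab = tab[tab.covariate != "access"]
        assert np.allclose(hab["delta_psi_mean"], 0.0)
        assert dom["access_dominates"].all()

    def test_sign_follows_slope_and_range(self):
        draws = build_draws(beta1=-0.8)
        tab, _ = mo.covariate_effect_contrasts(draws)
        acc = tab[tab.covariate == "access"]
        assert (acc["delta_psi_mean"] < 0).all()

    def test_zero_width_range_rejected(self):
        draws = build_draws()
        for key in draws.meta["cov_range_std"]:
            draws.meta["cov_range_std"][key] = np.tile([0.3, 0.3], (6, 1))
        with pytest.raises(ValueError, match="zero-width"):
            mo.covariate_effect_contrasts(draws)


class TestRichness:
    def test_sums_and_modal_tiebreak(self):
        n = 10
        w = np.ones((1, n, 3, 2), dtype=np.int8)
        w[0, :5, 2, 0] = 0  # area UAX: 5 draws at 2, 5 draws at 3 -> mode 2
        sr = np.full((1, n, 4), 3, dtype=np.int16)
        draws = build_draws(n=n, n_species=3, w=w, site_richness=sr)
        site_df, area_df = mo.richness_summaries(draws)
        assert area_df.loc[area_df.area == "UAX",
                           "modal_richness"].iloc[0] == 2
        assert area_df.loc[area_df.area == "MRANP",
                           "modal_richness"].iloc[0] == 3
        assert np.allclose(site_df["richness_mean"], 3.0)
        assert np.allclose(site_df["richness_sd"], 0.0)

    def test_area_richness_at_least_observed(self, small_fit):
        sv, data, draws = small_fit
        w = draws.stacked("w")
        for a in range(2):
            observed = int(((sv.truth.y[:, data.area_idx == a, :]
                             .sum(axis=(1, 2))) > 0).sum())
            assert w[:, :, a].sum(axis=1).min() >= observed


class TestRichnessVsAccess:
    def test_exact_linear_and_constant(self):
        import pandas as pd
        x = np.array([1.0, 3.0, 7.0, 11.0, 2.0, 8.0, 15.0, 21.0])
        site_df = pd.DataFrame({
            "station": [f"s{i}" for i in range(8)],
            "area": ["UAX"] * 4 + ["MRANP"] * 4,
            "access_hours": x,
            "richness_mean": x,  # richness == access -> slope 1, r = 1
        })
        tab = mo.richness_vs_access(site_df, n_boot=200, seed=1)
        assert np.allclose(tab["slope"], 1.0, atol=1e-10)
        assert np.allclose(tab["r"], 1.0, atol=1e-10)
        site_df["richness_mean"] = 5.0
        tab = mo.richness_vs_access(site_df, n_boot=200, seed=1)
        assert np.allclose(tab["slope"], 0.0, atol=1e-10)

    def test_noisy_linear_recovers_truth(self):
        import pandas as pd
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 20, 60)
        y = 4 + 0.25 * x + rng.normal(0, 0.5, 60)
        site_df = pd.DataFrame({
            "station": [f"s{i}" for i in range(60)],
            "area": ["UAX"] * 30 + ["MRANP"] * 30,
            "access_hours": x, "richness_mean": y})
        tab = mo.richness_vs_access(site_df, n_boot=500, seed=3)
        for _, row in tab.iterrows():
            assert row["slope_lo95"] <= 0.25 <= row["slope_hi95"]

    def test_too_few_stations(self):
        import pandas as pd
        site_df = pd.DataFrame({
            "station": ["a", "b", "c"], "area": ["UAX", "UAX", "MRANP"],
            "access_hours": [1.0, 2.0, 3.0], "richness_mean": [4, 5, 6]})
        with pytest.raises(ValueError, match="fewer than 3"):
            mo.richness_vs_access(site_df)


class TestGof:
    def test_degenerate_all_zero_fit(self):
        # T(y)=0 everywhere; ties count as extreme -> p = 1
        draws = build_draws()
        assert mo.bayesian_p_value(draws) == 1.0

    def test_probability_range(self, small_fit):
        _, _, draws = small_fit
        p = mo.bayesian_p_value(draws)
        assert 0.0 <= p <= 1.0


class TestReport:
    def test_all_tables_written(self, small_fit, tmp_path):
        _, _, draws = small_fit
        paths = mo.summary_report(draws, tmp_path)
        for name in ("species_occupancy", "access_effects", "prob_higher",
                     "covariate_contrasts", "access_dominance",
                     "richness_site", "richness_area", "richness_vs_access",
                     "community", "gof"):
            assert paths[name].exists(), name
        import pandas as pd
        occ = pd.read_csv(paths["species_occupancy"])
        K = len(draws.species_index)
        assert len(occ) == K * 2
        assert occ["reportable"].dtype == bool
        gof = paths["gof"].read_text()
        assert "p-value" in gof

    def test_sparse_species_flagged_not_reportable(self, small_fit, tmp_path):
        sv, data, draws = small_fit
        paths = mo.summary_report(draws, tmp_path, min_detections=10)
        import pandas as pd
        occ = pd.read_csv(paths["species_occupancy"])
        det = np.asarray(draws.meta["det_counts"])
        sp = draws.species_index
        for _, row in occ.iterrows():
            n = det[sp.index(row.species), mo.AREAS.index(row.area)]
            assert row["reportable"] == (n >= 10)


class TestPlots:
    def test_figure_set_written(self, small_fit, tmp_path):
        from msoccupancy.plotting import (
            caterpillar_access_effects,
            occupancy_vs_access_curves,
        )
        _, _, draws = small_fit
        p1 = caterpillar_access_effects(draws, tmp_path / "cat.png")
        p2 = occupancy_vs_access_curves(draws, tmp_path / "curves.png")
        assert p1.stat().st_size > 0
        assert p2.stat().st_size > 0
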