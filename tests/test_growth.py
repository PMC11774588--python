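"""State-space growth fit: reductions, prediction, derived curves."""

import numpy as np
import pytest

import charrgrowth as cg
from charrgrowth.data_io import JUNE, AUGUST
from charrgrowth.growth import asymptotic_size, asymptotic_size_from, simulate_growth_functions

from conftest import fake_growth_draws
from test_data_io import full_temps, make_captures


class TestArithmeticReduction:
    def test_single_noiseless_interval_pins_summer_growth(self):
        # 100 mm -> 110 mm over one 67-day summer with no noise anywhere:
        # the growth intercept is forced to 10 mm / 2 summer months
        caps, occs = make_captures(
            [("a", "c1", 2013, JUNE, 100.0), ("a", "c1", 2013, AUGUST, 110.0)]
        )
        panel = cg.build_panel(caps, full_temps(occs, ["c1"]), occs)
        draws = cg.fit_growth(
            panel,
            eta_sq=0.0,
            mcmc=cg.MCMCConfig(chains=2, draws=400, warmup=400, rhat_threshold=10),
            seed=1,
            ablations=("no_temperature",),
            include_random_effects=False,
            include_size_dependence=False,
        )
        assert draws.summary("alpha[summer]")["mean"] == pytest.approx(5.0, abs=1.0)

    def test_missing_eta_is_an_error(self, oracle_dataset):
        panel, _ = oracle_dataset
        with pytest.raises(cg.DataError, match="estimate_measurement_error"):
            cg.fit_growth(panel, eta_sq=None)

    def test_too_few_caves_is_an_error(self):
        caps, occs = make_captures(
            [("a", "c1", 2013, JUNE, 100.0), ("a", "c1", 2013, AUGUST, 110.0)]
        )
        panel = cg.build_panel(caps, full_temps(occs, ["c1"]), occs)
        with pytest.raises(cg.DataError, match="2 caves"):
            cg.fit_growth(panel, eta_sq=0.0)

    def test_unknown_ablation_rejected(self, oracle_dataset):
        panel, _ = oracle_dataset
        with pytest.raises(ValueError, match="ablation"):
            cg.fit_growth(panel, eta_sq=0.0, ablations=("no_gravity",))


class TestPrediction:
    def test_measured_occasion_is_reproduced_without_noise(self, oracle_fit):
        panel, _, draws = oracle_fit
        f = int(np.argmax(panel.last - panel.first))
        occ = int(panel.first[f])
        pred = cg.predict_size(draws, panel.fish_ids[f], occ)
        assert pred["mean"] == pytest.approx(panel.obs[f, occ], abs=1e-6)

    def test_occasion_outside_support_is_an_error(self, oracle_fit):
        panel, _, draws = oracle_fit
        f = int(np.argmax(panel.first))  # a fish recruited late
        with pytest.raises(KeyError, match="outside"):
            cg.predict_size(draws, panel.fish_ids[f], int(panel.first[f]) - 1)

    def test_interior_masked_sizes_interpolate_their_neighbours(self, masked_fit):
        panel, masked, picks, draws = masked_fit
        checked = 0
        for fish_id, occ in picks:
            f = panel.fish_index(fish_id)
            if np.isnan(masked.obs[f, occ - 1]) or np.isnan(masked.obs[f, occ + 1]):
                continue
            lo = min(masked.obs[f, occ - 1], masked.obs[f, occ + 1])
            hi = max(masked.obs[f, occ - 1], masked.obs[f, occ + 1])
            pred = cg.predict_size(draws, fish_id, occ)
            assert lo - 8.0 < pred["mean"] < hi + 8.0
            checked += 1
        assert checked >= 3

    def test_masking_leaves_fixed_effects_within_three_posterior_sd(
        self, oracle_fit, masked_fit
    ):
        _, _, full = oracle_fit
        _, _, _, masked = masked_fit
        for name in ("alpha[summer]", "alpha[winter]", "slope[summer]", "slope[winter]"):
            a, b = full.summary(name), masked.summary(name)
            sd = max(a["sd"], b["sd"])
            assert abs(a["mean"] - b["mean"]) < 3 * sd, name


class TestAblations:
    @pytest.fixture(scope="class")
    def tiny_panel(self):
        from conftest import tiny_config

        cfg = tiny_config()
        caps, occs, temps, _, _ = cg.simulate_dataset(cfg, seed=51)
        return cg.build_panel(caps, temps, occs)

    def test_no_temperature_drops_the_covariate_and_its_submodel(self, tiny_panel):
        mcmc = cg.MCMCConfig(chains=2, draws=200, warmup=200, rhat_threshold=10)
        draws = cg.fit_growth(
            tiny_panel, 0.6, mcmc=mcmc, seed=1, ablations=("no_temperature",)
        )
        assert "alpha_temp[summer]" not in draws.scalars
        assert "T_mean[summer]" not in draws.scalars
        assert "alpha[summer]" in draws.scalars

    def test_no_season_pools_growth_parameters(self, tiny_panel):
        mcmc = cg.MCMCConfig(chains=2, draws=200, warmup=200, rhat_threshold=10)
        draws = cg.fit_growth(
            tiny_panel, 0.6, mcmc=mcmc, seed=2, ablations=("no_season",)
        )
        assert draws.coords["season_labels"] == ["all"]
        assert "alpha[all]" in draws.scalars
        assert "alpha[summer]" not in draws.scalars
        # the temperature submodel keeps its real seasonal structure
        assert "T_mean[summer]" in draws.scalars

    def test_month_convention_override_rescales_rates(self, tiny_panel):
        mcmc = cg.MCMCConfig(chains=2, draws=250, warmup=250, rhat_threshold=10)
        base = cg.fit_growth(tiny_panel, 0.6, mcmc=mcmc, seed=3)
        halved = cg.fit_growth(
            tiny_panel, 0.6, mcmc=mcmc, seed=3,
            month_days={"summer": 67.0, "winter": 59.6},  # twice the default
        )
        a1 = base.summary("alpha[summer]")["mean"]
        a2 = halved.summary("alpha[summer]")["mean"]
        assert a2 == pytest.approx(2 * a1, rel=0.25)


class TestRelabelling:
    def test_cave_relabelling_does_not_move_the_posterior(self):
        from conftest import tiny_config

        cfg = tiny_config()
        caps, occs, temps, _, _ = cg.simulate_dataset(cfg, seed=31)
        relabel = {"cave00": "zebra", "cave01": "yak", "cave02": "xerus"}
        caps2 = [
            cg.CaptureRecord(
                "fish_" + c.fish_id, relabel[c.cave_id], c.occasion,
                c.fork_length_mm, c.capture_date,
            )
            for c in caps
        ]
        temps2 = [
            cg.TemperatureRecord(relabel[t.cave_id], t.year, t.season, t.mean_temp_C)
            for t in temps
        ]
        mcmc = cg.MCMCConfig(chains=2, draws=400, warmup=400, rhat_threshold=10)
        d1 = cg.fit_growth(cg.build_panel(caps, temps, occs), 0.6, mcmc=mcmc, seed=5)
        d2 = cg.fit_growth(cg.build_panel(caps2, temps2, occs), 0.6, mcmc=mcmc, seed=5)
        for name in ("alpha[summer]", "alpha[winter]", "slope[summer]",
                      "V_resid[summer]", "V_resid[winter]", "mu0"):
            a, b = d1.summary(name), d2.summary(name)
            mcse = max(a["sd"], b["sd"]) / np.sqrt(50)  # conservative ESS floor
            assert abs(a["mean"] - b["mean"]) < 4 * mcse, name


class TestGrowthCurves:
    def test_zero_variance_curves_collapse_to_the_fixed_line(self):
        draws = fake_growth_draws(jitter=0.0, v_alpha=(0.0, 0.0), v_slope=(0.0, 0.0))
        out = simulate_growth_functions(draws, n_curves=20, seed=0)
        zc = out["size_mm"] - draws.meta["center_size"]
        for season, alpha, slope in (("summer", 3.4, -0.05), ("winter", 0.82, -0.02)):
            for level in ("cave", "year", "caveyear"):
                curves = out["curves"][season][level]
                spread = curves.std(axis=0).max()
                assert spread < 0.4  # only posterior spread of the fixed effects
                assert np.allclose(curves.mean(axis=0), alpha + slope * zc, atol=0.2)

    def test_zero_slope_gives_horizontal_curves(self):
        draws = fake_growth_draws(
            jitter=0.0, slope=(0.0, 0.0), v_slope=(0.0, 0.0)
        )
        # kill the posterior spread of the slope itself
        for season in ("summer", "winter"):
            draws.scalars[f"slope[{season}]"][:] = 0.0
        out = simulate_growth_functions(draws, n_curves=10, seed=1)
        for season in ("summer", "winter"):
            curves = out["curves"][season]["cave"]
            assert np.allclose(curves, curves[:, :1], atol=1e-9)

    def test_spatial_slope_spread_matches_posterior_variance(self):
        v_b = 2.5e-4
        draws = fake_growth_draws(jitter=0.0, v_slope=(v_b, v_b))
        for season in ("summer", "winter"):
            draws.scalars[f"slope[{season}]"][:] = -0.05  # isolate the deviations
        out = simulate_growth_functions(draws, n_curves=600, seed=2, n_grid=2)
        for season in ("summer", "winter"):
            curves = out["curves"][season]["cave"]
            span = out["size_mm"][-1] - out["size_mm"][0]
            slopes = (curves[:, -1] - curves[:, 0]) / span
            assert slopes.std() == pytest.approx(np.sqrt(v_b), rel=0.2)

    def test_unknown_level_rejected(self):
        draws = fake_growth_draws()
        with pytest.raises(ValueError, match="level"):
            simulate_growth_functions(draws, levels=("continent",))


class TestAsymptoticSize:
    def test_root_at_centring_point_when_alpha_is_zero(self):
        z, n_undef = asymptotic_size_from(np.zeros(5), np.full(5, -0.01), 92.0)
        assert n_undef == 0
        assert np.allclose(z, 92.0)

    def test_hand_computed_example(self):
        z, _ = asymptotic_size_from(np.array([1.0]), np.array([-0.01]), 92.0)
        assert z[0] == pytest.approx(192.0)

    def test_non_negative_slopes_are_flagged_not_dropped(self):
        z, n_undef = asymptotic_size_from(
            np.array([1.0, 1.0, 1.0]), np.array([-0.01, 0.0, 0.02]), 92.0
        )
        assert n_undef == 2
        assert np.isnan(z[1]) and np.isnan(z[2])
        assert np.isfinite(z[0])

    def test_annualised_summary_from_draws(self):
        draws = fake_growth_draws(jitter=0.0, seed=3)
        out = asymptotic_size(draws)
        # annual: alpha = 2*3.4 + 10*0.82 = 15, slope = 2*-0.05 + 10*-0.02 = -0.3
        assert out["mean"] == pytest.approx(92.0 + 15.0 / 0.3, rel=0.05)
        assert out["n_undefined"] + np.isfinite(out["draws"]).sum() == out["draws"].size
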