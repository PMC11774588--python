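"""Variance derivations: covariate rule, unit conversion, R decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import charrgrowth as cg
from charrgrowth.data_io import AUGUST, JUNE
from charrgrowth.variance import (
    convert_slope_variance,
    fork_length_variance,
    repeatability,
    temperature_associated_variance,
)

from conftest import fake_growth_draws
from test_data_io import full_temps, make_captures


class TestTemperatureAssociatedVariance:
    def test_zero_effect_gives_zero(self):
        draws = fake_growth_draws(jitter=0.0, alpha_temp=(0.0, 0.0))
        draws.scalars["alpha_temp[summer]"][:] = 0.0
        v = temperature_associated_variance(draws, "year", "summer")
        assert np.allclose(v, 0.0)

    def test_hand_multiplied_example(self):
        # year temperature variance 0.15, effect 0.40 per month per C
        draws = fake_growth_draws(jitter=0.0)
        draws.scalars["V_year_T[summer]"][:] = 0.15
        draws.scalars["alpha_temp[summer]"][:] = 0.40
        v = temperature_associated_variance(draws, "year", "summer")
        assert np.allclose(v, 0.024)

    def test_matches_brute_force_variance_of_effect_times_covariate(self):
        # V(a + b x) = b^2 V(x): simulate year effects and check empirically
        rng = np.random.default_rng(0)
        v_x, effect = 0.15, 0.4
        x = rng.normal(0.0, np.sqrt(v_x), 200_000)
        brute = np.var(effect * x)
        draws = fake_growth_draws(jitter=0.0)
        draws.scalars["V_year_T[summer]"][:] = v_x
        draws.scalars["alpha_temp[summer]"][:] = effect
        analytic = temperature_associated_variance(draws, "year", "summer")[0]
        assert brute == pytest.approx(analytic, rel=0.02)

    def test_absent_component_under_ablation_is_an_error(self):
        draws = fake_growth_draws()
        del draws.scalars["alpha_temp[summer]"]
        with pytest.raises(cg.DataError, match="ablation"):
            temperature_associated_variance(draws, "year", "summer")

    def test_unknown_level_rejected(self):
        with pytest.raises(KeyError):
            temperature_associated_variance(fake_growth_draws(), "galaxy", "summer")


class TestSlopeVarianceConversion:
    def test_zero_and_printed_pair(self):
        assert convert_slope_variance(np.array([0.0]), 24.0)[0] == 0.0
        # the printed pair: V_b = 0.001 with sigma_fl^2 = 24 -> 0.024
        assert convert_slope_variance(np.array([0.001]), 24.0)[0] == pytest.approx(0.024)

    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 5))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_sigma_fl(self, scale, seed):
        vb = np.abs(np.random.default_rng(seed).normal(0, 1e-3, 50))
        a = convert_slope_variance(vb, scale)
        b = convert_slope_variance(vb, 2 * scale)
        assert np.allclose(b, 2 * a)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            convert_slope_variance(np.array([1.0]), -1.0)


def _panel_with_august_lengths(values, n_caves=4):
    rows = []
    per = len(values) // 4
    vals = iter(values)
    for k, (year, month) in enumerate(
        [(2013, JUNE), (2013, AUGUST), (2014, JUNE), (2014, AUGUST)]
    ):
        for i in range(per):
            rows.append(
                (f"f{k}_{i}", f"c{i % n_caves}", year, month, float(next(vals)))
            )
    caps, occs = make_captures(rows)
    caves = sorted({r[1] for r in rows})
    return cg.build_panel(caps, full_temps(occs, caves), occs)


class TestForkLengthVariance:
    def test_identical_lengths_give_zero(self):
        panel = _panel_with_august_lengths([92.0] * 160)
        out = fork_length_variance(panel, "summer")
        assert out.total == 0.0

    def test_recovers_a_known_sampling_variance(self):
        rng = np.random.default_rng(1)
        panel = _panel_with_august_lengths(list(rng.normal(92.0, 5.0, 400)))
        out = fork_length_variance(panel, "summer", seed=2)
        # truth 25; 3 SE of a variance on ~200 post-summer obs is ~7.5
        assert out.total == pytest.approx(25.0, abs=7.5)
        assert out.n_obs == 200  # only August occasions follow a summer

    def test_too_few_observations_is_an_error(self):
        panel = _panel_with_august_lengths([92.0] * 40)
        with pytest.raises(cg.DataError, match=">= 30"):
            fork_length_variance(panel, "winter")

    def test_unknown_season_rejected(self):
        panel = _panel_with_august_lengths([92.0] * 160)
        with pytest.raises(KeyError):
            fork_length_variance(panel, "spring")


class TestRepeatability:
    SIGMA_FL = {"summer": 24.0, "winter": 24.0}

    def test_single_nonzero_component_takes_the_whole_share(self):
        draws = fake_growth_draws(jitter=0.0, v_slope=(0.0, 0.0), alpha_temp=(0.0, 0.0))
        for season in ("summer", "winter"):
            draws.scalars[f"alpha_temp[{season}]"][:] = 0.0
            for level in ("cave", "year", "caveyear"):
                draws.scalars[f"V_alpha_{level}[{season}]"][:] = 0.0
                draws.scalars[f"V_slope_{level}[{season}]"][:] = 0.0
            draws.scalars[f"V_alpha_year[{season}]"][:] = 3.0
        rep = repeatability(draws, self.SIGMA_FL)
        for season in ("summer", "winter"):
            pd_ = rep.per_draw[season]
            assert np.allclose(pd_["R_alpha_year"], 1.0)
            for name in ("R_alpha_cave", "R_alpha_caveyear", "R_alpha(b)_year", "R_temp_year"):
                assert np.allclose(pd_[name], 0.0)

    def test_nine_shares_sum_to_one_per_draw(self):
        rep = repeatability(fake_growth_draws(seed=4), self.SIGMA_FL)
        for season in ("summer", "winter"):
            pd_ = rep.per_draw[season]
            total = sum(
                pd_[f"R_{part}_{level}"]
                for part in ("alpha", "alpha(b)", "temp")
                for level in ("cave", "year", "caveyear")
            )
            assert np.allclose(total, 1.0, atol=1e-12)

    def test_ratios_are_computed_per_draw_not_from_summaries(self):
        # heavily skewed draws make mean(a/b) differ from mean(a)/mean(b)
        draws = fake_growth_draws(jitter=0.0, v_slope=(0.0, 0.0))
        rng = np.random.default_rng(5)
        n = draws.n_draws
        skew = np.exp(rng.normal(0.0, 1.5, (1, n)))
        draws.scalars["V_alpha_cave[summer]"] = skew
        draws.scalars["V_alpha_year[summer]"][:] = 1.0
        draws.scalars["V_alpha_caveyear[summer]"][:] = 0.0
        for season in ("summer", "winter"):
            draws.scalars[f"alpha_temp[{season}]"][:] = 0.0
            for level in ("cave", "year", "caveyear"):
                draws.scalars[f"V_slope_{level}[{season}]"][:] = 0.0
        rep = repeatability(draws, self.SIGMA_FL)
        per_draw_mean = np.nanmean(rep.per_draw["summer"]["R_alpha_cave"])
        ratio_of_means = skew.mean() / (skew.mean() + 1.0)
        brute = np.mean(skew / (skew + 1.0))
        assert per_draw_mean == pytest.approx(brute, rel=1e-9)
        assert abs(per_draw_mean - ratio_of_means) > 0.05

    def test_all_zero_variances_flagged_undefined(self):
        draws = fake_growth_draws(jitter=0.0, v_alpha=(0.0, 0.0), v_slope=(0.0, 0.0))
        for season in ("summer", "winter"):
            draws.scalars[f"alpha_temp[{season}]"][:] = 0.0
            for level in ("cave", "year", "caveyear"):
                draws.scalars[f"V_alpha_{level}[{season}]"][:] = 0.0
                draws.scalars[f"V_slope_{level}[{season}]"][:] = 0.0
        rep = repeatability(draws, self.SIGMA_FL)
        n = draws.n_draws
        assert rep.n_undefined == {"summer": n, "winter": n}
        assert np.isnan(rep.per_draw["summer"]["R_alpha_cave"]).all()

    def test_every_derived_variance_is_non_negative(self):
        rep = repeatability(fake_growth_draws(seed=6), self.SIGMA_FL)
        for season, comp in rep.per_draw.items():
            for name, arr in comp.items():
                if name.startswith("V_"):
                    assert (arr >= 0).all(), (season, name)
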