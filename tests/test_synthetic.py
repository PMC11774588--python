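"""Generator contracts: determinism, closed-form reductions, calibrated moments."""

import filecmp

import numpy as np
import pytest

import charrgrowth as cg
from charrgrowth.synthetic import MONTH_DAYS, Seasonal, simulate_temperature_field

ZERO = Seasonal(0.0, 0.0)


def deterministic_config(**overrides):
    base = dict(
        n_caves=2,
        n_occasions=6,
        recruits_per_cave=2,
        temp_var_cave=ZERO,
        temp_var_year=ZERO,
        temp_var_resid=ZERO,
        temp_missing_fraction=0.0,
        slope=ZERO,
        alpha_temp=ZERO,
        slope_temp=ZERO,
        v_alpha_cave=ZERO,
        v_alpha_year=ZERO,
        v_alpha_caveyear=ZERO,
        v_slope_cave=ZERO,
        v_slope_year=ZERO,
        v_slope_caveyear=ZERO,
        v_resid=ZERO,
        sigma0=0.0,
        eta_sq=0.0,
        capture_prob=1.0,
        survival_prob=1.0,
        n_repeat_fish=0,
    )
    base.update(overrides)
    return cg.ScenarioConfig(**base)


class TestTemperatureField:
    def test_zero_variance_gives_exact_season_means(self):
        cfg = deterministic_config()
        records, truth = simulate_temperature_field(cfg, seed=0)
        for r in records:
            assert r.mean_temp_C == pytest.approx(cfg.temp_mean[r.season])

    def test_cell_variance_matches_component_sum(self):
        # big grid so the empirical variance pins down the component sum
        cfg = cg.ScenarioConfig(n_caves=60, n_occasions=41, temp_missing_fraction=0.0)
        _, truth = simulate_temperature_field(cfg, seed=1)
        for sid, season in enumerate(("summer", "winter")):
            cols = truth.values[:, [iv.season == season for iv in truth.intervals]]
            expected = (
                cfg.temp_var_cave[season]
                + cfg.temp_var_year[season]
                + cfg.temp_var_resid[season]
            )
            # 3 SE of a variance estimate, approximated as sqrt(2/n)*var
            tol = 3 * np.sqrt(2 / cols.size) * expected + 0.05 * expected
            assert abs(cols.var() - expected) < tol
            assert abs(cols.mean() - cfg.temp_mean[season]) < 0.2

    def test_missing_count_is_binomial_around_the_configured_fraction(self):
        cfg = cg.ScenarioConfig(n_caves=20, n_occasions=17, temp_missing_fraction=0.22)
        records, truth = simulate_temperature_field(cfg, seed=2)
        n_missing = sum(r.mean_temp_C is None for r in records)
        # 320 cells at 0.22: mean 70.4, SD 7.4
        assert 48 <= n_missing <= 93
        assert n_missing == truth.missing_mask.sum()

    def test_missingness_independent_of_values(self):
        cfg = cg.ScenarioConfig(n_caves=40, n_occasions=31, temp_missing_fraction=0.3)
        _, truth = simulate_temperature_field(cfg, seed=3)
        masked = truth.values[truth.missing_mask]
        unmasked = truth.values[~truth.missing_mask]
        se = np.sqrt(masked.var() / len(masked) + unmasked.var() / len(unmasked))
        assert abs(masked.mean() - unmasked.mean()) < 3 * se


class TestPopulation:
    def test_deterministic_propagation_matches_closed_form(self):
        cfg = deterministic_config()
        caps, occs, temps, _, manifest = cg.simulate_dataset(cfg, seed=4)
        ivs = cg.season_intervals(occs)
        for fish_id, (entry, death, traj) in manifest.trajectories.items():
            months = np.array(
                [iv.n_days / MONTH_DAYS[iv.season] for iv in ivs[entry:death]]
            )
            alpha = np.array([cfg.alpha[iv.season] for iv in ivs[entry:death]])
            expected = cfg.mu0 + np.concatenate([[0.0], np.cumsum(alpha * months)])
            assert np.allclose(traj, expected, atol=1e-9)
        # every fish observed at every alive occasion, exactly at its latent size
        by_fish = {}
        for c in caps:
            by_fish.setdefault(c.fish_id, []).append(c)
        for fish_id, (entry, death, traj) in manifest.trajectories.items():
            obs = sorted(by_fish[fish_id], key=lambda r: r.occasion)
            assert [r.occasion for r in obs] == list(range(entry, death + 1))
            assert np.allclose([r.fork_length_mm for r in obs], traj)

    def test_fixed_seed_reproduces_files_byte_identically(self, tmp_path):
        cfg = cg.preset("paper-small")
        cg.write_dataset(tmp_path / "a", cfg, seed=9)
        cg.write_dataset(tmp_path / "b", cfg, seed=9)
        for name in ("captures.csv", "temperatures.csv", "repeats.csv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_initial_size_moments(self):
        cfg = deterministic_config(sigma0=13.5, n_caves=10, recruits_per_cave=40)
        _, _, _, _, manifest = cg.simulate_dataset(cfg, seed=6)
        z0 = np.array([t[2][0] for t in manifest.trajectories.values()])
        assert abs(z0.mean() - cfg.mu0) < 3 * 13.5 / np.sqrt(len(z0))
        sd_se = 13.5 / np.sqrt(2 * len(z0))
        assert abs(z0.std() - 13.5) < 3 * sd_se

    def test_paper_like_preset_reproduces_study_scale(self):
        cfg = cg.preset("paper-like")
        assert (cfg.n_caves, cfg.n_occasions) == (20, 15)
        assert cfg.eta_sq == pytest.approx(0.6)
        caps, occs, temps, reps, manifest = cg.simulate_dataset(cfg, seed=7)
        lengths = np.array([c.fork_length_mm for c in caps])
        fish = {c.fish_id for c in caps}
        assert 88.0 < lengths.mean() < 96.0  # study condition: grand mean ~92 mm
        assert 6500 <= len(caps) <= 12500  # ~9,200 size observations
        assert 2800 <= len(fish) <= 4800  # ~3,800 known individuals
        assert len(reps) == 76

    def test_null_model_preset_is_fully_degenerate(self):
        cfg = cg.preset("null-model")
        assert cfg.slope == ZERO
        for name in (
            "v_alpha_cave",
            "v_alpha_year",
            "v_alpha_caveyear",
            "v_slope_cave",
            "v_slope_year",
            "v_slope_caveyear",
            "v_resid",
            "temp_var_cave",
            "temp_var_year",
            "temp_var_resid",
        ):
            assert getattr(cfg, name) == ZERO

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            cg.preset("bogus")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cg.ScenarioConfig(capture_prob=0.0)
        with pytest.raises(ValueError):
            cg.ScenarioConfig(v_resid=Seasonal(-1.0, 1.0))
        with pytest.raises(ValueError):
            cg.ScenarioConfig(temp_missing_fraction=1.0)
        with pytest.raises(ValueError):
            cg.ScenarioConfig(recruits_per_cave=0)
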