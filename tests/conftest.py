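"""Shared fixtures: small simulated cave systems and one reusable joint fit."""

import numpy as np
import pytest

import charrgrowth as cg
from charrgrowth.synthetic import Seasonal

ZERO = Seasonal(0.0, 0.0)


def oracle_config() -> cg.ScenarioConfig:
    """Fully observed, noise-free-measurement scenario with intercept-only
    random effects: the state-space fit must reduce to an ordinary
    random-effects regression of per-interval growth increments."""
    return cg.ScenarioConfig(
        n_caves=5,
        n_occasions=8,
        recruits_per_cave=6,
        v_alpha_cave=Seasonal(0.6, 0.08),
        v_alpha_year=Seasonal(1.2, 0.17),
        v_alpha_caveyear=Seasonal(0.4, 0.06),
        v_slope_cave=ZERO,
        v_slope_year=ZERO,
        v_slope_caveyear=ZERO,
        v_resid=Seasonal(2.4, 0.18),
        temp_missing_fraction=0.0,
        eta_sq=0.0,
        capture_prob=1.0,
        survival_prob=0.85,
        n_repeat_fish=0,
    )


@pytest.fixture(scope="session")
def oracle_dataset():
    cfg = oracle_config()
    caps, occs, temps, reps, manifest = cg.simulate_dataset(cfg, seed=20)
    panel = cg.build_panel(caps, temps, occs)
    return panel, manifest


@pytest.fixture(scope="session")
def oracle_fit(oracle_dataset):
    panel, manifest = oracle_dataset
    draws = cg.fit_growth(
        panel,
        eta_sq=0.0,
        mcmc=cg.MCMCConfig(chains=2, draws=500, warmup=500, rhat_threshold=1.2),
        seed=7,
    )
    return panel, manifest, draws


@pytest.fixture(scope="session")
def paper_small_dataset():
    cfg = cg.preset("paper-small")
    caps, occs, temps, reps, manifest = cg.simulate_dataset(cfg, seed=42)
    panel = cg.build_panel(caps, temps, occs)
    return panel, reps, manifest


@pytest.fixture(scope="session")
def masked_fit(oracle_dataset):
    """The oracle panel with 10% of its observations hidden, refitted.

    Interior (non-endpoint) observations are masked so supports are
    unchanged and every masked cell stays predictable.
    """
    panel, manifest = oracle_dataset
    rng = np.random.default_rng(99)
    interior = [
        (panel.fish_ids[f], o)
        for f in range(panel.n_fish)
        for o in range(panel.first[f] + 1, panel.last[f])
        if not np.isnan(panel.obs[f, o])
    ]
    k = max(1, len(interior) // 10)
    picks = [interior[i] for i in rng.choice(len(interior), size=k, replace=False)]
    masked = panel.drop_observations(picks)
    draws = cg.fit_growth(
        masked,
        eta_sq=0.0,
        mcmc=cg.MCMCConfig(chains=2, draws=500, warmup=500, rhat_threshold=1.2),
        seed=8,
    )
    return panel, masked, picks, draws


def fake_growth_draws(
    n=2000,
    seed=0,
    center_size=92.0,
    alpha=(3.4, 0.82),
    slope=(-0.05, -0.02),
    alpha_temp=(0.4, 0.0),
    v_alpha=(0.5, 0.17),
    v_slope=(2.5e-4, 1e-5),
    v_temp_cave=(0.22, 0.21),
    v_temp_year=(0.15, 0.03),
    v_temp_resid=(0.35, 1.03),
    v_resid=(2.35, 0.175),
    jitter=0.1,
):
    """Synthetic posterior draws with the growth fit's parameter layout."""
    rng = np.random.default_rng(seed)

    def draw(mean, scale=None):
        s = jitter * abs(mean) if scale is None else scale
        return np.abs(mean + s * rng.standard_normal((1, n))) * np.sign(mean or 1.0)

    scalars = {}
    for i, season in enumerate(("summer", "winter")):
        scalars[f"alpha[{season}]"] = alpha[i] + 0.2 * rng.standard_normal((1, n))
        scalars[f"slope[{season}]"] = slope[i] + 0.005 * rng.standard_normal((1, n))
        scalars[f"alpha_temp[{season}]"] = alpha_temp[i] + 0.05 * rng.standard_normal((1, n))
        scalars[f"slope_temp[{season}]"] = 0.001 * rng.standard_normal((1, n))
        scalars[f"V_resid[{season}]"] = draw(v_resid[i])
        scalars[f"V_cave_T[{season}]"] = draw(v_temp_cave[i])
        scalars[f"V_year_T[{season}]"] = draw(v_temp_year[i])
        scalars[f"V_resid_T[{season}]"] = draw(v_temp_resid[i])
        scalars[f"T_mean[{season}]"] = draw((6.33, 4.32)[i])
        for level in ("cave", "year", "caveyear"):
            scalars[f"V_alpha_{level}[{season}]"] = draw(v_alpha[i])
            scalars[f"V_slope_{level}[{season}]"] = draw(v_slope[i])
            scalars[f"cov_alpha_slope_{level}[{season}]"] = np.zeros((1, n))
    scalars["mu0"] = draw(76.0)
    scalars["sigma0_sq"] = draw(180.0)
    return cg.PosteriorDraws(
        scalars=scalars,
        coords={"season_labels": ["summer", "winter"]},
        meta={"model": "growth", "eta_sq": 0.6, "center_size": center_size,
              "center_temp": 5.3, "scale": "per-month", "seed": seed},
    )


def tiny_config(**overrides) -> cg.ScenarioConfig:
    """A minimal identifiable system for fast refit-based tests."""
    base = dict(
        n_caves=3,
        n_occasions=6,
        recruits_per_cave=5,
        v_alpha_cave=Seasonal(0.5, 0.1),
        v_alpha_year=Seasonal(1.0, 0.2),
        v_alpha_caveyear=Seasonal(0.3, 0.06),
        v_slope_cave=ZERO,
        v_slope_year=ZERO,
        v_slope_caveyear=ZERO,
        v_resid=Seasonal(2.0, 0.3),
        temp_missing_fraction=0.1,
        eta_sq=0.6,
        capture_prob=0.9,
        survival_prob=0.85,
        n_repeat_fish=0,
    )
    base.update(overrides)
    return cg.ScenarioConfig(**base)
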