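"""Synthetic cave-system datasets with the statistical structure the model assumes.

The generator draws a seasonal temperature field (season means plus cave,
year and residual deviations), then propagates latent fork-length
trajectories through the occasion grid with a linear size-dependent growth
function whose intercepts and slopes carry cave, year and cave-x-year random
deviations and a temperature effect.  Observation is intermittent (Bernoulli
capture), lengths are measured with additive noise, and a subset of fish is
measured twice at one occasion to support measurement-error estimation.

Growth parameters in :class:`ScenarioConfig` are expressed per month (the
reporting scale); the propagation converts to per-day rates using the
season's nominal month length (summer 67/2 = 33.5 d, winter 298/10 = 29.8 d).

A :class:`TruthManifest` records every realised random quantity so that
parameter-recovery tests can compare posteriors against the truth, including
re-expressing the true fixed effects at a fitted panel's centring constants.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import (
    AUGUST,
    JUNE,
    SEASONS,
    SUMMER,
    WINTER,
    CaptureRecord,
    Occasion,
    RepeatMeasureRecord,
    SeasonInterval,
    TemperatureRecord,
    build_occasion_grid,
    season_intervals,
    write_captures,
    write_repeats,
    write_temperatures,
)

#: nominal days in one "month" of each season (67/2 and 298/10)
MONTH_DAYS = {SUMMER: 33.5, WINTER: 29.8}


def month_days(season: str) -> float:
    return MONTH_DAYS[season]


@dataclass(frozen=True)
class Seasonal:
    """A per-season pair of values."""

    summer: float
    winter: float

    def __getitem__(self, season: str) -> float:
        if season == SUMMER:
            return self.summer
        if season == WINTER:
            return self.winter
        raise KeyError(season)

    def as_dict(self) -> dict:
        return {"summer": self.summer, "winter": self.winter}


def _pair(x) -> Seasonal:
    if isinstance(x, Seasonal):
        return x
    if np.isscalar(x):
        return Seasonal(float(x), float(x))
    return Seasonal(*map(float, x))


@dataclass
class ScenarioConfig:
    """Full parameterisation of one simulated cave system.

    Growth fixed effects and variance components are on the per-month growth
    scale (mm/month for intercept-like terms, month^-1 for slopes); the
    temperature block is in deg C.
    """

    n_caves: int = 8
    n_occasions: int = 11
    start_year: int = 2013
    start_month: str = AUGUST

    # temperature process
    temp_mean: Seasonal = field(default_factory=lambda: Seasonal(6.33, 4.32))
    temp_var_cave: Seasonal = field(default_factory=lambda: Seasonal(0.22, 0.21))
    temp_var_year: Seasonal = field(default_factory=lambda: Seasonal(0.15, 0.03))
    temp_var_resid: Seasonal = field(default_factory=lambda: Seasonal(0.35, 1.03))
    temp_missing_fraction: float = 0.22

    # growth fixed effects, per month
    alpha: Seasonal = field(default_factory=lambda: Seasonal(3.4, 0.82))
    slope: Seasonal = field(default_factory=lambda: Seasonal(-0.05, -0.02))
    alpha_temp: Seasonal = field(default_factory=lambda: Seasonal(0.40, -9.85e-4))
    slope_temp: Seasonal = field(default_factory=lambda: Seasonal(4.99e-3, 7.81e-4))

    # growth variance components, per month^2.  The reference decomposition
    # is stated on the seasonal-total growth scale; dividing by the squared
    # season length (2 summer months, 10 winter months) converts it to the
    # per-month scale used throughout this package.
    v_alpha_cave: Seasonal = field(default_factory=lambda: Seasonal(1.986 / 4, 5.032 / 100))
    v_alpha_year: Seasonal = field(default_factory=lambda: Seasonal(4.721 / 4, 16.593 / 100))
    v_alpha_caveyear: Seasonal = field(
        default_factory=lambda: Seasonal(1.233 / 4, 5.901 / 100)
    )
    v_slope_cave: Seasonal = field(default_factory=lambda: Seasonal(0.001 / 4, 0.001 / 100))
    v_slope_year: Seasonal = field(default_factory=lambda: Seasonal(0.001 / 4, 0.001 / 100))
    v_slope_caveyear: Seasonal = field(
        default_factory=lambda: Seasonal(0.001 / 4, 0.002 / 100)
    )
    corr_alpha_slope: Seasonal = field(default_factory=lambda: Seasonal(0.0, 0.0))
    v_resid: Seasonal = field(default_factory=lambda: Seasonal(9.403 / 4, 17.539 / 100))

    # initial sizes and measurement; fish below the tagging threshold never
    # enter the record, so initial sizes are truncated there
    mu0: float = 76.0
    sigma0: float = 13.5
    min_initial_size: float = 45.0
    eta_sq: float = 0.6

    # sampling design
    capture_prob: float = 0.5
    survival_prob: float = 0.8
    recruits_per_cave: int = 4
    n_repeat_fish: int = 76
    n_repeat_measures: int = 2
    date_jitter_days: int = 0

    # centring used by the simulation (the fit may centre differently)
    center_size: float | None = None  # defaults to mu0
    center_temp: float | None = None  # defaults to mean of the two season means

    def __post_init__(self):
        for name in (
            "temp_mean temp_var_cave temp_var_year temp_var_resid alpha slope "
            "alpha_temp slope_temp v_alpha_cave v_alpha_year v_alpha_caveyear "
            "v_slope_cave v_slope_year v_slope_caveyear corr_alpha_slope v_resid"
        ).split():
            setattr(self, name, _pair(getattr(self, name)))
        for name in (
            "temp_var_cave temp_var_year temp_var_resid v_alpha_cave "
            "v_alpha_year v_alpha_caveyear v_slope_cave v_slope_year "
            "v_slope_caveyear v_resid"
        ).split():
            pair = getattr(self, name)
            if pair.summer < 0 or pair.winter < 0:
                raise ValueError(f"{name} must be non-negative")
        for s in SEASONS:
            if not -1.0 <= self.corr_alpha_slope[s] <= 1.0:
                raise ValueError("corr_alpha_slope must lie in [-1, 1]")
        if not 0.0 < self.capture_prob <= 1.0:
            raise ValueError("capture_prob must be in (0, 1]")
        if not 0.0 <= self.temp_missing_fraction < 1.0:
            raise ValueError("temp_missing_fraction must be in [0, 1)")
        if self.sigma0 < 0 or self.eta_sq < 0:
            raise ValueError("sigma0 and eta_sq must be non-negative")
        if self.n_occasions < 2:
            raise ValueError("need at least two occasions")
        if self.recruits_per_cave < 1:
            raise ValueError("recruitment must add at least one fish per occasion")

    @property
    def sim_center_size(self) -> float:
        return self.mu0 if self.center_size is None else self.center_size

    @property
    def sim_center_temp(self) -> float:
        if self.center_temp is None:
            return 0.5 * (self.temp_mean.summer + self.temp_mean.winter)
        return self.center_temp

    def occasions(self) -> list[Occasion]:
        pairs = []
        year, month = self.start_year, self.start_month
        for _ in range(self.n_occasions):
            pairs.append((year, month))
            if month == JUNE:
                month = AUGUST
            else:
                month, year = JUNE, year + 1
        return build_occasion_grid(pairs)


def preset(name: str) -> ScenarioConfig:
    """Named scenario: ``paper-like``, ``paper-small`` or ``null-model``."""
    if name == "paper-like":
        return ScenarioConfig(
            n_caves=20,
            n_occasions=15,
            start_year=2012,
            recruits_per_cave=16,
        )
    if name == "paper-small":
        return ScenarioConfig()
    if name == "null-model":
        zero = Seasonal(0.0, 0.0)
        return ScenarioConfig(
            temp_var_cave=zero,
            temp_var_year=zero,
            temp_var_resid=zero,
            temp_missing_fraction=0.0,
            slope=zero,
            alpha_temp=zero,
            slope_temp=zero,
            v_alpha_cave=zero,
            v_alpha_year=zero,
            v_alpha_caveyear=zero,
            v_slope_cave=zero,
            v_slope_year=zero,
            v_slope_caveyear=zero,
            v_resid=zero,
            sigma0=0.0,
            eta_sq=0.0,
            capture_prob=1.0,
        )
    raise ValueError(f"unknown preset {name!r}; choose paper-like, paper-small, null-model")


@dataclass
class TemperatureTruth:
    """Realised temperature field over the cave x interval grid."""

    values: np.ndarray  # (C, K) true seasonal means
    missing_mask: np.ndarray  # (C, K) True where the emitted record is missing
    cave_dev: dict  # season -> (C,)
    year_dev: dict  # season -> (Y,)
    years: list[int]
    intervals: list[SeasonInterval]


@dataclass
class TruthManifest:
    """Everything the generator realised, for recovery testing."""

    config: ScenarioConfig
    temperature: TemperatureTruth
    #: season -> level -> array of realised (intercept, slope) deviations, per month
    growth_effects: dict
    #: fish_id -> (entry_occasion, death_occasion, latent sizes over alive span)
    trajectories: dict
    n_resampled_residuals: int = 0

    def fixed_effects_at(self, center_size: float, center_temp: float) -> dict:
        """True per-month fixed effects re-expressed at the given centring."""
        dz = center_size - self.config.sim_center_size
        dT = center_temp - self.config.sim_center_temp
        out = {}
        for s in SEASONS:
            a, b = self.config.alpha[s], self.config.slope[s]
            aT, bT = self.config.alpha_temp[s], self.config.slope_temp[s]
            out[s] = {
                "alpha": a + b * dz + aT * dT + bT * dz * dT,
                "slope": b + bT * dT,
                "alpha_temp": aT + bT * dz,
                "slope_temp": bT,
            }
        return out

    def variance_components_at(self, center_size: float) -> dict:
        """True per-month variance components at the given size centring.

        Shifting the centring turns slope variance into intercept variance:
        V_alpha' = V_alpha + 2 d Cov + d^2 V_b with d the centring shift.
        """
        d = center_size - self.config.sim_center_size
        out = {}
        for s in SEASONS:
            comp = {}
            for level, va, vb in (
                ("cave", self.config.v_alpha_cave[s], self.config.v_slope_cave[s]),
                ("year", self.config.v_alpha_year[s], self.config.v_slope_year[s]),
                (
                    "caveyear",
                    self.config.v_alpha_caveyear[s],
                    self.config.v_slope_caveyear[s],
                ),
            ):
                cov = self.config.corr_alpha_slope[s] * np.sqrt(va * vb)
                comp[level] = {
                    "v_alpha": va + 2 * d * cov + d * d * vb,
                    "v_slope": vb,
                    "cov": cov + d * vb,
                }
            comp["v_resid"] = self.config.v_resid[s]
            out[s] = comp
        return out


def simulate_temperature_field(
    config: ScenarioConfig, seed: int | np.random.SeedSequence
) -> tuple[list[TemperatureRecord], TemperatureTruth]:
    """Draw the seasonal temperature field and apply the missingness mask.

    Each cave x interval cell gets T = a_h + a_hj + a_ht + eps with
    season-specific cave deviations, year deviations and residuals; the
    missing mask is uniform at random at ``temp_missing_fraction``,
    independent of the values (missing at random by construction).
    """
    rng = np.random.default_rng(seed)
    occasions = config.occasions()
    intervals = season_intervals(occasions)
    years = sorted({iv.year for iv in intervals})
    year_idx = {y: i for i, y in enumerate(years)}
    C, K, Y = config.n_caves, len(intervals), len(years)

    cave_dev = {s: rng.normal(0.0, np.sqrt(config.temp_var_cave[s]), C) for s in SEASONS}
    year_dev = {s: rng.normal(0.0, np.sqrt(config.temp_var_year[s]), Y) for s in SEASONS}

    values = np.empty((C, K))
    for k, iv in enumerate(intervals):
        s = iv.season
        eps = rng.normal(0.0, np.sqrt(config.temp_var_resid[s]), C)
        values[:, k] = (
            config.temp_mean[s] + cave_dev[s] + year_dev[s][year_idx[iv.year]] + eps
        )
    missing = rng.random((C, K)) < config.temp_missing_fraction

    records = [
        TemperatureRecord(
            cave_id=f"cave{c:02d}",
            year=iv.year,
            season=iv.season,
            mean_temp_C=None if missing[c, k] else float(values[c, k]),
        )
        for c in range(C)
        for k, iv in enumerate(intervals)
    ]
    truth = TemperatureTruth(
        values=values,
        missing_mask=missing,
        cave_dev=cave_dev,
        year_dev=year_dev,
        years=years,
        intervals=intervals,
    )
    return records, truth


def _draw_pairs(
    rng: np.random.Generator, n: int, va: float, vb: float, corr: float
) -> np.ndarray:
    """n draws of correlated (intercept, slope) deviations."""
    cov = corr * np.sqrt(va * vb)
    sigma = np.array([[va, cov], [cov, vb]])
    # guard the degenerate all-zero case
    if va == 0 and vb == 0:
        return np.zeros((n, 2))
    jitter = 1e-12 * max(va, vb)
    chol = np.linalg.cholesky(sigma + jitter * np.eye(2))
    return rng.standard_normal((n, 2)) @ chol.T


def simulate_population(
    config: ScenarioConfig,
    temperature_truth: TemperatureTruth,
    seed: int | np.random.SeedSequence,
) -> tuple[list[CaptureRecord], list[RepeatMeasureRecord], TruthManifest]:
    """Propagate latent trajectories and emit intermittent noisy captures.

    Fish recruit at every occasion (``recruits_per_cave`` per cave), start at
    Normal(mu0, sigma0^2), survive each interval with ``survival_prob`` and,
    while alive, are captured with ``capture_prob``.  Observed lengths add
    Normal(0, eta_sq) measurement noise.  A propagated size that would fall
    to zero or below has its growth residual resampled (counted in the
    manifest).
    """
    rng = np.random.default_rng(seed)
    occasions = config.occasions()
    intervals = temperature_truth.intervals
    years = temperature_truth.years
    year_idx = {y: i for i, y in enumerate(years)}
    C, T, Y = config.n_caves, len(occasions), len(years)
    cz, cT = config.sim_center_size, config.sim_center_temp

    effects = {}
    for s in SEASONS:
        effects[s] = {
            "cave": _draw_pairs(
                rng, C, config.v_alpha_cave[s], config.v_slope_cave[s],
                config.corr_alpha_slope[s],
            ),
            "year": _draw_pairs(
                rng, Y, config.v_alpha_year[s], config.v_slope_year[s],
                config.corr_alpha_slope[s],
            ),
            "caveyear": _draw_pairs(
                rng, C * Y, config.v_alpha_caveyear[s], config.v_slope_caveyear[s],
                config.corr_alpha_slope[s],
            ).reshape(C, Y, 2),
        }

    captures: list[CaptureRecord] = []
    trajectories: dict = {}
    capture_cells: list[tuple[str, int, float]] = []  # fish, occasion, latent size
    n_resampled = 0

    for cave in range(C):
        cave_id = f"cave{cave:02d}"
        for entry in range(T):
            n_new = config.recruits_per_cave
            z0 = rng.normal(config.mu0, config.sigma0, n_new)
            if config.sigma0 > 0:
                for _ in range(100):  # truncate at the tagging threshold
                    low = z0 < config.min_initial_size
                    if not low.any():
                        break
                    z0[low] = rng.normal(config.mu0, config.sigma0, int(low.sum()))
            if config.survival_prob >= 1.0:
                alive_spans = np.full(n_new, T, dtype=int)  # clipped to grid below
            else:
                alive_spans = rng.geometric(1.0 - config.survival_prob, n_new) - 1
            for i in range(n_new):
                fish_id = f"f{cave:02d}_{entry:02d}_{i:03d}"
                death = min(entry + int(alive_spans[i]), T - 1)
                z = [float(z0[i])]
                for k in range(entry, death):
                    iv = intervals[k]
                    s = iv.season
                    md = MONTH_DAYS[s]
                    y = year_idx[iv.year]
                    dev = (
                        effects[s]["cave"][cave]
                        + effects[s]["year"][y]
                        + effects[s]["caveyear"][cave, y]
                    )
                    Tc = temperature_truth.values[cave, k] - cT
                    a_m = config.alpha[s] + dev[0] + config.alpha_temp[s] * Tc
                    b_m = config.slope[s] + dev[1] + config.slope_temp[s] * Tc
                    # convert monthly rate to daily and integrate over the interval
                    mean_day = (a_m + b_m * (z[-1] - cz)) / md
                    sd_day = np.sqrt(config.v_resid[s]) / md
                    D = iv.n_days
                    for _attempt in range(100):
                        z_next = z[-1] + (mean_day + sd_day * rng.standard_normal()) * D
                        if z_next > 0:
                            break
                        n_resampled += 1
                    else:
                        z_next = 1.0  # pathological configuration; keep going
                    z.append(float(z_next))
                traj = np.array(z)
                trajectories[fish_id] = (entry, death, traj)
                for occ in range(entry, death + 1):
                    if rng.random() < config.capture_prob:
                        obs = traj[occ - entry] + rng.normal(0.0, np.sqrt(config.eta_sq))
                        date = occasions[occ].nominal_date
                        if config.date_jitter_days:
                            date = date + _dt.timedelta(
                                days=int(
                                    rng.integers(
                                        -config.date_jitter_days,
                                        config.date_jitter_days + 1,
                                    )
                                )
                            )
                        captures.append(
                            CaptureRecord(
                                fish_id=fish_id,
                                cave_id=cave_id,
                                occasion=occ,
                                fork_length_mm=float(obs),
                                capture_date=date,
                            )
                        )
                        capture_cells.append((fish_id, occ, float(traj[occ - entry])))

    # duplicate measurements on a random subset of captured fish (one occasion each)
    repeats: list[RepeatMeasureRecord] = []
    if config.n_repeat_fish > 0 and capture_cells:
        by_fish: dict[str, tuple[int, float]] = {}
        for fish_id, occ, z in capture_cells:
            by_fish[fish_id] = (occ, z)  # keep the last capture
        chosen = rng.choice(
            sorted(by_fish), size=min(config.n_repeat_fish, len(by_fish)), replace=False
        )
        for fish_id in chosen:
            _, z = by_fish[fish_id]
            meas = z + rng.normal(0.0, np.sqrt(config.eta_sq), config.n_repeat_measures)
            repeats.append(
                RepeatMeasureRecord(fish_id=fish_id, measurements=tuple(map(float, meas)))
            )

    manifest = TruthManifest(
        config=config,
        temperature=temperature_truth,
        growth_effects=effects,
        trajectories=trajectories,
        n_resampled_residuals=n_resampled,
    )
    return captures, repeats, manifest


def simulate_dataset(config: ScenarioConfig, seed: int):
    """Temperature field + population in one call with independent substreams.

    Returns (captures, occasions, temperature_records, repeats, manifest).
    """
    ss = np.random.SeedSequence(seed)
    temp_seed, pop_seed = ss.spawn(2)
    temp_records, temp_truth = simulate_temperature_field(config, temp_seed)
    captures, repeats, manifest = simulate_population(config, temp_truth, pop_seed)
    return captures, config.occasions(), temp_records, repeats, manifest


def write_dataset(out_dir: str | Path, config: ScenarioConfig, seed: int) -> dict:
    """Simulate and write captures.csv, temperatures.csv, repeats.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    captures, occasions, temps, repeats, manifest = simulate_dataset(config, seed)
    write_captures(out / "captures.csv", captures, occasions)
    write_temperatures(out / "temperatures.csv", temps)
    write_repeats(out / "repeats.csv", repeats)
    truth = {
        "seed": seed,
        "config": _config_to_jsonable(config),
        "n_fish_simulated": len(manifest.trajectories),
        "n_captures": len(captures),
        "n_resampled_residuals": manifest.n_resampled_residuals,
        "temperature_values": manifest.temperature.values.tolist(),
        "temperature_missing_mask": manifest.temperature.missing_mask.tolist(),
        "growth_effects": {
            s: {lvl: np.asarray(arr).tolist() for lvl, arr in level.items()}
            for s, level in manifest.growth_effects.items()
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth


def _config_to_jsonable(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    return {k: (v if not isinstance(v, dict) else v) for k, v in d.items()}
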