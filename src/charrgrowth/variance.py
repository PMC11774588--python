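"""Derived variance components: temperature shares, slope-variance conversion
and proportional (R) decomposition.

Three transformations turn raw posterior draws into comparable quantities,
each applied draw-by-draw (never to posterior summaries, because the mean of
a ratio is not the ratio of means):

* temperature-associated variance: V(a + b x) = b^2 V(x), so the share of a
  growth variance component attributable to the temperature covariate is the
  matching temperature variance times the squared temperature effect;
* slope-variance conversion: slope (size-dependent) variance is in units of
  (growth per mm)^2 and is re-expressed as growth variance by multiplying
  with the variance of fork lengths after the season's growth (sigma_fl^2);
* repeatability: each spatial/temporal/spatiotemporal component's share of
  V_g = V_j + V_t + V_jt, where each of V_j, V_t, V_jt is the sum of its
  size-independent, converted size-dependent and temperature-associated
  parts.  The residual V_e is reported alongside and an alternative share
  with V_e in the denominator is labelled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._samplers import HalfTVariance
from .config import Priors
from .data_io import DataError, GrowthPanel, SEASONS
from .draws import PosteriorDraws

#: growth level -> temperature-model variance component that varies the same way
TEMP_COMPONENT = {"cave": "V_cave_T", "year": "V_year_T", "caveyear": "V_resid_T"}
LEVELS = ("cave", "year", "caveyear")


def temperature_associated_variance(
    draws: PosteriorDraws, level: str, season: str
) -> np.ndarray:
    """Per-draw V(effect * temperature) for one level and season, mm^2/month^2."""
    if level not in TEMP_COMPONENT:
        raise KeyError(f"unknown level {level!r}")
    temp_name = f"{TEMP_COMPONENT[level]}[{season}]"
    effect_name = f"alpha_temp[{season}]"
    if temp_name not in draws.scalars or effect_name not in draws.scalars:
        raise DataError(
            f"{temp_name} / {effect_name} absent from the draws: the fit was run "
            f"without the temperature model (ablation) or without this season"
        )
    return draws.stacked(temp_name) * draws.stacked(effect_name) ** 2


def convert_slope_variance(v_slope_draws: np.ndarray, sigma_fl_sq: float) -> np.ndarray:
    """Slope variance -> growth variance: elementwise V_b * sigma_fl^2."""
    if sigma_fl_sq < 0:
        raise ValueError("sigma_fl_sq must be non-negative")
    return np.asarray(v_slope_draws) * sigma_fl_sq


@dataclass
class ForkLengthVariance:
    """Total variance of fork lengths measured after one season's growth."""

    season: str
    total: float
    interval: tuple[float, float]
    components: dict  # posterior means of cave / year / residual parts
    n_obs: int


def fork_length_variance(
    panel: GrowthPanel,
    season: str,
    n_iter: int = 2000,
    warmup: int = 500,
    seed: int = 0,
    priors: Priors | None = None,
) -> ForkLengthVariance:
    """sigma_fl^2: variance of post-season observed lengths.

    Fits an intercept-only variance-components model with cave and year
    grouping factors by Gibbs sampling.  The reported total is the realized
    decomposition per draw: the observation-weighted variance of the fitted
    cave and year deviations plus the residual variance.  With few grouping
    levels the realized variance of the shrunk deviations is far better
    behaved than the population variance parameter, whose posterior is
    prior-dominated, while both agree when group structure is real.
    """
    if season not in SEASONS:
        raise KeyError(f"unknown season {season!r}")
    priors = priors or Priors()
    # occasions that follow an interval of the requested season
    occs = [iv.to_occasion for iv in panel.intervals if iv.season == season]
    vals, caves, years = [], [], []
    year_of_occ = {iv.to_occasion: iv.year for iv in panel.intervals}
    for o in occs:
        seen = np.where(~np.isnan(panel.obs[:, o]))[0]
        vals.extend(panel.obs[seen, o])
        caves.extend(panel.fish_cave[seen])
        years.extend([year_of_occ[o]] * len(seen))
    x = np.asarray(vals, dtype=float)
    if len(x) < 30:
        raise DataError(
            f"only {len(x)} post-{season} observations; need >= 30 for sigma_fl^2"
        )
    if np.ptp(x) == 0.0:
        return ForkLengthVariance(season, 0.0, (0.0, 0.0), {}, len(x))

    cave_ids, cave_ix = np.unique(caves, return_inverse=True)
    year_ids, year_ix = np.unique(years, return_inverse=True)
    nC, nY, n = len(cave_ids), len(year_ids), len(x)
    rng = np.random.default_rng(seed)
    mu = float(x.mean())
    uc = np.zeros(nC)
    uy = np.zeros(nY)
    # data-scaled weakly informative priors on the SDs
    sd_scale = float(x.std())
    v_cave = HalfTVariance(priors.sd_df, sd_scale, init=1.0)
    v_year = HalfTVariance(priors.sd_df, sd_scale, init=1.0)
    v_res = HalfTVariance(priors.sd_df, sd_scale, init=float(np.var(x)))
    nc = np.bincount(cave_ix, minlength=nC).astype(float)
    ny = np.bincount(year_ix, minlength=nY).astype(float)
    totals = np.empty(n_iter)
    comps = np.empty((n_iter, 3))
    for it in range(warmup + n_iter):
        r = x - mu - uy[year_ix]
        prec = nc / v_res.value + 1.0 / v_cave.value
        uc = np.bincount(cave_ix, weights=r, minlength=nC) / v_res.value / prec
        uc += rng.standard_normal(nC) / np.sqrt(prec)
        r = x - mu - uc[cave_ix]
        prec = ny / v_res.value + 1.0 / v_year.value
        uy = np.bincount(year_ix, weights=r, minlength=nY) / v_res.value / prec
        uy += rng.standard_normal(nY) / np.sqrt(prec)
        r = x - uc[cave_ix] - uy[year_ix]
        prec_mu = n / v_res.value + 1e-6
        mu = r.sum() / v_res.value / prec_mu + rng.standard_normal() / np.sqrt(prec_mu)
        resid = r - mu
        v_res.update(float(resid @ resid), n, rng)
        v_cave.update(float(uc @ uc), nC, rng)
        v_year.update(float(uy @ uy), nY, rng)
        if it >= warmup:
            comps[it - warmup] = (
                float(np.var(uc[cave_ix])),
                float(np.var(uy[year_ix])),
                v_res.value,
            )
            totals[it - warmup] = comps[it - warmup].sum()
    return ForkLengthVariance(
        season=season,
        total=float(totals.mean()),
        interval=(float(np.quantile(totals, 0.025)), float(np.quantile(totals, 0.975))),
        components={
            "cave": float(comps[:, 0].mean()),
            "year": float(comps[:, 1].mean()),
            "residual": float(comps[:, 2].mean()),
        },
        n_obs=len(x),
    )


@dataclass
class VarianceReport:
    """Per-season decomposition with posterior summaries and per-draw arrays."""

    table: pd.DataFrame
    per_draw: dict  # season -> {name: draws}
    n_undefined: dict  # season -> draws where V_g == 0 (excluded from R summaries)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def repeatability(
    draws: PosteriorDraws,
    sigma_fl_sq: dict[str, float],
    include_residual_share: bool = True,
) -> VarianceReport:
    """Full per-draw decomposition and proportional contributions R.

    ``sigma_fl_sq`` maps season -> post-season fork-length variance (from
    :func:`fork_length_variance`).  Per draw and season, the level totals are

        V_level = V_alpha_level + V_slope_level * sigma_fl^2 + V_level_T

    and V_g is their sum; every R is the component divided by V_g for that
    draw.  Draws with V_g = 0 are excluded from the R summaries (counted in
    ``n_undefined``).
    """
    seasons = [s for s in draws.coords["season_labels"] if s in SEASONS] or list(
        draws.coords["season_labels"]
    )
    has_temp = any(k.startswith("alpha_temp") for k in draws.scalars)
    rows = []
    per_draw: dict = {}
    n_undef: dict = {}
    for season in seasons:
        sfl = sigma_fl_sq[season] if season in sigma_fl_sq else sigma_fl_sq.get("all")
        if sfl is None:
            raise KeyError(f"sigma_fl_sq missing entry for season {season!r}")
        comp: dict[str, np.ndarray] = {}
        for level in LEVELS:
            va = draws.stacked(f"V_alpha_{level}[{season}]")
            vb = draws.stacked(f"V_slope_{level}[{season}]")
            comp[f"V_alpha_{level}"] = va
            comp[f"V_slope_{level}"] = vb
            comp[f"V_alpha(b)_{level}"] = convert_slope_variance(vb, sfl)
            comp[f"V_temp_{level}"] = (
                temperature_associated_variance(draws, level, season)
                if has_temp
                else np.zeros_like(va)
            )
        level_totals = {
            level: comp[f"V_alpha_{level}"]
            + comp[f"V_alpha(b)_{level}"]
            + comp[f"V_temp_{level}"]
            for level in LEVELS
        }
        v_g = sum(level_totals.values())
        v_e = draws.stacked(f"V_resid[{season}]")
        ok = v_g > 0
        n_undef[season] = int((~ok).sum())
        for level in LEVELS:
            for part in ("alpha", "alpha(b)", "temp"):
                name = f"R_{part}_{level}"
                comp[name] = np.where(ok, comp[f"V_{part}_{level}"] / np.where(ok, v_g, 1.0), np.nan)
        comp["V_g"] = v_g
        comp["V_e"] = v_e
        if include_residual_share:
            tot = v_g + v_e
            ok2 = tot > 0
            for level in LEVELS:
                comp[f"R_total_{level}_incl_resid"] = np.where(
                    ok2, level_totals[level] / np.where(ok2, tot, 1.0), np.nan
                )
        per_draw[season] = comp
        for name, arr in comp.items():
            finite = arr[np.isfinite(arr)]
            rows.append(
                {
                    "season": season,
                    "quantity": name,
                    "mean": float(finite.mean()) if len(finite) else float("nan"),
                    "q2.5": float(np.quantile(finite, 0.025)) if len(finite) else float("nan"),
                    "q97.5": float(np.quantile(finite, 0.975)) if len(finite) else float("nan"),
                    "n_draws": int(len(finite)),
                }
            )
    return VarianceReport(table=pd.DataFrame(rows), per_draw=per_draw, n_undefined=n_undef)
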