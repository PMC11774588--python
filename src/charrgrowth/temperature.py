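"""Hierarchical seasonal water-temperature model with missing-cell augmentation.

Process model per cave j, year t and season h:

    T_hjt = a_h + a_hj + a_ht + eps,   eps ~ N(0, V_eps_h)

with season-specific cave deviations a_hj ~ N(0, V_cave_h) and year
deviations a_ht ~ N(0, V_year_h).  The observation model adds a fixed,
essentially-zero error variance so that observed and missing cells can be
treated uniformly: missing cells become latent parameters sampled jointly
with everything else (data augmentation), which is what lets the growth
model integrate over missing covariate values.

The module is used standalone (:func:`fit_temperature`) and embedded in the
joint growth fit, which adds the growth likelihood's contribution to the
latent-cell update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._samplers import HalfTVariance, collapsed_scalar_loglik
from .config import MCMCConfig, Priors
from .data_io import DataError, SEASONS, TemperatureRecord
from .draws import PosteriorDraws, convergence_diagnostics


@dataclass
class TemperatureGrid:
    """Cave x cell layout of the temperature data.

    Cells are (year, season) pairs in chronological order; ``values`` holds
    observed seasonal means with NaN for missing cells.
    """

    caves: list[str]
    cell_year: np.ndarray  # (K,) year per cell
    cell_season: np.ndarray  # (K,) season id per cell (0 summer, 1 winter)
    years: list[int]
    cell_year_idx: np.ndarray  # (K,) index into years
    values: np.ndarray  # (C, K), NaN = missing

    @property
    def n_caves(self) -> int:
        return len(self.caves)

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


SEASON_ID = {s: i for i, s in enumerate(SEASONS)}


def grid_from_records(records: Sequence[TemperatureRecord]) -> TemperatureGrid:
    caves = sorted({r.cave_id for r in records})
    cells = sorted({(r.year, r.season) for r in records}, key=lambda p: (p[0], SEASON_ID[p[1]]))
    years = sorted({y for y, _ in cells})
    cave_idx = {c: i for i, c in enumerate(caves)}
    cell_idx = {cell: k for k, cell in enumerate(cells)}
    values = np.full((len(caves), len(cells)), np.nan)
    for r in records:
        if r.mean_temp_C is not None:
            values[cave_idx[r.cave_id], cell_idx[(r.year, r.season)]] = r.mean_temp_C
    return TemperatureGrid(
        caves=caves,
        cell_year=np.array([y for y, _ in cells]),
        cell_season=np.array([SEASON_ID[s] for _, s in cells]),
        years=years,
        cell_year_idx=np.array([years.index(y) for y, _ in cells]),
        values=values,
    )


def grid_from_panel(panel) -> TemperatureGrid:
    """Grid aligned with a :class:`~charrgrowth.data_io.GrowthPanel`'s intervals."""
    intervals = panel.intervals
    years = sorted({iv.year for iv in intervals})
    return TemperatureGrid(
        caves=list(panel.cave_ids),
        cell_year=np.array([iv.year for iv in intervals]),
        cell_season=np.array([SEASON_ID[iv.season] for iv in intervals]),
        years=years,
        cell_year_idx=np.array([years.index(iv.year) for iv in intervals]),
        values=panel.temp.copy(),
    )


class TemperatureGibbs:
    """Gibbs state and updates for the seasonal temperature model."""

    def __init__(self, grid: TemperatureGrid, priors: Priors, rng: np.random.Generator):
        self.grid = grid
        self.priors = priors
        C, K, Y = grid.n_caves, grid.n_cells, len(grid.years)
        self.obs_mask = ~np.isnan(grid.values)
        for sid, season in enumerate(SEASONS):
            cols = grid.cell_season == sid
            if cols.any() and not self.obs_mask[:, cols].any():
                raise DataError(f"season {season!r} has no observed temperature cells")
        season_means = np.array(
            [
                np.nanmean(grid.values[:, grid.cell_season == sid])
                if (grid.cell_season == sid).any()
                else 5.0
                for sid in range(2)
            ]
        )
        # state
        self.a = season_means + 0.1 * rng.standard_normal(2)
        self.a_cave = np.zeros((2, C))
        self.a_year = np.zeros((2, Y))
        self.v_cave = [
            HalfTVariance(priors.sd_df, priors.sd_scale, init=0.2 * rng.uniform(0.5, 2))
            for _ in range(2)
        ]
        self.v_year = [
            HalfTVariance(priors.sd_df, priors.sd_scale, init=0.1 * rng.uniform(0.5, 2))
            for _ in range(2)
        ]
        self.v_resid = [
            HalfTVariance(priors.sd_df, priors.sd_scale, init=0.5 * rng.uniform(0.5, 2))
            for _ in range(2)
        ]
        self.cells = np.where(
            self.obs_mask, grid.values, season_means[grid.cell_season][None, :]
        )
        # identifiability bookkeeping
        self.degenerate = C < 2 or Y < 2

    def process_mean(self) -> np.ndarray:
        g = self.grid
        return (
            self.a[g.cell_season][None, :]
            + self.a_cave[g.cell_season, :].T
            + self.a_year[g.cell_season, g.cell_year_idx][None, :]
        )

    def resid_var_cells(self) -> np.ndarray:
        return np.array([self.v_resid[s].value for s in range(2)])[self.grid.cell_season]

    def update_latent(
        self,
        rng: np.random.Generator,
        extra_prec: np.ndarray | None = None,
        extra_mean_num: np.ndarray | None = None,
    ) -> None:
        """Sample the latent cell temperatures.

        ``extra_prec``/``extra_mean_num`` are (C, K) precision and
        precision-weighted-mean contributions from an embedding model (the
        growth likelihood).
        """
        g = self.grid
        proc_mean = self.process_mean()
        vr = self.resid_var_cells()[None, :]
        prec = 1.0 / vr + self.obs_mask / self.priors.temp_obs_var
        num = proc_mean / vr + np.where(self.obs_mask, g.values, 0.0) / self.priors.temp_obs_var
        if extra_prec is not None:
            prec = prec + extra_prec
            num = num + extra_mean_num
        self.cells = num / prec + rng.standard_normal(prec.shape) / np.sqrt(prec)

    def update_params(self, rng: np.random.Generator) -> None:
        g = self.grid
        C = g.n_caves
        for sid in range(2):
            cols = np.where(g.cell_season == sid)[0]
            if len(cols) == 0:
                continue
            vr = self.v_resid[sid].value
            sub = self.cells[:, cols]  # (C, ncols)
            yearix = g.cell_year_idx[cols]
            # season mean
            r = sub - self.a_cave[sid][:, None] - self.a_year[sid, yearix][None, :]
            n = r.size
            prec = n / vr + 1.0 / self.priors.fixed_effect_sd**2
            self.a[sid] = r.sum() / vr / prec + rng.standard_normal() / math.sqrt(prec)
            # cave deviations: collapsed Metropolis on the variance first
            # (deviations integrated out), then the exact conditional draw
            r = sub - self.a[sid] - self.a_year[sid, yearix][None, :]
            s_n = np.full(C, float(len(cols)))
            s_r = r.sum(axis=1)
            self.v_cave[sid].mh_update(
                lambda v: collapsed_scalar_loglik(v, s_n, s_r, vr), rng
            )
            prec_c = len(cols) / vr + 1.0 / max(self.v_cave[sid].value, 1e-12)
            mean_c = s_r / vr / prec_c
            self.a_cave[sid] = mean_c + rng.standard_normal(C) / np.sqrt(prec_c)
            # year deviations (each year appears once per season)
            r = sub - self.a[sid] - self.a_cave[sid][:, None]
            sums = np.zeros(len(g.years))
            counts = np.zeros(len(g.years))
            np.add.at(sums, yearix, r.sum(axis=0))
            np.add.at(counts, yearix, C)
            present = counts > 0
            self.v_year[sid].mh_update(
                lambda v: collapsed_scalar_loglik(
                    v, counts[present], sums[present], vr
                ),
                rng,
            )
            prec_y = counts / vr + 1.0 / max(self.v_year[sid].value, 1e-12)
            mean_y = np.where(present, sums / vr / prec_y, 0.0)
            draw = mean_y + rng.standard_normal(len(g.years)) / np.sqrt(prec_y)
            self.a_year[sid] = np.where(present, draw, self.a_year[sid])
            # translation moves: shift mass between the season mean and each
            # deviation set (likelihood-invariant; exact Gaussian conditional).
            # Breaks the mean/deviation confounding of the centered scheme.
            f_prec = 1.0 / self.priors.fixed_effect_sd**2
            p = f_prec + C / max(self.v_cave[sid].value, 1e-12)
            m = (
                -self.a[sid] * f_prec
                + self.a_cave[sid].sum() / max(self.v_cave[sid].value, 1e-12)
            ) / p
            delta = m + rng.standard_normal() / math.sqrt(p)
            self.a[sid] += delta
            self.a_cave[sid] -= delta
            n_present = int(present.sum())
            if n_present:
                vy = max(self.v_year[sid].value, 1e-12)
                p = f_prec + n_present / vy
                m = (-self.a[sid] * f_prec + self.a_year[sid][present].sum() / vy) / p
                delta = m + rng.standard_normal() / math.sqrt(p)
                self.a[sid] += delta
                self.a_year[sid][present] -= delta
            # conjugate refresh on top of the collapsed Metropolis moves
            self.v_cave[sid].update(float(self.a_cave[sid] @ self.a_cave[sid]), C, rng)
            yvals = self.a_year[sid][present]
            self.v_year[sid].update(float(yvals @ yvals), int(present.sum()), rng)
            eps = sub - self.a[sid] - self.a_cave[sid][:, None] - self.a_year[sid, yearix][None, :]
            self.v_resid[sid].update(float((eps**2).sum()), eps.size, rng)

    def record(self) -> dict:
        out = {}
        for sid, season in enumerate(SEASONS):
            out[f"T_mean[{season}]"] = self.a[sid]
            out[f"V_cave_T[{season}]"] = self.v_cave[sid].value
            out[f"V_year_T[{season}]"] = self.v_year[sid].value
            out[f"V_resid_T[{season}]"] = self.v_resid[sid].value
        return out


def fit_temperature(
    records: Sequence[TemperatureRecord],
    priors: Priors | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit the seasonal temperature model and augment missing cells.

    Returns draws for the season means, the three variance components per
    season and the full latent cell field (including every augmented cell),
    with convergence diagnostics attached.
    """
    priors = priors or Priors()
    mcmc = mcmc or MCMCConfig()
    grid = grid_from_records(records)
    missing_fraction = float(np.isnan(grid.values).mean())
    warnings_list = []
    if missing_fraction > mcmc.missing_warn_fraction:
        warnings_list.append(
            f"{missing_fraction:.0%} of temperature cells are missing; covariate "
            f"augmentation becomes unreliable well below full coverage"
        )

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(mcmc.chains)
    scalar_names = None
    scalars_by_chain = []
    cells_by_chain = []
    degenerate = False
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        gibbs = TemperatureGibbs(grid, priors, rng)
        degenerate = gibbs.degenerate
        rec_scalars = {}
        rec_cells = np.empty((mcmc.draws, grid.n_caves, grid.n_cells))
        for it in range(mcmc.warmup + mcmc.draws):
            gibbs.update_latent(rng)
            gibbs.update_params(rng)
            if it >= mcmc.warmup:
                d = it - mcmc.warmup
                for k, v in gibbs.record().items():
                    rec_scalars.setdefault(k, np.empty(mcmc.draws))[d] = v
                rec_cells[d] = gibbs.cells
        scalar_names = list(rec_scalars)
        scalars_by_chain.append(rec_scalars)
        cells_by_chain.append(rec_cells)

    scalars = {
        k: np.stack([c[k] for c in scalars_by_chain]) for k in scalar_names
    }
    arrays = {"T_cell": np.stack(cells_by_chain)}
    draws = PosteriorDraws(
        scalars=scalars,
        arrays=arrays,
        coords={
            "caves": grid.caves,
            "cells": [
                {"year": int(y), "season": SEASONS[s]}
                for y, s in zip(grid.cell_year, grid.cell_season)
            ],
            "missing_cells": np.argwhere(np.isnan(grid.values)).tolist(),
        },
        meta={
            "model": "temperature",
            "seed": seed,
            "chains": mcmc.chains,
            "warmup": mcmc.warmup,
            "draws_per_chain": mcmc.draws,
            "missing_fraction": missing_fraction,
            "degenerate_design": degenerate,
            "warnings": warnings_list,
        },
    )
    if mcmc.chains >= 2:
        draws.diagnostics = convergence_diagnostics(
            draws, mcmc.rhat_threshold, mcmc.ess_threshold
        )
    return draws


def augmented_cell_summary(draws: PosteriorDraws) -> list[dict]:
    """Posterior summaries of every augmented (missing) temperature cell."""
    cells = draws.arrays["T_cell"]
    flat = cells.reshape(-1, *cells.shape[2:])
    out = []
    for c, k in draws.coords["missing_cells"]:
        x = flat[:, c, k]
        cell = draws.coords["cells"][k]
        out.append(
            {
                "cave": draws.coords["caves"][c],
                "year": cell["year"],
                "season": cell["season"],
                "mean": float(x.mean()),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
            }
        )
    return out
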