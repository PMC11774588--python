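"""Joint Bayesian state-space fit of size-dependent seasonal growth.

Latent fork lengths z evolve across consecutive capture occasions as

    z[t+1] = z[t] + g(z[t]) * m[t],     g(z) = a_jt + b_jt (z - z_bar) + e

where m[t] is the interval length expressed in season-months (a summer month
is 67/2 nominal days, a winter month 298/10), g is the growth rate in
mm/month, and the intercept a_jt and slope b_jt carry season fixed effects,
a centred water-temperature effect and correlated random deviations over
cave (spatial), year (temporal) and cave x year (spatiotemporal):

    a_jt = a_h + a_hj + a_ht + a_hjt + a_hT * (T_hjt - T_bar)
    b_jt = b_h + b_hj + b_ht + b_hjt + b_hT * (T_hjt - T_bar)

Observed lengths add fixed measurement noise (variance eta^2, estimated
separately from repeat measures); sizes at unobserved occasions inside each
fish's capture span and missing temperature cells are sampled as latent
parameters, so the posterior integrates over both kinds of missingness.
The size at first capture follows N(mu0, sigma0^2).

Everything is conditionally linear-Gaussian, so the sampler is a pure Gibbs
scheme built from the conjugate blocks in :mod:`charrgrowth._samplers`.
Reported parameters are on the per-month growth scale throughout.
"""

from __future__ import annotations

import numpy as np

from ._samplers import (
    HalfTVariance,
    HuangWandCov2,
    collapsed_bivariate_loglik,
    sample_bivariate_groups,
    sample_mvn_regression,
)
from .config import MCMCConfig, Priors
from .data_io import DataError, GrowthPanel, SEASONS
from .draws import PosteriorDraws, convergence_diagnostics
from .synthetic import MONTH_DAYS
from .temperature import TemperatureGibbs, grid_from_panel

LEVELS = ("cave", "year", "caveyear")

NO_TEMPERATURE = "no_temperature"
NO_SEASON = "no_season"


class _FitData:
    """Flat index arrays derived from a panel, ready for the sampler."""

    def __init__(
        self,
        panel: GrowthPanel,
        ablations: frozenset[str],
        month_days: dict[str, float] | None = None,
    ):
        month_days = month_days or MONTH_DAYS
        F, T = panel.obs.shape
        self.panel = panel
        lat_of = np.full((F, T), -1, dtype=int)
        lat_fish, lat_occ = [], []
        for f in range(F):
            for o in range(panel.first[f], panel.last[f] + 1):
                lat_of[f, o] = len(lat_fish)
                lat_fish.append(f)
                lat_occ.append(o)
        self.lat_of = lat_of
        self.lat_fish = np.array(lat_fish)
        self.lat_occ = np.array(lat_occ)
        self.n_lat = len(lat_fish)
        self.first_lat = lat_of[np.arange(F), panel.first]

        obs_cells = np.argwhere(~np.isnan(panel.obs))
        self.obs_lat = lat_of[obs_cells[:, 0], obs_cells[:, 1]]
        self.obs_val = panel.obs[obs_cells[:, 0], obs_cells[:, 1]]

        # one interval per consecutive-occasion transition inside a support
        cur, nxt, months, k_idx, cave = [], [], [], [], []
        for f in range(F):
            for o in range(panel.first[f], panel.last[f]):
                cur.append(lat_of[f, o])
                nxt.append(lat_of[f, o + 1])
                iv = panel.intervals[o]
                months.append(panel.days[f, o] / month_days[iv.season])
                k_idx.append(o)
                cave.append(panel.fish_cave[f])
        self.cur = np.array(cur, dtype=int)
        self.nxt = np.array(nxt, dtype=int)
        self.months = np.array(months)
        self.k = np.array(k_idx, dtype=int)
        self.cave = np.array(cave, dtype=int)
        self.n_intervals = len(cur)

        years = sorted({iv.year for iv in panel.intervals})
        self.years = years
        year_of_k = np.array([years.index(iv.year) for iv in panel.intervals])
        self.year = year_of_k[self.k]
        real_season = np.array(
            [0 if iv.season == SEASONS[0] else 1 for iv in panel.intervals]
        )
        self.real_season = real_season[self.k]

        if NO_SEASON in ablations:
            self.season_labels = ["all"]
            self.gseason = np.zeros(self.n_intervals, dtype=int)
        else:
            self.season_labels = list(SEASONS)
            self.gseason = self.real_season.copy()
        self.n_seasons = len(self.season_labels)

        # per-season interval partitions and compact group indices per level
        self.sel = [np.where(self.gseason == s)[0] for s in range(self.n_seasons)]
        n_years = len(years)
        self.groups: list[dict] = []
        for s in range(self.n_seasons):
            sel = self.sel[s]
            keys = {
                "cave": self.cave[sel],
                "year": self.year[sel],
                "caveyear": self.cave[sel] * n_years + self.year[sel],
            }
            g = {}
            for level, arr in keys.items():
                uniq, inv = np.unique(arr, return_inverse=True)
                g[level] = (inv, len(uniq))
            self.groups.append(g)


class _GrowthState:
    def __init__(
        self,
        data: _FitData,
        priors: Priors,
        eta_sq: float,
        with_temp: bool,
        with_ranef: bool,
        with_size: bool,
        rng: np.random.Generator,
    ):
        panel = data.panel
        self.with_temp = with_temp
        self.with_ranef = with_ranef
        self.with_size = with_size
        self.eta_sq = eta_sq
        self.p = 4  # full coefficient vector; inactive entries stay zero

        # latent sizes: interpolate observed values along each support
        z = np.empty(data.n_lat)
        obs = panel.obs
        for f in range(panel.n_fish):
            occ = np.arange(panel.first[f], panel.last[f] + 1)
            seen = occ[~np.isnan(obs[f, occ])]
            z[data.lat_of[f, occ]] = np.interp(occ, seen, obs[f, seen])
        if eta_sq > 0:
            z += 0.5 * rng.standard_normal(data.n_lat)
        self.z = z
        self.pinned = np.zeros(data.n_lat, dtype=bool)
        if eta_sq == 0.0:
            self.pinned[data.obs_lat] = True
            self.z[data.obs_lat] = data.obs_val

        self.mu0 = float(np.mean(z[data.first_lat]))
        self.sig0 = HalfTVariance(
            priors.sd_df, priors.size_sd_scale,
            init=max(float(np.var(z[data.first_lat])), 1.0),
        )
        self.beta = [
            np.zeros(self.p) for _ in range(data.n_seasons)
        ]  # alpha, slope, alpha_T, slope_T (per month)
        self.u = [
            {level: np.zeros((data.groups[s][level][1], 2)) for level in LEVELS}
            for s in range(data.n_seasons)
        ]
        self.sigma = [
            {
                level: HuangWandCov2(priors.hw_nu, (priors.sd_scale, priors.sd_scale))
                for level in LEVELS
            }
            for s in range(data.n_seasons)
        ]
        self.ve = [
            HalfTVariance(priors.sd_df, priors.sd_scale, init=rng.uniform(0.5, 2.0))
            for _ in range(data.n_seasons)
        ]

    def linpred(self, data: _FitData, tc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interval-level intercept A and slope B of g(z) = A + B (z - z_bar)."""
        A = np.empty(data.n_intervals)
        B = np.empty(data.n_intervals)
        for s in range(data.n_seasons):
            sel = data.sel[s]
            b = self.beta[s]
            a_s = np.full(len(sel), b[0])
            b_s = np.full(len(sel), b[1])
            if self.with_temp:
                a_s += b[2] * tc[sel]
                b_s += b[3] * tc[sel]
            if self.with_ranef:
                for level in LEVELS:
                    gid, _ = data.groups[s][level]
                    a_s += self.u[s][level][gid, 0]
                    b_s += self.u[s][level][gid, 1]
            A[sel] = a_s
            B[sel] = b_s
        if not self.with_size:
            B[:] = 0.0
        return A, B

    def ve_per_interval(self, data: _FitData) -> np.ndarray:
        return np.array([v.value for v in self.ve])[data.gseason]


def fit_growth(
    panel: GrowthPanel,
    eta_sq: float | None,
    priors: Priors | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    ablations: tuple[str, ...] = (),
    include_random_effects: bool = True,
    include_size_dependence: bool = True,
    month_days: dict[str, float] | None = None,
) -> PosteriorDraws:
    """Run the joint Gibbs sampler over growth, latent sizes and temperature.

    ``eta_sq`` is the fixed measurement-error variance (mm^2); pass the
    estimate from :func:`charrgrowth.measurement.estimate_measurement_error`.
    ``ablations`` may contain ``"no_temperature"`` (drop the covariate and
    the embedded temperature model) and/or ``"no_season"`` (pool the two
    seasons' growth parameters).  ``month_days`` overrides the season-month
    convention (default: summer 33.5 d, winter 29.8 d).
    ``include_random_effects`` and ``include_size_dependence`` exist for
    degenerate designs and reduction checks; leave them on for real fits.
    """
    if eta_sq is None:
        raise DataError(
            "eta_sq is required: estimate it from repeat measures with "
            "charrgrowth.measurement.estimate_measurement_error"
        )
    if eta_sq < 0:
        raise DataError("eta_sq must be non-negative")
    unknown = set(ablations) - {NO_TEMPERATURE, NO_SEASON}
    if unknown:
        raise ValueError(f"unknown ablation flags {sorted(unknown)}")
    priors = priors or Priors()
    mcmc = mcmc or MCMCConfig()
    ab = frozenset(ablations)
    data = _FitData(panel, ab, month_days)
    with_temp = NO_TEMPERATURE not in ab
    n_years = len(data.years)
    if include_random_effects and (panel.n_caves < 2 or n_years < 2):
        raise DataError(
            "variance components need >= 2 caves and >= 2 years; "
            "set include_random_effects=False for degenerate designs"
        )

    temp_grid = grid_from_panel(panel) if with_temp else None
    missing_fraction = (
        float(np.isnan(panel.temp).mean()) if with_temp else 0.0
    )
    warnings_list = []
    if with_temp and missing_fraction > mcmc.missing_warn_fraction:
        warnings_list.append(
            f"{missing_fraction:.0%} of temperature cells are missing; "
            f"covariate augmentation may not converge at this coverage"
        )

    ss = np.random.SeedSequence(seed)
    scalars_by_chain, z_by_chain, t_by_chain = [], [], []
    for cs in ss.spawn(mcmc.chains):
        rng = np.random.default_rng(cs)
        out = _run_chain(data, priors, mcmc, eta_sq, with_temp,
                         include_random_effects, include_size_dependence,
                         temp_grid, rng)
        scalars_by_chain.append(out[0])
        z_by_chain.append(out[1])
        if with_temp:
            t_by_chain.append(out[2])

    scalars = {
        k: np.stack([c[k] for c in scalars_by_chain]) for k in scalars_by_chain[0]
    }
    arrays = {}
    if mcmc.store_latent:
        arrays["z"] = np.stack(z_by_chain)
        if with_temp:
            arrays["T_cell"] = np.stack(t_by_chain)

    draws = PosteriorDraws(
        scalars=scalars,
        arrays=arrays,
        coords={
            "latent": [
                [panel.fish_ids[f], int(o)]
                for f, o in zip(data.lat_fish, data.lat_occ)
            ],
            "caves": panel.cave_ids,
            "years": data.years,
            "season_labels": data.season_labels,
            "cells": [
                {"year": iv.year, "season": iv.season} for iv in panel.intervals
            ],
        },
        meta={
            "model": "growth",
            "seed": seed,
            "chains": mcmc.chains,
            "warmup": mcmc.warmup,
            "draws_per_chain": mcmc.draws,
            "eta_sq": eta_sq,
            "center_size": panel.center_size,
            "center_temp": panel.center_temp,
            "ablations": sorted(ab),
            "temperature_missing_fraction": missing_fraction,
            "warnings": warnings_list,
            "scale": "per-month",
        },
    )
    if mcmc.chains >= 2:
        draws.diagnostics = convergence_diagnostics(
            draws, mcmc.rhat_threshold, mcmc.ess_threshold
        )
    return draws


def _run_chain(
    data: _FitData,
    priors: Priors,
    mcmc: MCMCConfig,
    eta_sq: float,
    with_temp: bool,
    with_ranef: bool,
    with_size: bool,
    temp_grid,
    rng: np.random.Generator,
):
    panel = data.panel
    cz, cT = panel.center_size, panel.center_temp
    state = _GrowthState(data, priors, eta_sq, with_temp, with_ranef, with_size, rng)
    temp = TemperatureGibbs(temp_grid, priors, rng) if with_temp else None
    C = panel.n_caves
    K = len(panel.intervals)
    cell_flat = data.cave * K + data.k
    parity = data.lat_occ % 2
    fixed_prior_prec = np.eye(state.p) / priors.fixed_effect_sd**2

    rec_scalars: dict[str, np.ndarray] = {}
    rec_z = np.empty((mcmc.draws, data.n_lat))
    rec_t = np.empty((mcmc.draws, C, K)) if with_temp else None

    for it in range(mcmc.warmup + mcmc.draws):
        tc = (temp.cells.reshape(-1)[cell_flat] - cT) if with_temp else np.zeros(data.n_intervals)

        # --- latent sizes, alternating occasion parity -------------------
        for p in (0, 1):
            A, B = state.linpred(data, tc)
            ve = state.ve_per_interval(data) * data.months**2
            prec = np.zeros(data.n_lat)
            num = np.zeros(data.n_lat)
            if eta_sq > 0:
                np.add.at(prec, data.obs_lat, 1.0 / eta_sq)
                np.add.at(num, data.obs_lat, data.obs_val / eta_sq)
            prec[data.first_lat] += 1.0 / state.sig0.value
            num[data.first_lat] += state.mu0 / state.sig0.value
            zc_cur = state.z[data.cur]
            m_back = zc_cur + (A + B * (zc_cur - cz)) * data.months
            prec += np.bincount(data.nxt, weights=1.0 / ve, minlength=data.n_lat)
            prec_w = np.bincount(data.nxt, weights=m_back / ve, minlength=data.n_lat)
            num += prec_w
            c = 1.0 + B * data.months
            d = (A - B * cz) * data.months
            prec += np.bincount(data.cur, weights=c * c / ve, minlength=data.n_lat)
            num += np.bincount(
                data.cur, weights=c * (state.z[data.nxt] - d) / ve, minlength=data.n_lat
            )
            upd = (parity == p) & ~state.pinned
            state.z[upd] = num[upd] / prec[upd] + rng.standard_normal(
                int(upd.sum())
            ) / np.sqrt(prec[upd])

        # --- initial-size distribution -----------------------------------
        zf = state.z[data.first_lat]
        F = len(zf)
        prec0 = F / state.sig0.value + 1e-6
        state.mu0 = zf.sum() / state.sig0.value / prec0 + rng.standard_normal() / np.sqrt(prec0)
        state.sig0.update(float(((zf - state.mu0) ** 2).sum()), F, rng)

        # --- growth regression blocks ------------------------------------
        y = (state.z[data.nxt] - state.z[data.cur]) / data.months
        zcdev = state.z[data.cur] - cz
        for s in range(data.n_seasons):
            sel = data.sel[s]
            ve_s = state.ve[s].value
            # fixed effects
            A, B = state.linpred(data, tc)
            ran_a = A[sel] - _fixed_part(state, s, tc[sel], 0)
            ran_b = B[sel] - _fixed_part(state, s, tc[sel], 1)
            r = y[sel] - ran_a - ran_b * zcdev[sel]
            X, cols = _design(state, zcdev[sel], tc[sel])
            beta_sub = sample_mvn_regression(
                X.T @ X, X.T @ r, ve_s, fixed_prior_prec[np.ix_(cols, cols)], rng
            )
            beta = np.zeros(4)
            beta[cols] = beta_sub
            state.beta[s] = beta
            # random-effect levels: collapsed Metropolis on the covariance
            # (deviations integrated out, to cross the near-zero funnel),
            # then exact redraw of the deviations, then a conjugate refresh
            if state.with_ranef:
                for level in LEVELS:
                    gid, G = data.groups[s][level]
                    A, B = state.linpred(data, tc)
                    own = state.u[s][level][gid]
                    r = y[sel] - ((A[sel] - own[:, 0]) + (B[sel] - own[:, 1]) * zcdev[sel])
                    x = zcdev[sel]
                    s_n = np.bincount(gid, minlength=G).astype(float)
                    s_x = np.bincount(gid, weights=x, minlength=G)
                    s_xx = np.bincount(gid, weights=x * x, minlength=G)
                    s_r = np.bincount(gid, weights=r, minlength=G)
                    s_xr = np.bincount(gid, weights=x * r, minlength=G)
                    state.sigma[s][level].mh_update(
                        lambda sig: collapsed_bivariate_loglik(
                            sig, s_n, s_x, s_xx, s_r, s_xr, ve_s
                        ),
                        rng,
                    )
                    prior_prec = np.linalg.inv(state.sigma[s][level].value)
                    state.u[s][level] = sample_bivariate_groups(
                        prior_prec, s_n, s_x, s_xx, s_r, s_xr, ve_s, rng
                    )
                    u = state.u[s][level]
                    state.sigma[s][level].update(u.T @ u, G, rng)
            # translation ("sweep") moves: shift mass between the fixed
            # effect and each level's deviations.  Every interval carries
            # exactly one deviation per level, so the likelihood is invariant
            # and the shift has an exact Gaussian conditional; this breaks
            # the fixed-effect/random-mean confounding that otherwise makes
            # the centered Gibbs scheme mix very slowly.
            if state.with_ranef:
                f_prec = 1.0 / priors.fixed_effect_sd**2
                for level in LEVELS:
                    u = state.u[s][level]
                    G = len(u)
                    sig_inv = np.linalg.inv(state.sigma[s][level].value)
                    active = [0, 1] if state.with_size else [0]
                    P = (f_prec * np.eye(2) + G * sig_inv)[np.ix_(active, active)]
                    rhs = (
                        -f_prec * state.beta[s][:2] + sig_inv @ u.sum(axis=0)
                    )[active]
                    mean = np.linalg.solve(P, rhs)
                    chol = np.linalg.cholesky(P)
                    delta_sub = mean + np.linalg.solve(
                        chol.T, rng.standard_normal(len(active))
                    )
                    delta = np.zeros(2)
                    delta[active] = delta_sub
                    state.beta[s][0] += delta[0]
                    state.beta[s][1] += delta[1]
                    state.u[s][level] = u - delta
            # residual variance
            A, B = state.linpred(data, tc)
            resid = y[sel] - (A[sel] + B[sel] * zcdev[sel])
            state.ve[s].update(float(resid @ resid), len(sel), rng)

        # --- embedded temperature model ----------------------------------
        if with_temp:
            A, B = state.linpred(data, tc)
            w = np.empty(data.n_intervals)
            for s in range(data.n_seasons):
                sel = data.sel[s]
                w[sel] = state.beta[s][2] + state.beta[s][3] * zcdev[sel]
            ve_i = state.ve_per_interval(data)
            # response minus the mean with the temperature term removed
            r_nt = y - (A + B * zcdev) + w * tc
            extra_prec = np.bincount(
                cell_flat, weights=w * w / ve_i, minlength=C * K
            ).reshape(C, K)
            extra_num = np.bincount(
                cell_flat, weights=w * (r_nt + w * cT) / ve_i, minlength=C * K
            ).reshape(C, K)
            temp.update_latent(rng, extra_prec, extra_num)
            temp.update_params(rng)

        # --- record -------------------------------------------------------
        if it >= mcmc.warmup:
            dix = it - mcmc.warmup
            rec = _record(state, data, temp)
            for k, v in rec.items():
                rec_scalars.setdefault(k, np.empty(mcmc.draws))[dix] = v
            rec_z[dix] = state.z
            if with_temp:
                rec_t[dix] = temp.cells
    return rec_scalars, rec_z, rec_t


def _fixed_part(state: _GrowthState, s: int, tc: np.ndarray, which: int) -> np.ndarray:
    b = state.beta[s]
    if which == 0:
        out = np.full(len(tc), b[0])
        if state.with_temp:
            out = out + b[2] * tc
    else:
        out = np.full(len(tc), b[1])
        if state.with_temp:
            out = out + b[3] * tc
        if not state.with_size:
            out[:] = 0.0
    return out


def _design(state: _GrowthState, zc: np.ndarray, tc: np.ndarray):
    """Active design columns of [1, zc, tc, tc*zc] and their indices."""
    columns = {0: np.ones_like(zc), 1: zc, 2: tc, 3: tc * zc}
    cols = [0]
    if state.with_size:
        cols.append(1)
    if state.with_temp:
        cols.append(2)
        if state.with_size:
            cols.append(3)
    return np.column_stack([columns[c] for c in cols]), np.array(cols)


def _record(state: _GrowthState, data: _FitData, temp) -> dict:
    out = {"mu0": state.mu0, "sigma0_sq": state.sig0.value}
    for s, label in enumerate(data.season_labels):
        b = state.beta[s]
        out[f"alpha[{label}]"] = b[0]
        out[f"slope[{label}]"] = b[1]
        if state.with_temp:
            out[f"alpha_temp[{label}]"] = b[2]
            out[f"slope_temp[{label}]"] = b[3]
        out[f"V_resid[{label}]"] = state.ve[s].value
        if state.with_ranef:
            for level in LEVELS:
                sig = state.sigma[s][level].value
                out[f"V_alpha_{level}[{label}]"] = sig[0, 0]
                out[f"V_slope_{level}[{label}]"] = sig[1, 1]
                out[f"cov_alpha_slope_{level}[{label}]"] = sig[0, 1]
    if temp is not None:
        out.update(temp.record())
    return out


# ---------------------------------------------------------------------------
# posterior-based operations


def predict_size(
    draws: PosteriorDraws,
    fish_id: str,
    occasion: int,
    include_measurement_noise: bool = True,
    seed: int = 0,
) -> dict:
    """Posterior-predictive summary of a fish's size at one occasion.

    The occasion must lie inside the fish's latent support.  The predictive
    distribution adds measurement noise (variance eta^2 from the fit's
    metadata) to the latent-size draws, matching what an actual measurement
    would look like.
    """
    if "z" not in draws.arrays:
        raise ValueError("fit was run with store_latent=False; latent draws unavailable")
    key = [fish_id, int(occasion)]
    try:
        idx = draws.coords["latent"].index(key)
    except ValueError:
        raise KeyError(
            f"occasion {occasion} is outside the latent support of fish {fish_id!r}"
        ) from None
    z = draws.stacked("z")[:, idx]
    if include_measurement_noise and draws.meta["eta_sq"] > 0:
        rng = np.random.default_rng(seed)
        z = z + rng.normal(0.0, np.sqrt(draws.meta["eta_sq"]), len(z))
    return {
        "mean": float(z.mean()),
        "sd": float(z.std(ddof=1)),
        "q2.5": float(np.quantile(z, 0.025)),
        "q97.5": float(np.quantile(z, 0.975)),
    }


def simulate_growth_functions(
    draws: PosteriorDraws,
    size_range: tuple[float, float] = (70.0, 120.0),
    n_curves: int = 50,
    seed: int = 0,
    levels: tuple[str, ...] = LEVELS,
    n_grid: int = 26,
) -> dict:
    """Sample growth-rate curves g(z) in mm/month over a size grid.

    For each season and requested level, draws a posterior sample of the
    fixed effects and level covariance, then a random (intercept, slope)
    deviation from that covariance, giving one curve
    g(z) = (a_h + da) + (b_h + db)(z - z_bar).  The spread of the curves
    visualises how much growth varies at that level.
    """
    rng = np.random.default_rng(seed)
    unknown = set(levels) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown level name(s) {sorted(unknown)}")
    grid = np.linspace(size_range[0], size_range[1], n_grid)
    zc = grid - draws.meta["center_size"]
    out = {"size_mm": grid, "curves": {}}
    n_total = draws.n_chains * draws.n_draws
    for label in draws.coords["season_labels"]:
        alpha = draws.stacked(f"alpha[{label}]")
        slope = draws.stacked(f"slope[{label}]")
        out["curves"][label] = {}
        for level in levels:
            va = draws.stacked(f"V_alpha_{level}[{label}]")
            vb = draws.stacked(f"V_slope_{level}[{label}]")
            cab = draws.stacked(f"cov_alpha_slope_{level}[{label}]")
            pick = rng.integers(0, n_total, n_curves)
            curves = np.empty((n_curves, n_grid))
            for i, ix in enumerate(pick):
                cov = np.array([[va[ix], cab[ix]], [cab[ix], vb[ix]]])
                # guard tiny negative determinants from posterior draws
                cov[0, 0] = max(cov[0, 0], 0.0)
                cov[1, 1] = max(cov[1, 1], 0.0)
                lim = np.sqrt(cov[0, 0] * cov[1, 1])
                cov[0, 1] = cov[1, 0] = np.clip(cov[0, 1], -lim, lim)
                da, db = rng.multivariate_normal([0.0, 0.0], cov, method="svd")
                curves[i] = (alpha[ix] + da) + (slope[ix] + db) * zc
            out["curves"][label][level] = curves
    return out


def asymptotic_size_from(
    alpha: np.ndarray, slope: np.ndarray, center_size: float
) -> tuple[np.ndarray, int]:
    """Sizes where expected growth is zero: z* = z_bar - alpha / slope.

    Draws with non-negative slope have no finite asymptote and come back as
    NaN; the count of such draws is returned alongside.
    """
    alpha = np.asarray(alpha, dtype=float)
    slope = np.asarray(slope, dtype=float)
    defined = slope < 0
    z_star = np.where(defined, center_size - alpha / np.where(defined, slope, -1.0), np.nan)
    return z_star, int((~defined).sum())


def asymptotic_size(draws: PosteriorDraws) -> dict:
    """Per-draw asymptotic size from annualised growth parameters.

    Annual rates sum the per-month seasonal rates over the season lengths
    (2 summer months + 10 winter months); the asymptote is where the annual
    expected growth of the average environment crosses zero.
    """
    labels = draws.coords["season_labels"]
    if labels == ["all"]:
        alpha = 12.0 * draws.stacked("alpha[all]")
        slope = 12.0 * draws.stacked("slope[all]")
    else:
        alpha = 2.0 * draws.stacked("alpha[summer]") + 10.0 * draws.stacked("alpha[winter]")
        slope = 2.0 * draws.stacked("slope[summer]") + 10.0 * draws.stacked("slope[winter]")
    z_star, n_undefined = asymptotic_size_from(alpha, slope, draws.meta["center_size"])
    finite = z_star[np.isfinite(z_star)]
    return {
        "draws": z_star,
        "n_undefined": n_undefined,
        "mean": float(finite.mean()) if len(finite) else float("nan"),
        "q2.5": float(np.quantile(finite, 0.025)) if len(finite) else float("nan"),
        "q97.5": float(np.quantile(finite, 0.975)) if len(finite) else float("nan"),
    }
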