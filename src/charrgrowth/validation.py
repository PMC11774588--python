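"""Posterior-predictive validation by single-observation holdouts.

The scheme removes one observed fork length from each of a handful of
randomly chosen fish, refits the full joint model, and asks the posterior
predictive distribution to recover the held-out measurement.  Repeating the
round many times (the field protocol is 10 fish per round, 99 rounds, i.e.
990 holdout predictions) yields calibration aggregates: the fraction of
held-out observations inside their 95% predictive intervals, the Pearson
correlation between predictions and observations, and the mean absolute
residual in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MCMCConfig, Priors
from .data_io import DataError, GrowthPanel
from .draws import PosteriorDraws, convergence_diagnostics
from .growth import fit_growth, predict_size


@dataclass(frozen=True)
class RemovalPlan:
    """Reproducible holdout schedule: one removed observation per fish per round."""

    rounds: tuple[tuple[tuple[str, int], ...], ...]
    seed: int

    @property
    def n_holdouts(self) -> int:
        return sum(len(r) for r in self.rounds)


def plan_removals(
    panel: GrowthPanel,
    n_fish_per_round: int = 10,
    n_rounds: int = 99,
    seed: int = 0,
    min_observations: int = 3,
) -> RemovalPlan:
    """Draw the holdout schedule.

    Only fish with at least ``min_observations`` captures are eligible, so
    each holdout leaves a trajectory with >= 2 points that still informs
    growth.  Fish are distinct within a round; rounds are independent draws.
    """
    n_obs = (~np.isnan(panel.obs)).sum(axis=1)
    eligible = np.where(n_obs >= min_observations)[0]
    if len(eligible) < n_fish_per_round:
        raise DataError(
            f"only {len(eligible)} fish have >= {min_observations} observations; "
            f"{n_fish_per_round} needed per round"
        )
    rng = np.random.default_rng(seed)
    rounds = []
    for _ in range(n_rounds):
        fish = rng.choice(eligible, size=n_fish_per_round, replace=False)
        rnd = []
        for f in fish:
            occs = np.where(~np.isnan(panel.obs[f]))[0]
            occ = int(rng.choice(occs))
            rnd.append((panel.fish_ids[f], occ))
        rounds.append(tuple(rnd))
    return RemovalPlan(rounds=tuple(rounds), seed=seed)


@dataclass
class PPCResult:
    """Per-holdout predictions and calibration aggregates."""

    table: pd.DataFrame  # fish_id, occasion, observed, pred_mean, q2.5, q97.5, round
    coverage: float
    correlation: float
    mean_abs_residual: float
    n_rounds: int
    n_failed_rounds: int
    failed_rounds: list = field(default_factory=list)

    def recompute_aggregates(self) -> dict:
        """Aggregates recomputed from the per-point table (consistency check)."""
        t = self.table
        inside = (t["observed"] >= t["q2.5"]) & (t["observed"] <= t["q97.5"])
        return {
            "coverage": float(inside.mean()),
            "correlation": float(np.corrcoef(t["observed"], t["pred_mean"])[0, 1]),
            "mean_abs_residual": float((t["observed"] - t["pred_mean"]).abs().mean()),
        }


def run_ppc(
    panel: GrowthPanel,
    plan: RemovalPlan,
    eta_sq: float,
    mcmc: MCMCConfig | None = None,
    priors: Priors | None = None,
    seed: int = 0,
    ablations: tuple[str, ...] = (),
) -> PPCResult:
    """Refit once per round with the round's observations held out and score.

    Rounds whose refit fails the convergence diagnostics are flagged and
    excluded from the aggregates; their count is reported.  Aggregates use
    the 95% predictive interval (latent size plus measurement noise).
    """
    mcmc = mcmc or MCMCConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    failed = []
    for rnd_ix, (rnd, rs) in enumerate(zip(plan.rounds, ss.spawn(len(plan.rounds)))):
        sub = panel.drop_observations(list(rnd))
        fit_seed = int(rs.generate_state(1)[0] % (2**31))
        draws = fit_growth(
            sub, eta_sq, priors=priors, mcmc=mcmc, seed=fit_seed, ablations=ablations
        )
        if draws.diagnostics is not None and not draws.diagnostics["converged"]:
            failed.append(rnd_ix)
            continue
        for fish_id, occ in rnd:
            pred = predict_size(draws, fish_id, occ, seed=fit_seed)
            rows.append(
                {
                    "round": rnd_ix,
                    "fish_id": fish_id,
                    "occasion": occ,
                    "observed": float(panel.obs[panel.fish_index(fish_id), occ]),
                    "pred_mean": pred["mean"],
                    "q2.5": pred["q2.5"],
                    "q97.5": pred["q97.5"],
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise DataError("no converged PPC rounds; nothing to aggregate")
    inside = (table["observed"] >= table["q2.5"]) & (table["observed"] <= table["q97.5"])
    return PPCResult(
        table=table,
        coverage=float(inside.mean()),
        correlation=float(np.corrcoef(table["observed"], table["pred_mean"])[0, 1]),
        mean_abs_residual=float((table["observed"] - table["pred_mean"]).abs().mean()),
        n_rounds=len(plan.rounds),
        n_failed_rounds=len(failed),
        failed_rounds=failed,
    )


def diagnostics(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.05,
    ess_threshold: float = 100.0,
) -> dict:
    """Split-chain convergence report; see :func:`charrgrowth.draws.convergence_diagnostics`."""
    return convergence_diagnostics(draws, rhat_threshold, ess_threshold)
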