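"""Seasonal summaries, unit conversions and rendered report tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import SEASON_MONTHS, SEASONS
from .draws import PosteriorDraws
from .growth import simulate_growth_functions
from .validation import PPCResult
from .variance import VarianceReport


def monthly_to_seasonal(value_per_month: float, season: str) -> float:
    """Convert a monthly rate to a season total (x2 summer, x10 winter).

    Under the season-month convention (a summer month is 67/2 nominal days,
    a winter month 298/10) seasonal totals are exactly the monthly rate
    times the number of season months, so interval bounds convert the same
    way as point estimates.
    """
    if season not in SEASON_MONTHS:
        raise KeyError(f"unknown season {season!r}")
    return value_per_month * SEASON_MONTHS[season]


def seasonal_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Growth of the average-sized fish per season: monthly and season totals.

    Reports the posterior mean and equal-tailed 95% interval of the growth
    intercept (mm/month at the centring size and temperature), its seasonal
    total, the temperature effects, and the size-dependence slope per month
    and annualised (2 summer + 10 winter months).
    """
    rows = []
    labels = draws.coords["season_labels"]
    for label in labels:
        months = SEASON_MONTHS.get(label, 12)
        a = draws.stacked(f"alpha[{label}]")
        b = draws.stacked(f"slope[{label}]")
        entries = {
            "growth_mm_per_month": a,
            "growth_mm_per_season": a * months,
            "slope_per_month": b,
        }
        if f"alpha_temp[{label}]" in draws.scalars:
            entries["temp_effect_mm_per_month_per_C"] = draws.stacked(
                f"alpha_temp[{label}]"
            )
            entries["temp_effect_on_slope_per_C"] = draws.stacked(f"slope_temp[{label}]")
        for name, arr in entries.items():
            rows.append(
                {
                    "season": label,
                    "quantity": name,
                    "mean": float(arr.mean()),
                    "q2.5": float(np.quantile(arr, 0.025)),
                    "q97.5": float(np.quantile(arr, 0.975)),
                }
            )
    if set(labels) == set(SEASONS):
        b_ann = 2.0 * draws.stacked("slope[summer]") + 10.0 * draws.stacked("slope[winter]")
        rows.append(
            {
                "season": "annual",
                "quantity": "slope_per_year",
                "mean": float(b_ann.mean()),
                "q2.5": float(np.quantile(b_ann, 0.025)),
                "q97.5": float(np.quantile(b_ann, 0.975)),
            }
        )
    return pd.DataFrame(rows)


def temperature_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Seasonal temperature table: mean, the variance components and their total."""
    rows = []
    for season in SEASONS:
        name = f"T_mean[{season}]"
        if name not in draws.scalars:
            continue
        entries = {
            "posterior_mean_T": draws.stacked(name),
            "variance_among_caves": draws.stacked(f"V_cave_T[{season}]"),
            "variance_among_years": draws.stacked(f"V_year_T[{season}]"),
            "residual_variance": draws.stacked(f"V_resid_T[{season}]"),
        }
        entries["total_variance"] = (
            entries["variance_among_caves"]
            + entries["variance_among_years"]
            + entries["residual_variance"]
        )
        for qname, arr in entries.items():
            rows.append(
                {
                    "season": season,
                    "quantity": qname,
                    "mean": float(arr.mean()),
                    "q2.5": float(np.quantile(arr, 0.025)),
                    "q97.5": float(np.quantile(arr, 0.975)),
                }
            )
    return pd.DataFrame(rows)


def make_report(
    draws: PosteriorDraws,
    variance_report: VarianceReport | None,
    ppc: PPCResult | None,
    out_dir: str | Path,
    curve_seed: int = 0,
) -> dict:
    """Render CSV tables and curve samples; returns the run manifest.

    Writes growth_summary.csv, temperature_summary.csv (when the temperature
    model was fitted), variance_report.csv, growth_curves.csv (sampled
    growth functions over the 70-120 mm core size range) and ppc.csv, plus
    manifest.json recording seeds and configuration for re-running.  Cells
    unavailable under an ablation are rendered as "NA", not left blank.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seasonal_summary(draws).to_csv(out / "growth_summary.csv", index=False)
    tsum = temperature_summary(draws)
    if not tsum.empty:
        tsum.to_csv(out / "temperature_summary.csv", index=False)
    if variance_report is not None:
        variance_report.to_csv(out / "variance_report.csv")
    else:
        pd.DataFrame(
            [{"season": "NA", "quantity": "NA", "mean": "NA", "q2.5": "NA", "q97.5": "NA"}]
        ).to_csv(out / "variance_report.csv", index=False)

    curves = simulate_growth_functions(draws, seed=curve_seed)
    rows = []
    for season, by_level in curves["curves"].items():
        for level, arr in by_level.items():
            for i, curve in enumerate(arr):
                for z, g in zip(curves["size_mm"], curve):
                    rows.append(
                        {
                            "season": season,
                            "level": level,
                            "curve": i,
                            "size_mm": float(z),
                            "growth_mm_per_month": float(g),
                        }
                    )
    pd.DataFrame(rows).to_csv(out / "growth_curves.csv", index=False)

    if ppc is not None:
        ppc.table.to_csv(out / "ppc.csv", index=False)

    manifest = {
        "fit_meta": {k: v for k, v in draws.meta.items()},
        "diagnostics_converged": None
        if draws.diagnostics is None
        else draws.diagnostics["converged"],
        "curve_seed": curve_seed,
        "ppc": None
        if ppc is None
        else {
            "coverage": ppc.coverage,
            "correlation": ppc.correlation,
            "mean_abs_residual": ppc.mean_abs_residual,
            "n_failed_rounds": ppc.n_failed_rounds,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
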