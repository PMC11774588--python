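"""Container for MCMC output shared by the temperature and growth fits."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PosteriorDraws:
    """Joint posterior draws with chain structure preserved.

    ``scalars`` maps a parameter label (e.g. ``"alpha[summer]"``) to an array
    of shape (chains, draws).  Larger blocks (latent sizes, the augmented
    temperature field) live in ``arrays`` with shape (chains, draws, ...),
    with their index labels in ``coords``.
    """

    scalars: dict[str, np.ndarray]
    arrays: dict[str, np.ndarray] = field(default_factory=dict)
    coords: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    diagnostics: dict | None = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.scalars.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.scalars.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (chains*draws, ...)."""
        if name in self.scalars:
            return self.scalars[name].reshape(-1)
        arr = self.arrays[name]
        return arr.reshape(-1, *arr.shape[2:])

    def summary(self, name: str) -> dict:
        """Posterior mean with an equal-tailed 95% credible interval."""
        x = self.stacked(name)
        return {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "q2.5": float(np.quantile(x, 0.025)),
            "q97.5": float(np.quantile(x, 0.975)),
        }

    def summary_frame(self) -> pd.DataFrame:
        rows = [dict(parameter=k, **self.summary(k)) for k in self.scalars]
        return pd.DataFrame(rows).set_index("parameter")

    def to_inference_data(self):
        """Scalar parameters as an :mod:`arviz` InferenceData object."""
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.scalars.items()})

    # -- persistence --------------------------------------------------------

    def save(self, out_dir: str | Path, include_arrays: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        chains, draws = self.n_chains, self.n_draws
        tab = {
            "chain": np.repeat(np.arange(chains), draws),
            "draw": np.tile(np.arange(draws), chains),
        }
        for k, v in self.scalars.items():
            tab[k] = v.reshape(-1)
        pd.DataFrame(tab).to_csv(out / "draws.csv", index=False)
        manifest = {
            "meta": _jsonable(self.meta),
            "coords": _jsonable(self.coords),
            "diagnostics": _jsonable(self.diagnostics),
            "scalars": list(self.scalars),
            "arrays": {k: list(v.shape) for k, v in self.arrays.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        if include_arrays:
            for k, v in self.arrays.items():
                flat = v.reshape(chains * draws, -1)
                pd.DataFrame(flat).to_csv(out / f"array_{k}.csv", index=False)

    @classmethod
    def load(cls, in_dir: str | Path) -> "PosteriorDraws":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        tab = pd.read_csv(src / "draws.csv")
        chains = int(tab["chain"].max()) + 1
        draws = len(tab) // chains
        scalars = {
            k: tab[k].to_numpy().reshape(chains, draws) for k in manifest["scalars"]
        }
        arrays = {}
        for k, shape in manifest["arrays"].items():
            path = src / f"array_{k}.csv"
            if path.exists():
                arrays[k] = pd.read_csv(path).to_numpy().reshape(shape)
        return cls(
            scalars=scalars,
            arrays=arrays,
            coords=manifest["coords"],
            meta=manifest["meta"],
            diagnostics=manifest["diagnostics"],
        )


def convergence_diagnostics(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.05,
    ess_threshold: float = 100.0,
) -> dict:
    """Split-chain R-hat and bulk effective sample size per scalar parameter.

    Passes when every parameter's R-hat is at or below the threshold and
    every effective sample size is at or above its floor.  Parameters that
    are numerically constant across all draws (e.g. a variance pinned at
    zero in a degenerate design) are reported but not scored.
    """
    import warnings

    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require at least two chains")
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    checked = []
    for name, arr in draws.scalars.items():
        if np.ptp(arr) < 1e-12:  # constant; R-hat undefined
            rhat[name] = float("nan")
            ess[name] = float("nan")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = float(az.rhat(arr[None] if arr.ndim == 1 else arr))
            e = float(az.ess(arr[None] if arr.ndim == 1 else arr))
        rhat[name] = r
        ess[name] = e
        checked.append(name)
    ok = all(rhat[n] <= rhat_threshold for n in checked) and all(
        ess[n] >= ess_threshold for n in checked
    )
    return {
        "rhat": rhat,
        "ess": ess,
        "rhat_threshold": rhat_threshold,
        "ess_threshold": ess_threshold,
        "converged": bool(ok),
    }


def _jsonable(obj):
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)
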