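"""Generate a synthetic cave-system dataset and look at its shape.

The generator emulates the field design: ~20 isolated cave populations of
Arctic charr sampled each June and August, individually tagged fish measured
to the nearest mm, seasonal mean water temperature per cave with a fraction
of cells missing, and duplicate measurements on a subset of fish.
"""

import numpy as np

import charrgrowth as cg

config = cg.preset("paper-small")  # ~8 caves x 11 occasions, desk scale
captures, occasions, temperatures, repeats, truth = cg.simulate_dataset(config, seed=1)

panel = cg.build_panel(captures, temperatures, occasions)
lengths = np.array([c.fork_length_mm for c in captures])

print(f"occasions     : {panel.n_occasions} (June/August "
      f"{occasions[0].year}-{occasions[-1].year})")
print(f"caves         : {panel.n_caves}")
print(f"fish observed : {panel.n_fish} (of {len(truth.trajectories)} simulated)")
print(f"observations  : {len(captures)}")
print(f"mean length   : {lengths.mean():.1f} mm "
      f"(95% range {np.quantile(lengths, 0.025):.0f}-{np.quantile(lengths, 0.975):.0f})")
print(f"temperature   : {panel.n_missing_temp} of "
      f"{panel.temp.size} cave x season cells missing")

# Each fish is seen intermittently; the model will integrate over the gaps.
n_obs = (~np.isnan(panel.obs)).sum(axis=1)
print(f"captures/fish : mean {n_obs.mean():.2f}, max {n_obs.max()}")
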