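"""Partition growth variation into space, time, space-time and temperature.

From a fitted posterior, each season's growth variance splits into
size-independent components (intercept variance over cave / year /
cave x year), size-dependent components (slope variance, converted to growth
units via the post-season fork-length variance sigma_fl^2), and the share
associated with water temperature (via V(a + bx) = b^2 V(x)).  R values are
each component's share of the spatiotemporal total V_g, computed per draw.
"""

import charrgrowth as cg

config = cg.preset("paper-small")
captures, occasions, temperatures, repeats, _ = cg.simulate_dataset(config, seed=5)
panel = cg.build_panel(captures, temperatures, occasions)

draws = cg.fit_growth(panel, eta_sq=config.eta_sq, mcmc=cg.smoke_mcmc(), seed=6)

sigma_fl = {
    season: cg.fork_length_variance(panel, season, seed=0).total
    for season in ("summer", "winter")
}
print(f"sigma_fl^2: summer {sigma_fl['summer']:.1f} mm^2, "
      f"winter {sigma_fl['winter']:.1f} mm^2")

report = cg.repeatability(draws, sigma_fl)
tab = report.table
shares = tab[tab.quantity.str.startswith("R_alpha_")]
print(shares.round(3).to_string(index=False))
# R_alpha_year is the fraction of spatiotemporal growth variation carried by
# year-to-year (temporal) differences in size-independent growth; the three
# size-independent, three size-dependent and three temperature shares sum to
# one within each season.
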