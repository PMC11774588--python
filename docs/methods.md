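# Methods

## Model

The package implements an integrated state-space model for seasonal,
size-dependent growth of individually tagged fish in a grid of discrete
sites ("caves") sampled twice a year (June and August).  Two linked process
models share one posterior:

**Growth.** For fish *i* in cave *j*, the latent fork length at the next
occasion is `z[t+1] = z[t] + g(z[t])·m`, where `m` is the interval length in
season-months and `g(z) = α_jt + b_jt(z − z̄) + e` is the growth rate in
mm/month at centred size.  The intercept α (size-independent growth) and
slope b (size-dependent growth) each decompose into a season fixed effect,
a centred-temperature effect, and random deviations over cave, year and
cave×year.  At each level and season the (intercept, slope) deviation pair
is bivariate normal with an estimated 2×2 covariance.  The residual e has a
season-specific variance on the per-month growth-rate scale, independent of
interval length.  Sizes at first capture follow `N(μ0, σ0²)` shared across
caves; observed lengths add fixed measurement noise `N(0, η²)`.

**Temperature.** Seasonal mean water temperature per cave×year cell follows
`T = a_h + a_hj + a_ht + ε` with season-specific cave and year intercepts.
A fixed, essentially-zero observation variance (1e-4 °C²) is attached to
observed cells purely so that observed and missing cells share one latent
representation; missing cells are then ordinary latent parameters, and the
growth model's covariate term integrates over them.

**Assumptions worth stating.** Latent-size support ends at the last
capture: the data cannot distinguish death from non-capture and no survival
sub-model is attempted, so nothing is asserted about a fish after it is
last seen.  Single-capture fish are retained; they inform μ0, σ0² and the
measurement model only.  Temperature missingness is assumed ignorable
(missing at random).  Growth is linear in size over the observed range —
the usual local linearisation of saturating size-at-age curves — so the
"asymptotic size" z* = z̄ − α/b is an extrapolation diagnostic, not a fitted
quantity.

## Units and conversions

The canonical reporting scale is mm/month, with a season-month defined as
season length over months-in-season: summer = 67/2 = 33.5 nominal days,
winter = 298/10 = 29.8.  This makes seasonal totals exactly
months × monthly rate, so credible-interval bounds convert by the same
factor (×2 summer, ×10 winter).  Interval day counts are calendar-exact
(leap-year winters are 299 days) from the nominal field dates (16 June,
22 August), overridden by actual capture dates when a fish was measured on
both ends of a consecutive-occasion transition.  Variance components are
reported per month²; multiplying by months² gives the seasonal-total scale.
The month convention is overridable (`month_days=` / model.yaml).

## Sampler

All full conditionals are conjugate (normal regression blocks,
inverse-gamma variances via the half-Student-t scale mixture, Huang–Wand
inverse-Wishart for the 2×2 covariance blocks, ν=2, so SDs are marginally
half-t and correlations uniform).  Two known pathologies of the plain
centered Gibbs scheme are addressed with extra exact moves:

* **Translation sweeps.** A fixed effect and the mean of its random
  deviations are strongly anti-correlated.  Because every interval carries
  exactly one deviation per level, shifting δ from the deviations into the
  fixed effect leaves the likelihood invariant, and δ has an exact Gaussian
  conditional; one sweep per level per iteration removes the confounding.
  The temperature model gets the scalar analogue.
* **Collapsed Metropolis on variances.** Near zero, the conjugate
  variance update barely moves (the funnel).  Each iteration also proposes
  random-walk moves on (log V₀, log V₁, atanh ρ) against the marginal
  likelihood with the group deviations integrated out analytically
  (Woodbury in closed 2×2 form), then redraws the deviations — a partially
  collapsed scheme that mixes across orders of magnitude.

Latent sizes are updated by red–black (even/odd occasion) blocks — each
size's conditional given its neighbours, the observation, and the
first-capture prior is Gaussian.  With η² = 0 observed sizes are pinned to
the data.  Latent temperature cells combine the process prior, the
(near-delta) observation term, and the growth likelihood, which is linear
in T.

Defaults: 4 chains × 1000 post-warmup draws (1000 warmup), split-chain
R-hat ≤ 1.05 and bulk ESS ≥ 100 on every scalar parameter.
Near-zero variance components mix slowest; a fit flagged non-converged
should simply be run longer.  `smoke_mcmc()` (2 × 400, R-hat ≤ 1.2,
ESS ≥ 25) exists for demonstrations and quick checks, not for results.

Priors: N(0, 100²) on fixed effects; half-t(3, 5) on growth-scale SDs;
half-t(3, 25) on fork-length-scale SDs (σ0); the fork-length-variance side
model scales its SD priors to the data SD.  All configurable via `Priors`.

## Derived quantities

Every derived quantity is computed per posterior draw and only then
summarised.  Temperature-associated variance uses `V(a + bx) = b²V(x)`:
the cave-level share pairs the growth temperature effect with the
temperature model's cave variance, the year level with the year variance,
and the cave×year level with the temperature residual variance.
Slope (size-dependent) variance is converted to growth-variance units by
multiplying with σ²_fl, the variance of fork lengths observed after the
season in question.  σ²_fl comes from an intercept-only variance-components
model (cave and year factors); it reports the *realized* decomposition
(observation-weighted variance of the fitted, shrunk deviations plus
residual variance) rather than the population variance parameters, which
are prior-dominated when a factor has few levels.  The proportional shares
R divide each of the nine components (3 levels × {size-independent,
converted size-dependent, temperature}) by V_g = V_j + V_t + V_jt and sum
to exactly 1 per draw; draws with V_g = 0 are excluded from R summaries and
counted.  V_e is reported alongside, and an alternative share with V_e in
the denominator is included under an explicit `_incl_resid` label, since
either convention appears in practice.

## Synthetic data

The generator emulates the study design: ~20 caves × 15 semi-annual
occasions (the `paper-like` preset; `paper-small` is the same structure at
8 caves × 11 occasions for desk-scale work), temperature fields with the
study's seasonal means and variance components, growth parameters at the
study's posterior means, measurement noise η² = 0.6 mm², and intermittent
observation.  Reference variance components are interpreted on the
seasonal-total growth scale and divided by months² for the per-month scale;
the per-month reading would imply year-to-year winter swings (~±40 mm per
winter) wildly inconsistent with the reported seasonal totals.

Choices the design left open, fixed once here: capture probability 0.5 per
occasion and geometric per-interval survival 0.8 with steady recruitment
(16 recruits/cave/occasion in `paper-like`), which jointly reproduce the
study's observation intensity (~9.2k observations of ~3.8k fish, ~2.4
captures per fish); initial sizes N(76, 13.5²) mm truncated at the 45 mm
tagging threshold, calibrated so the preset reproduces the reported grand
mean (~92 mm) and 95% size range; temperature missingness 22%, applied
uniformly at random; intercept–slope correlations 0 by default.  Negative
propagated sizes are handled by resampling the growth residual (counted in
the truth manifest), keeping the process otherwise linear-Gaussian.

What the generator does **not** emulate: tag loss, the two-visit
within-occasion structure, size-dependent capture probability, true
mortality/emigration distinction, food input, or any non-linearity in
growth.  Passing recovery tests on these simulations therefore demonstrates
the estimator is correct *under the model's own assumptions*, not that the
model is adequate for any particular field system.

## Validation

The holdout scheme removes one observation from each of 10 random fish
(eligibility ≥ 3 captures so every holdout leaves a usable trajectory),
refits the full joint model, and predicts the held-out measurements; over
many rounds this yields coverage of the 95% predictive intervals, the
prediction–observation correlation, and the mean absolute residual.  The
field protocol (99 rounds → 990 predictions) is the planner's default; test
and demonstration runs use fewer rounds at reduced MCMC effort.

## Problem sizes used by the checks

The test suite exercises: the mixed-model oracle equivalence on a fully
observed 5-cave × 8-occasion system (~240 fish; state-space posterior vs a
statsmodels crossed-random-effects fit, within 3 posterior SDs);
variance-component recovery over 5 replicate `paper-small` simulations
(95% CI coverage ≥ 0.85 across 40 component checks); predictive coverage on
200 holdouts (20 rounds × 10 fish) at reduced MCMC effort; and the
derivation identities per draw.  These sizes were chosen as the smallest
instances at which each property is statistically meaningful; all scale up
unchanged.

## Known limitations

* The temperature effect on growth is weakly identified when cave/year/
  cave×year random effects are free — they can absorb most
  covariate-correlated variation.  Its posterior is honest but wide, and it
  is the slowest-mixing fixed effect.
* Covariate augmentation degrades as missingness grows; fits warn above a
  configurable missing fraction (default 50%).
* R-hat is reported as NaN for parameters that are numerically constant
  across draws (e.g. variances pinned in degenerate designs); such
  parameters are excluded from the pass/fail decision.
* The asymptotic-size summary annualises per-month rates with the fixed
  2/10 month convention; it ignores within-year sequencing of seasons.
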