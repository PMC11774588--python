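# charrgrowth

Bayesian state-space partitioning of spatiotemporal variation in
size-dependent fish growth from capture–mark–recapture (CMR) data.

## The problem

Long-term CMR studies of fish — here, individually tagged Arctic charr
(*Salvelinus alpinus*) in ~20 small, isolated, groundwater-fed cave pools
sampled each June and August — yield intermittent records of fork length
(mm).  Two kinds of missingness frustrate a naive analysis: fish are not
captured on every occasion, and the environmental covariate (seasonal mean
water temperature per cave) has missing cells.  This package fits the joint
hierarchical model that handles both by data augmentation, then decomposes
growth variation into spatial (among caves), temporal (among years) and
spatiotemporal components, each split into size-independent, size-dependent
and temperature-associated parts.

## The model

Latent sizes evolve across consecutive occasions *t* → *t*+1 separated by
*D* days,

```
z[i,j,t+1] = z[i,j,t] + g(z[i,j,t]) · m,        m = D / (season days per month)
g(z)       = α_jt + b_jt (z − z̄) + e,           e ~ N(0, V_e,h)
```

with a linear growth function in mm/month (a summer month is 67/2 nominal
days, a winter month 298/10).  Intercepts (size-independent growth) and
slopes (size-dependent growth) carry season fixed effects, a centred
temperature effect and correlated random deviations by cave (j), year (t)
and cave×year (jt):

```
α_jt = α_h + α_hj + α_ht + α_hjt + α_hT (T_hjt − T̄)
b_jt = b_h + b_hj + b_ht + b_hjt + b_hT (T_hjt − T̄)
```

Seasonal water temperature has its own process model
`T_hjt = a_h + a_hj + a_ht + ε` with an essentially-zero observation error
that lets missing cells be augmented.  Observed lengths add fixed
measurement noise `z* = z + η`, with η² estimated separately from duplicate
field measurements.  Sizes at first capture follow `N(μ0, σ0²)`.

Everything is conditionally linear-Gaussian, so the sampler is a blocked
Gibbs scheme (conjugate normal / inverse-gamma / inverse-Wishart updates)
augmented with exact translation sweeps and collapsed Metropolis moves on
the variance components for healthy mixing.

Derived quantities (all computed per posterior draw): temperature-associated
variances via `V(a + bx) = b²V(x)`; slope variance converted to growth units
via the post-season fork-length variance σ²_fl; and proportional shares
`R = V_component / V_g` with `V_g = V_j + V_t + V_jt`.

## Worked example

`examples/` contains one short script per capability.  Estimating the
measurement-error variance from 76 fish measured twice
(`python examples/02_measurement_error.py`):

```
Bayesian intercept model : eta^2 = 0.686 mm^2 [0.501; 0.948]
method-of-moments check  : eta^2 = 0.654 mm^2
between-fish variance    : 234 mm^2
```

The within-fish variance (~0.7 mm², truth 0.6) says a typical measurement is
off by less than 1 mm, tiny next to real between-fish spread.  Fitting the
joint model on a desk-scale synthetic system
(`python examples/03_fit_growth_model.py`):

```
season                       quantity   mean   q2.5  q97.5
summer            growth_mm_per_month  4.001  2.291  5.640
summer           growth_mm_per_season  8.003  4.581 11.280
summer                slope_per_month -0.050 -0.099  0.005
winter            growth_mm_per_month  0.482 -0.388  1.227
winter                slope_per_month -0.023 -0.038 -0.009
annual                 slope_per_year -0.330 -0.513 -0.161
...
true summer growth 2.91 mm/month, slope -0.049 per mm
```

The summer intercept is the expected growth of an average-sized fish at
average temperature in mm/month (truth 2.91 inside the interval); the
negative slopes say larger fish grow less, and the annual slope sums the two
seasons (2 summer + 10 winter months).

## Command line

The same pipeline is scriptable:

```
charrgrowth simulate --preset paper-small --seed 42 --out data/
charrgrowth measurement-error --repeats data/repeats.csv --out eta.json
charrgrowth fit --captures data/captures.csv --temps data/temperatures.csv \
                --eta-sq eta.json --seed 1 --out draws/
charrgrowth derive --draws draws/ --captures data/captures.csv \
                --temps data/temperatures.csv --out variance_report.csv
charrgrowth validate --captures data/captures.csv --temps data/temperatures.csv \
                --eta-sq eta.json --rounds 5 --seed 2 --out ppc.csv
charrgrowth report --draws draws/ --captures data/captures.csv \
                --temps data/temperatures.csv --out report/
```

Exit codes: 0 success, 1 usage error, 2 validation/convergence failure.

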