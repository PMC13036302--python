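# msoccupancy

Hierarchical multispecies occupancy modelling for camera-trap surveys
comparing wildlife communities between two management areas — built for
the common monitoring question in tropical forests: does a
community-managed forest sustain the same terrestrial vertebrate
community as a strictly protected reference area, once imperfect
detection and *cryptic* human disturbance (hunting and forest-product
harvest that leave the canopy intact) are accounted for?

The package is aimed at ecologists and conservation analysts who have
camera-trap record tables and want species- and community-level
occupancy estimates, access-gradient effects, and richness posteriors
with honest uncertainty — without writing their own BUGS/JAGS code.

## The model

For species *k* at station *i* (area *a(i)*, camera feature *f(i)*,
occasion *j*), with a fixed species list of size *M* augmented by a
community-inclusion indicator:

```
w_ka  ~ Bernoulli(Omega)
z_ik  ~ Bernoulli(w_ka * psi_ki)
y_kij ~ Bernoulli(z_ik * p_kij)

logit psi_ki = beta0_ka + beta1_ka * access_i + beta2_k * canopy_i
             + beta3_k * EVI_i + beta4_k * D2W_i
             + beta5_k * slope_i + beta6_k * elev_i
logit p_kij  = alpha0_kaf + alpha1_ka * day_ij
```

Species coefficients are community random effects (area-specific means
for the occupancy intercept and access slope, feature-specific means
for detection intercepts). Area richness is `sum_k w_ka`, site richness
`sum_k z_ik`, and mean community occupancy the per-draw average of
`psi` over included species. The model is fit by a bespoke
Metropolis-within-Gibbs sampler (exact conditionals for `z`, `w`,
`Omega` and the hyper-means; slice updates for the hyper-SDs; adaptive
random-walk Metropolis for species coefficients) — see
`docs/methods.md` for priors, update order and design choices.

## Worked example

`examples/` contains one narrative script per capability. Generating a
small synthetic survey (8 species, 55 stations) and fitting it with a
reduced protocol (`examples/02_fit_community_model.py`):

```
retained draws: 1200 (2 chains x 600)
max split-Rhat over hyperparameters: 1.059 (< 1.1 indicates convergence)
mu.beta0.UAX   posterior mean -0.66 [0.81 SD]
mu.beta0.MRANP posterior mean -0.76 [1.35 SD]
mu.beta1.UAX   posterior mean +0.54 [0.61 SD]
omega          posterior mean +0.76 [0.12 SD]
generator truth: mu.beta0 = (-0.80, -0.40), mu.beta1.UAX = +0.50, omega = 0.90
```

The hyper-means are the centres of the community random-effect
distributions (logit scale): the fitted access-slope mean (+0.54)
recovers the simulated positive effect of remoteness on occupancy in
the community-managed area. Summaries of the same fit
(`examples/03_posterior_summaries.py`):

```
mean community occupancy (species-averaged psi, 85% BCI):
 area  mean  lo85  hi85  n_draws_excluded
  UAX 0.379 0.298 0.463                 0
MRANP 0.419 0.282 0.558                 0

strongest access response: sp06 in MRANP: +708% odds change per 6 h walked (Pr(slope>0) = 1.00)

area richness (sum of community-inclusion indicators):
 area  modal_richness  mean_richness  lo85  hi85
  UAX               7           7.22   7.0   8.0
MRANP               5           5.83   5.0   8.0
true community sizes: [7 6]
```

Mean community occupancy is the species-averaged probability of site
use at mean covariate values; the odds change converts the
standardized access slope back to raw walking hours; modal richness is
the posterior mode of the community size, which here brackets the
generator's truth.

A thin CLI wraps the same pipeline for shell use:

```sh
msoccupancy simulate --seed 1 --output survey/
msoccupancy fit --records survey/records.csv --stations survey/stations.csv \
    --species survey/species.csv --output fit/ --chains 3
msoccupancy summarize --draws fit/draws.npz --output tables/ --plots
msoccupancy gof --draws fit/draws.npz
```

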