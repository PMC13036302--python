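# Methods

## The model

`msoccupancy` implements a two-area community (multispecies) occupancy
model with data augmentation over a fixed species list of size *M*
(default 28). Species *k* at station *i* (in area *a(i)*, with camera
feature *f(i)*) during occasion *j* follows three Bernoulli layers:

```
w_ka  ~ Bernoulli(Omega)                      community inclusion
z_ik  ~ Bernoulli(w_ka * psi_ki)              occupancy / site use
y_kij ~ Bernoulli(z_ik * p_kij)               detection per occasion
```

with logit-linear regressions

```
logit psi_ki = beta0_ka + beta1_ka * access_i + beta2_k * canopy_i
             + beta3_k * EVI_i + beta4_k * D2W_i + beta5_k * slope_i
             + beta6_k * elev_i
logit p_kij  = alpha0_kaf + alpha1_ka * day_ij
```

Species-level coefficients are community random effects: the occupancy
intercept and access slope have area-specific means and SDs
(`beta{0,1}_ka ~ N(mu_{0,1,a}, sigma_{0,1,a})`), the five habitat
slopes are shared between areas, detection intercepts have
feature-specific means/SDs shared between areas
(`alpha0_kaf ~ N(mu_alpha0_f, sigma_alpha0_f)`), and the day
(seasonality) slope has a single community mean. A single inclusion
probability `Omega` is shared by both areas (a per-area `Omega` was
considered; the single-`Omega` form is the default because one
community-level inclusion parameter is what the standard
augmented-community construction specifies, and the areas share a
species pool).

Hyperpriors: `Omega ~ beta(0.001, 1)`; every hyper-mean is
`N(0, 0.2)` read in the JAGS convention as a **precision** (SD
`sqrt(5) ~ 2.236`; `PriorConfig(mean_spread_is_precision=False)`
switches to the SD reading); every hyper-SD is uniform on (0, 5].

All six site covariates and the occasion day covariate are standardized
by the pooled (both-areas) mean and SD. Reported occupancy "at mean
covariate values" is therefore `logit^-1(beta0)`.

## Detection histories

Records are collapsed to binary detection/non-detection per 3-day
occasion. Occasions tile each deployment window from its start date; a
trailing partial occasion (deployment length not divisible by 3) is
**retained** and flagged, and detection probability is not
effort-adjusted within an occasion — the model treats every active
occasion as exchangeable, so dropping partial occasions would discard
data without a compensating benefit. The occasion-level seasonality
covariate is the Julian day (day of year) of the occasion's first day:
a deterministic, resolution-matched choice given that detections are
only known to the occasion. Records of species not on the fixed list
are dropped with a logged count (the species list is an a-priori
modelling choice, not a data property); records outside a station's
deployment window are dropped and counted.

## Sampler

The posterior is sampled by Metropolis-within-Gibbs
(`msoccupancy.sampler`):

* `z` and `w` — exact Bernoulli full conditionals. `w` uses the
  partially collapsed form, marginalizing `z` out of each species'
  all-zero histories (`L1 = prod_i [psi_i prod_j (1-p_ij) + 1-psi_i]`),
  immediately followed by a full `z` refresh, which together form a
  valid block update.
* species coefficients — Gaussian random-walk Metropolis per scalar,
  vectorized across species. Area-disjoint blocks (intercepts, access
  slope, detection parameters) are proposed jointly and accepted per
  scalar because their likelihood terms touch disjoint stations; the
  habitat slopes share all stations and are updated one covariate at a
  time. Proposal SDs adapt toward 0.44 acceptance during the adaptation
  phase (Robbins-Monro step `min(0.2, 1/sqrt(t))`, scales clipped to
  [1e-3, 10]) and are frozen afterwards to preserve detailed balance.
* hyper-means — conjugate normal draws; hyper-SDs — slice sampling with
  stepping-out on (0, 5]; `Omega` — conjugate
  `beta(0.001 + sum w, 1 + 2M - sum w)`.

The default protocol is 3 chains, 15,000 adaptation iterations
(discarded as burn-in), 150,000 sampling iterations thinned by 20 —
3 x 7,500 = 22,500 retained draws. Adaptation is counted **outside**
the sampling iterations (the jagsUI convention), which is what makes
the retained-draw arithmetic come out to `n_iter / thin` per chain.
One master seed spawns independent per-chain streams
(`numpy.random.SeedSequence`); identical seeds give bit-identical
draws. Convergence is monitored with the split-chain Gelman-Rubin
statistic (computed via `arviz`, method `"split"`); constant chains are
reported as 1.0 with a zero-variance flag, and parameters at or above
1.1 are flagged.

Stations with zero active occasions contribute occupancy terms only
through `z`'s prior; they drop out of the detection likelihood but stay
in the `psi` terms. A non-finite starting density triggers
re-initialization with jitter (at most 10 attempts).

One numerical subtlety: the beta(0.001, 1) inclusion prior is so
heavily concentrated at 0 that roughly half of its mass lies below the
smallest positive double. `Omega` draws are therefore clipped only at
the floating-point representable limits (5e-324, 1 - 1e-16) — enough
to keep `log(Omega)` and `log(1 - Omega)` finite without distorting
the distribution at any representable value.

The three hot likelihood reductions (detection and occupancy Bernoulli
sums at the current and proposed parameter point, and the per-site
`log prod_j (1-p)` term) are compiled with numba when available; pure
numpy fallbacks compute the same quantities and the test suite checks
their agreement.

## Goodness of fit

Posterior-predictive fit uses the Freeman-Tukey discrepancy
`T(y) = sum_ki (sqrt(y_ki.) - sqrt(E_ki))^2` on detection totals per
species x station, with `E_ki = z_ik sum_j p_kij` conditional on the
sampled occupancy state, and a replicate detection table drawn from the
same `(z, p)` at every retained draw; the Bayesian p-value is
`Pr(T(y_rep) >= T(y))` with ties counted as extreme. The expected
counts condition on the sampled `z` (the aggregation level follows
common occupancy-model practice). Note that conditioning on a latent
state that was itself updated from the data makes the p-value's
distribution over replicate surveys wider than for pivotal quantities,
so values in roughly the 0.3-0.6 range are typical for well-specified
fits at this survey size; the package also exposes the per-draw
discrepancy pair for custom checks.

## Posterior summaries

* Equal-tailed quantile intervals at 66% and 85% (matching
  jagsUI-style summaries; not HPD).
* Access odds change per 6 walking hours:
  `exp(beta1_bar * 6 / SD_access) - 1` from the posterior-mean slope
  (the headline single percentage), with the full odds-ratio posterior
  summarized alongside. The formulation is in raw hours, so it is
  invariant to how access was standardized.
* `Pr(psi_MRANP > psi_UAX)` at mean covariates, ties split 50/50
  (unbiased under exchangeability); classified higher/lower at
  0.60/0.40.
* Covariate contrasts: occupancy at each covariate's observed maximum
  minus at its minimum, others at their means. Access (area-specific
  slope) uses the area's own observed range; habitat covariates
  (shared slopes) use the pooled range. A dominance flag records
  whether the absolute access effect exceeds every habitat effect.
* Richness: site richness per draw is `sum_k z_ik`; area richness is
  `sum_k w_ka`; the reported "modal richness" is the posterior mode
  with ties broken toward the smaller value (a conservative count).
* Richness vs access: a descriptive per-area OLS slope of posterior
  mean site richness on walking hours with a percentile bootstrap over
  stations — deliberately not a model component.
* Species with fewer than 10 raw detections in an area are flagged
  "not reportable" (their posteriors are prior-dominated) but are never
  dropped from fitting.
* Mean community occupancy averages `psi` over the species included in
  the area's community in each draw (`w = 1`); draws with an empty
  community are excluded with a logged count.

## Synthetic surveys

The generator (`msoccupancy.synthetic`) produces surveys with the exact
structure the model assumes, plus a truth record for recovery tests.
Default study conditions: 28 species; 188 + 138 stations; access
spanning 0.5-16.5 walking hours in the community-managed area and
8.8-25.3 h in the protected area, stratified into four equal-quota
bands (emulating hexagon-stratified sampling — hexagon geometry itself
is not modelled because spatial coordinates never enter the
likelihood); equal road/water/forest proportions; deployment lengths
uniform on 21-25 days; one field season per area in different years
(year and area are confounded by design, as in the survey the package
emulates, and no year effect is modelled). True hyperparameters default
to `mu_beta0 = (-0.8, -0.4)` (mean community occupancy ~0.35-0.45),
feature-ordered detection intercepts `(-1.2, -1.4, -1.8)` (per-occasion
detection ~0.1-0.3, roads > waterholes > forest), a positive access
effect stronger in the community-managed area
(`mu_beta1 = (0.5, 0.25)`), a mild canopy effect, and `Omega = 0.9`.
Habitat covariates are drawn independently from realistic marginal
distributions; real surveys have correlated covariates and
non-ignorable station placement, so passing recovery tests demonstrates
correctness of the estimator under the model's own assumptions, not
robustness to misspecification. Detection timestamps are uniform
within their occasion (only occasion membership matters downstream),
and every detection emits a record so ingest is exercised end to end.

## Test and acceptance problem sizes

The test suite verifies exact conditionals and likelihood oracles at
enumerable sizes, and calibration properties at a reduced protocol
chosen to keep a full run on one CPU short: parameter recovery fits use
the default 326-station survey with 3 chains x 10,000 iterations
(1,000 adaptation, thin 10) over 3 simulation replicates, pooling 39
hyper-mean credible intervals for the coverage check; the goodness-of-
fit calibration check averages the p-value over those same fits; prior
recovery uses a fully effort-masked survey so every update targets its
prior. The acceptance script fits 3 chains x 4,000 iterations (800
adaptation, thin 10) on the default survey. The full production
protocol (3 x 150,000, thin 20) is available unchanged through
`McmcConfig()` defaults.

## Known limitations

* Single-season (closed) occupancy only; no spatial autocorrelation,
  false-positive detections, or abundance-induced detection
  heterogeneity.
* The access covariate is consumed as a station attribute; computing
  travel-time cost surfaces is out of scope.
* The headline odds-change percentage uses the posterior mean of the
  access slope; for strongly skewed slopes the posterior median of the
  odds ratio (also emitted) is the safer summary.
* Guild/hunted metadata are carried as labels only; no trophic-guild
  meta-analysis is performed.
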