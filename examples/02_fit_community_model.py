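"""Fit the community occupancy model to a synthetic survey.

Runs a reduced Metropolis-within-Gibbs protocol (2 chains rather than
the full 3 x 150,000-iteration production protocol) and prints
convergence diagnostics and the community-level posterior.
"""

import msoccupancy as mo

config = mo.ScenarioConfig(n_species=8, stations_per_area=(30, 25), seed=1)
survey = mo.simulate_survey(config)
data = mo.assemble_model_data(survey.stations, survey.detection)

draws = mo.run_mcmc(data, mo.McmcConfig(
    n_chains=2, n_iter=3000, n_adapt=600, thin=5, seed=1))
print(f"retained draws: {draws.n_total} "
      f"({draws.n_chains} chains x {draws.n_draws})")

rtab = mo.rhat(draws, include_species=False)
print(f"max split-Rhat over hyperparameters: {rtab['rhat'].max():.3f} "
      f"(< 1.1 indicates convergence)")

# community hyperparameters: the means of the random-effect
# distributions from which species coefficients are drawn
flat = draws.flat_params(include_species=False)
for name in ("mu.beta0.UAX", "mu.beta0.MRANP", "mu.beta1.UAX", "omega"):
    arr = flat[name].ravel()
    print(f"{name:14s} posterior mean {arr.mean():+.2f} "
          f"[{arr.std():.2f} SD]")
truth = survey.truth.hypers
print(f"generator truth: mu.beta0 = ({truth.mu_beta0[0]:+.2f}, "
      f"{truth.mu_beta0[1]:+.2f}), mu.beta1.UAX = {truth.mu_beta1[0]:+.2f}, "
      f"omega = {truth.omega:.2f}")
# The occupancy-intercept means set each area's typical species
# occupancy on the logit scale; omega is the probability a species
# list member belongs to an area's community.
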