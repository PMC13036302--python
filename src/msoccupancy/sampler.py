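"""Metropolis-within-Gibbs sampler for the community occupancy model.

Update scheme per sweep:

* ``w`` — exact Bernoulli full conditional with the occupancy states of
  undetected species marginalized out (a partially collapsed update),
  immediately followed by
* ``z`` — exact Bernoulli full conditional given ``w``,
* species-level coefficients — Gaussian random-walk Metropolis on each
  scalar, vectorized across species, with proposal scales adapted
  toward 0.44 acceptance during the adaptation phase and frozen after,
* hyper-means — conjugate normal draws,
* hyper-SDs — slice sampling on (0, sigma_upper],
* ``Omega`` — conjugate beta draw given ``w``.

The adaptation phase doubles as burn-in and is discarded; thinning is
applied to the sampling iterations only, so the default protocol
(3 chains x 150,000 sampling iterations, 15,000 adaptation, thin 20)
retains 3 x 7,500 = 22,500 draws.

A Freeman-Tukey discrepancy pair (observed and replicated) is computed
at every retained draw so posterior-predictive goodness of fit costs no
extra pass over the chain.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from ._kernels import det_ll_pair, log_q0, occ_ll_pair
from .ingest import ModelData, StandardizationParams
from .model import (
    AREAS,
    FEATURES,
    N_AREAS,
    N_FEATURES,
    N_HABITAT,
    CommunityHyperparams,
    LatentState,
    PriorConfig,
    SpeciesParams,
    detection_logits,
    log_complete_likelihood,
    occupancy_logits,
)

logger = logging.getLogger(__name__)

_SPECIES_BLOCKS = ("beta0", "beta1", "beta_habitat", "alpha0", "alpha1")


@dataclass
class McmcConfig:
    """MCMC protocol.

    ``n_iter`` counts post-adaptation sampling iterations per chain (the
    jagsUI convention: adaptation is extra and discarded), so retained
    draws per chain = ``n_iter // thin``.
    """

    n_chains: int = 3
    n_iter: int = 150_000
    n_adapt: int = 15_000
    thin: int = 20
    seed: int = 0
    target_accept: float = 0.44
    prop_sd_init: float = 0.3
    prop_sd_bounds: tuple = (1e-3, 10.0)

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_iter < 1 or self.n_adapt < 0:
            raise ValueError("iteration counts must be positive")
        if not self.prop_sd_init > 0:
            raise ValueError("proposal SD must be > 0")
        lo, hi = self.prop_sd_bounds
        if not (0 < lo < hi):
            raise ValueError("proposal-scale bounds must satisfy 0 < lo < hi")

    @property
    def n_retained_per_chain(self) -> int:
        return self.n_iter // self.thin


def n_retained(config: McmcConfig) -> int:
    """Total retained draws across chains under the given protocol."""
    return config.n_chains * config.n_retained_per_chain


@dataclass
class PosteriorDraws:
    """Thinned multi-chain draws keyed by parameter block.

    ``params`` maps block names to arrays of shape (chain, draw, ...):
    species blocks beta0/beta1 (K, 2), beta_habitat (K, 5), alpha0
    (K, 2, 3), alpha1 (K, 2); hyper blocks mu.beta0/sigma.beta0 (2,),
    mu.habitat/sigma.habitat (5,), mu.alpha0/sigma.alpha0 (3,),
    mu.alpha1/sigma.alpha1/omega (scalar); latent block w (K, 2).
    ``site_richness`` holds the per-draw species sums over z.
    """

    params: dict
    site_richness: np.ndarray  # (C, D, I)
    ft_obs: np.ndarray         # (C, D)
    ft_rep: np.ndarray         # (C, D)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.params["omega"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.params["omega"].shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_draws

    @property
    def species_index(self) -> list:
        return list(self.meta["species_index"])

    def stacked(self, name: str) -> np.ndarray:
        """Block with chains concatenated: shape (C*D, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def flat_params(self, include_species: bool = True) -> dict:
        """Scalar parameter name -> (chain, draw) array."""
        out = {}
        for a, area in enumerate(AREAS):
            out[f"mu.beta0.{area}"] = self.params["mu.beta0"][:, :, a]
            out[f"sigma.beta0.{area}"] = self.params["sigma.beta0"][:, :, a]
            out[f"mu.beta1.{area}"] = self.params["mu.beta1"][:, :, a]
            out[f"sigma.beta1.{area}"] = self.params["sigma.beta1"][:, :, a]
        for m in range(N_HABITAT):
            out[f"mu.beta{m + 2}"] = self.params["mu.habitat"][:, :, m]
            out[f"sigma.beta{m + 2}"] = self.params["sigma.habitat"][:, :, m]
        for f, feat in enumerate(FEATURES):
            out[f"mu.alpha0.{feat}"] = self.params["mu.alpha0"][:, :, f]
            out[f"sigma.alpha0.{feat}"] = self.params["sigma.alpha0"][:, :, f]
        out["mu.alpha1"] = self.params["mu.alpha1"]
        out["sigma.alpha1"] = self.params["sigma.alpha1"]
        out["omega"] = self.params["omega"]
        if include_species:
            sp = self.species_index
            for k, s in enumerate(sp):
                for a, area in enumerate(AREAS):
                    out[f"beta0.{s}.{area}"] = self.params["beta0"][:, :, k, a]
                    out[f"beta1.{s}.{area}"] = self.params["beta1"][:, :, k, a]
                    out[f"alpha1.{s}.{area}"] = self.params["alpha1"][:, :, k, a]
                    for f, feat in enumerate(FEATURES):
                        out[f"alpha0.{s}.{area}.{feat}"] = \
                            self.params["alpha0"][:, :, k, a, f]
                for m in range(N_HABITAT):
                    out[f"beta{m + 2}.{s}"] = \
                        self.params["beta_habitat"][:, :, k, m]
        return out


HYPER_MEAN_NAMES = tuple(
    [f"mu.beta0.{a}" for a in AREAS]
    + [f"mu.beta1.{a}" for a in AREAS]
    + [f"mu.beta{m + 2}" for m in range(N_HABITAT)]
    + [f"mu.alpha0.{f}" for f in FEATURES]
    + ["mu.alpha1"]
)


# ---------------------------------------------------------------------------
# state initialization


def init_state(data: ModelData, rng: np.random.Generator):
    """Initial (params, hypers, latent) honouring the data constraints.

    z starts at the observed-detection maxima; w is 1 wherever a species
    was observed in an area and Bernoulli(0.5) otherwise; coefficients
    and hyper-means start at 0, hyper-SDs at 1, Omega at 0.5.
    """
    K, I = data.n_species, data.n_stations
    params = SpeciesParams.zeros(K)
    hypers = CommunityHyperparams.default_init()

    det_any = (data.y.astype(bool) & data.active[None]).any(axis=2)
    det_any_area = np.zeros((K, N_AREAS), dtype=bool)
    for a in range(N_AREAS):
        det_any_area[:, a] = det_any[:, data.area_idx == a].any(axis=1)

    w = np.where(det_any_area, 1,
                 rng.random((K, N_AREAS)) < 0.5).astype(np.int8)
    z = det_any.astype(np.int8)
    z[(w[:, data.area_idx] == 0)] = 0  # w=0 forces z=0; detections force w=1
    return params, hypers, LatentState(z=z, w=w)


# ---------------------------------------------------------------------------
# scalar slice sampler (for hyper-SDs)


def slice_sample(logf: Callable[[float], float], x0: float,
                 rng: np.random.Generator, lower: float, upper: float,
                 width: float = 0.5, max_steps: int = 50) -> float:
    """Univariate slice sampler with stepping out on bounded support."""
    height = logf(x0) - rng.exponential(1.0)
    u = rng.random()
    left = x0 - width * u
    right = left + width
    steps = max_steps
    while left > lower and logf(max(left, lower + 1e-12)) > height and steps:
        left -= width
        steps -= 1
    steps = max_steps
    while right < upper and logf(min(right, upper)) > height and steps:
        right += width
        steps -= 1
    left = max(left, lower + 1e-12)
    right = min(right, upper)
    while True:
        x1 = left + rng.random() * (right - left)
        if logf(x1) > height:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def sample_omega(w: np.ndarray, prior: PriorConfig,
                 rng: np.random.Generator) -> float:
    """Conjugate draw Omega | w ~ beta(a + sum w, b + n - sum w).

    Clipped only at the floating-point representable limits: the
    default beta(0.001, 1) prior is extreme enough that draws underflow
    to exact 0, and the latent-state updates need log(Omega) and
    log(1 - Omega) finite.
    """
    s = float(np.sum(w))
    n = w.size
    val = rng.beta(prior.omega_shape1 + s, prior.omega_shape2 + n - s)
    return float(np.clip(val, 5e-324, 1.0 - 1e-16))


def _norm_lpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)


# ---------------------------------------------------------------------------
# the sampler


class GibbsSampler:
    """Single-chain sampler state and update kernels.

    Holds the data-dependent constants (detection maxima, one-hot
    grouping matrices) plus the current parameter/latent state.  All
    kernels mutate the state in place and are vectorized across species.
    """

    def __init__(self, data: ModelData, config: McmcConfig | None = None,
                 prior: PriorConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.data = data
        self.config = config or McmcConfig()
        self.prior = prior or PriorConfig()
        self.rng = rng or np.random.default_rng()

        K, I = data.n_species, data.n_stations
        self.K, self.I = K, I
        a_idx, f_idx = data.area_idx, data.feature_idx
        self._active_f = data.active.astype(float)
        self._eff = np.ascontiguousarray(data.active)
        self._day = np.ascontiguousarray(data.day_std, dtype=float)
        self._y_f = np.ascontiguousarray(
            data.y.astype(float) * self._active_f[None])
        self.y_tot = self._y_f.sum(axis=2)  # (K, I)
        self.det_any = self.y_tot > 0
        self.det_any_area = np.zeros((K, N_AREAS), dtype=bool)
        self._area_group = np.ascontiguousarray(a_idx, dtype=np.int64)
        self._af_group = np.ascontiguousarray(
            a_idx * N_FEATURES + f_idx, dtype=np.int64)
        self._area_onehot = np.zeros((I, N_AREAS))
        self._area_onehot[np.arange(I), a_idx] = 1.0
        for a in range(N_AREAS):
            self.det_any_area[:, a] = self.det_any[:, a_idx == a].any(axis=1)

        self.params, self.hypers, self.latent = init_state(data, self.rng)
        bounds = self.config.prop_sd_bounds
        self._lsd_bounds = (np.log(bounds[0]), np.log(bounds[1]))
        init_lsd = np.log(self.config.prop_sd_init)
        self._lsd = {
            "beta0": np.full((K, N_AREAS), init_lsd),
            "beta1": np.full((K, N_AREAS), init_lsd),
            "beta_habitat": np.full((K, N_HABITAT), init_lsd),
            "alpha0": np.full((K, N_AREAS, N_FEATURES), init_lsd),
            "alpha1": np.full((K, N_AREAS), init_lsd),
        }
        self._adapt_t = 0
        self._acc = {name: 0.0 for name in _SPECIES_BLOCKS}
        self._acc_n = {name: 0 for name in _SPECIES_BLOCKS}

    # -- latent updates ----------------------------------------------------

    def _det_site_terms(self):
        """Detection logits decomposed as a0_site + a1_site * day."""
        a0s = np.ascontiguousarray(
            self.params.alpha0[:, self.data.area_idx, self.data.feature_idx])
        a1s = np.ascontiguousarray(self.params.alpha1[:, self.data.area_idx])
        return a0s, a1s

    def _latent_arrays(self):
        """(psi logits, log psi, log 1-psi, log prod_j (1-p)) as (K, I)."""
        d = self.data
        psi_l = occupancy_logits(self.params, d.X, d.area_idx)
        a0s, a1s = self._det_site_terms()
        lq0 = log_q0(self._eff, a0s, a1s, self._day)
        return psi_l, log_expit(psi_l), log_expit(-psi_l), lq0

    def update_z(self, rng=None, _arrays=None) -> LatentState:
        """Exact conditional: z=1 at detections, 0 where w=0, else
        Bernoulli(psi q0 / (psi q0 + 1 - psi)) with q0 = prod (1-p)."""
        rng = rng or self.rng
        _, log_psi, log_1mpsi, log_q0 = _arrays or self._latent_arrays()
        a = log_psi + log_q0
        p1 = np.exp(a - np.logaddexp(a, log_1mpsi))
        z = (rng.random((self.K, self.I)) < p1).astype(np.int8)
        z[self.det_any] = 1
        z[self.latent.w[:, self.data.area_idx] == 0] = 0
        self.latent.z = z
        return self.latent

    def update_w(self, rng=None, _arrays=None) -> LatentState:
        """Collapsed conditional: w=1 where the species was detected in
        the area, else Bernoulli(Omega L1 / (Omega L1 + 1 - Omega)) with
        z marginalized out of the all-zero histories."""
        rng = rng or self.rng
        _, log_psi, log_1mpsi, log_q0 = _arrays or self._latent_arrays()
        m = np.logaddexp(log_psi + log_q0, log_1mpsi)  # (K, I)
        logL1 = m @ self._area_onehot  # (K, 2)
        omega = self.hypers.omega
        eta = np.log(omega) - np.log1p(-omega) + logL1
        w = (rng.random((self.K, N_AREAS)) < expit(eta)).astype(np.int8)
        w[self.det_any_area] = 1
        self.latent.w = w
        return self.latent

    def update_latent(self, rng=None) -> LatentState:
        """w then z from one set of likelihood arrays (the valid pair)."""
        rng = rng or self.rng
        arrays = self._latent_arrays()
        self.update_w(rng, _arrays=arrays)
        self.update_z(rng, _arrays=arrays)
        return self.latent

    # -- coefficient updates ----------------------------------------------

    def _mh_accept(self, name, cur_ll, new_ll, dprior, rng, adapt):
        log_r = new_ll - cur_ll + dprior
        acc = np.log(rng.random(log_r.shape)) < log_r
        if adapt:
            self._adapt_t += 1
            delta = min(0.2, 1.0 / np.sqrt(self._adapt_t))
            lsd = self._lsd[name]
            lsd += delta * (acc.astype(float) - self.config.target_accept)
            np.clip(lsd, *self._lsd_bounds, out=lsd)
        else:
            self._acc[name] += float(acc.mean())
            self._acc_n[name] += 1
        return acc

    def update_coefficients(self, rng=None, adapt: bool = False):
        """Random-walk Metropolis on every species-level coefficient.

        Area-disjoint blocks (beta0, beta1, alpha0, alpha1) are proposed
        jointly and accepted per scalar since their likelihood terms
        touch disjoint station sets; habitat slopes share all stations
        and are updated one covariate at a time.
        """
        rng = rng or self.rng
        d = self.data
        p, h = self.params, self.hypers
        a_idx = d.area_idx
        z = np.ascontiguousarray(self.latent.z)
        eligible = np.ascontiguousarray(self.latent.w[:, a_idx])
        no_group = np.zeros(self.I, dtype=np.int64)

        # occupancy intercept and access slope (area-disjoint blocks)
        for name, block, mu, sd, mult in (
            ("beta0", p.beta0, h.mu_beta0, h.sigma_beta0, None),
            ("beta1", p.beta1, h.mu_beta1, h.sigma_beta1, d.X[:, 0]),
        ):
            cur_psi = occupancy_logits(p, d.X, a_idx)
            eps = rng.standard_normal(block.shape) * np.exp(self._lsd[name])
            shift = eps[:, a_idx] if mult is None else eps[:, a_idx] * mult
            cur, new = occ_ll_pair(z, eligible, cur_psi, cur_psi + shift,
                                   self._area_group, N_AREAS)
            dprior = (_norm_lpdf(block + eps, mu, sd)
                      - _norm_lpdf(block, mu, sd))
            acc = self._mh_accept(name, cur, new, dprior, rng, adapt)
            block += np.where(acc, eps, 0.0)

        # shared habitat slopes, one covariate at a time
        for m in range(N_HABITAT):
            cur_psi = occupancy_logits(p, d.X, a_idx)
            eps = rng.standard_normal(self.K) * np.exp(
                self._lsd["beta_habitat"][:, m])
            new_psi = cur_psi + eps[:, None] * d.X[:, 1 + m][None, :]
            cur, new = occ_ll_pair(z, eligible, cur_psi, new_psi, no_group, 1)
            col = p.beta_habitat[:, m]
            dprior = (_norm_lpdf(col + eps, h.mu_habitat[m], h.sigma_habitat[m])
                      - _norm_lpdf(col, h.mu_habitat[m], h.sigma_habitat[m]))
            log_r = new[:, 0] - cur[:, 0] + dprior
            acc = np.log(rng.random(self.K)) < log_r
            if adapt:
                self._adapt_t += 1
                delta = min(0.2, 1.0 / np.sqrt(self._adapt_t))
                lsd = self._lsd["beta_habitat"][:, m]
                lsd += delta * (acc.astype(float) - self.config.target_accept)
                np.clip(lsd, *self._lsd_bounds, out=lsd)
            else:
                self._acc["beta_habitat"] += float(acc.mean())
                self._acc_n["beta_habitat"] += 1
            col += np.where(acc, eps, 0.0)

        # detection intercepts (area x feature blocks are site-disjoint)
        a0s, a1s = self._det_site_terms()
        eps = rng.standard_normal(p.alpha0.shape) * np.exp(self._lsd["alpha0"])
        a0n = a0s + eps[:, a_idx, d.feature_idx]
        cur, new = det_ll_pair(self._y_f, self._eff, z, a0s, a0n, a1s, a1s,
                               self._day, self._af_group,
                               N_AREAS * N_FEATURES)
        mu = np.broadcast_to(h.mu_alpha0, (N_AREAS, N_FEATURES))
        sd = np.broadcast_to(h.sigma_alpha0, (N_AREAS, N_FEATURES))
        dprior = (_norm_lpdf(p.alpha0 + eps, mu, sd)
                  - _norm_lpdf(p.alpha0, mu, sd))
        acc = self._mh_accept(
            "alpha0", cur.reshape(self.K, N_AREAS, N_FEATURES),
            new.reshape(self.K, N_AREAS, N_FEATURES), dprior, rng, adapt)
        p.alpha0 += np.where(acc, eps, 0.0)

        # detection day slope (area-disjoint)
        a0s, a1s = self._det_site_terms()
        eps = rng.standard_normal(p.alpha1.shape) * np.exp(self._lsd["alpha1"])
        a1n = a1s + eps[:, a_idx]
        cur, new = det_ll_pair(self._y_f, self._eff, z, a0s, a0s, a1s, a1n,
                               self._day, self._area_group, N_AREAS)
        dprior = (_norm_lpdf(p.alpha1 + eps, h.mu_alpha1, h.sigma_alpha1)
                  - _norm_lpdf(p.alpha1, h.mu_alpha1, h.sigma_alpha1))
        acc = self._mh_accept("alpha1", cur, new, dprior, rng, adapt)
        p.alpha1 += np.where(acc, eps, 0.0)
        return self.params

    # -- hyperparameter updates -------------------------------------------

    def _update_group(self, values, rng):
        """Conjugate mu draw then slice-sampled sigma for one group."""
        x = np.asarray(values, dtype=float).ravel()
        n = x.size
        v0 = self.prior.mean_sd ** 2

        def draw(mu, sigma):
            var = 1.0 / (1.0 / v0 + n / sigma ** 2)
            mean = var * (x.sum() / sigma ** 2 + self.prior.mean_loc / v0)
            mu_new = rng.normal(mean, np.sqrt(var))
            ss = float(((x - mu_new) ** 2).sum())

            def logf(s):
                return -n * np.log(s) - ss / (2.0 * s * s)

            sigma_new = slice_sample(logf, sigma, rng, 0.0,
                                     self.prior.sigma_upper)
            return mu_new, sigma_new

        return draw

    def update_hypers_and_omega(self, rng=None):
        rng = rng or self.rng
        p, h = self.params, self.hypers
        for a in range(N_AREAS):
            h.mu_beta0[a], h.sigma_beta0[a] = self._update_group(
                p.beta0[:, a], rng)(h.mu_beta0[a], h.sigma_beta0[a])
            h.mu_beta1[a], h.sigma_beta1[a] = self._update_group(
                p.beta1[:, a], rng)(h.mu_beta1[a], h.sigma_beta1[a])
        for m in range(N_HABITAT):
            h.mu_habitat[m], h.sigma_habitat[m] = self._update_group(
                p.beta_habitat[:, m], rng)(h.mu_habitat[m], h.sigma_habitat[m])
        for f in range(N_FEATURES):
            h.mu_alpha0[f], h.sigma_alpha0[f] = self._update_group(
                p.alpha0[:, :, f], rng)(h.mu_alpha0[f], h.sigma_alpha0[f])
        h.mu_alpha1, h.sigma_alpha1 = self._update_group(
            p.alpha1, rng)(h.mu_alpha1, h.sigma_alpha1)
        h.omega = sample_omega(self.latent.w, self.prior, rng)
        return self.hypers

    # -- sweep and goodness-of-fit ----------------------------------------

    def sweep(self, adapt: bool = False):
        self.update_latent()
        self.update_coefficients(adapt=adapt)
        self.update_hypers_and_omega()

    def freeman_tukey_pair(self, rng=None):
        """(T_obs, T_rep): Freeman-Tukey discrepancy of the observed and
        of a replicated detection table at the current draw, aggregated
        at species x site level conditional on the sampled z."""
        rng = rng or self.rng
        d = self.data
        p_l = detection_logits(self.params, d.day_std, d.area_idx,
                               d.feature_idx)
        pdet = expit(p_l) * self._active_f[None]
        z = self.latent.z.astype(float)
        E = z * pdet.sum(axis=2)
        t_obs = float(((np.sqrt(self.y_tot) - np.sqrt(E)) ** 2).sum())
        y_rep = (rng.random(p_l.shape) < pdet) & (z[:, :, None] > 0)
        rep_tot = y_rep.sum(axis=2)
        t_rep = float(((np.sqrt(rep_tot) - np.sqrt(E)) ** 2).sum())
        return t_obs, t_rep

    def acceptance_rates(self) -> dict:
        return {
            name: (self._acc[name] / self._acc_n[name]
                   if self._acc_n[name] else np.nan)
            for name in _SPECIES_BLOCKS
        }


# ---------------------------------------------------------------------------
# multi-chain orchestration


def _run_chain(data: ModelData, config: McmcConfig, prior: PriorConfig,
               seed_seq: np.random.SeedSequence, store: dict, chain: int):
    rng = np.random.default_rng(seed_seq)
    sampler = GibbsSampler(data, config, prior, rng)

    # guard against a non-finite starting density (re-init with jitter)
    for attempt in range(10):
        ll = log_complete_likelihood(sampler.params, sampler.latent,
                                     sampler.hypers, data)
        if np.isfinite(ll):
            break
        sampler.params.beta0 += rng.normal(0, 0.1, sampler.params.beta0.shape)
        sampler.params, sampler.hypers, sampler.latent = (
            sampler.params, sampler.hypers, init_state(data, rng))
    else:
        raise RuntimeError("could not find a finite starting state")

    for _ in range(config.n_adapt):
        sampler.sweep(adapt=True)
    draw = 0
    for it in range(config.n_iter):
        sampler.sweep(adapt=False)
        if (it + 1) % config.thin == 0:
            p, h, lat = sampler.params, sampler.hypers, sampler.latent
            store["beta0"][chain, draw] = p.beta0
            store["beta1"][chain, draw] = p.beta1
            store["beta_habitat"][chain, draw] = p.beta_habitat
            store["alpha0"][chain, draw] = p.alpha0
            store["alpha1"][chain, draw] = p.alpha1
            store["mu.beta0"][chain, draw] = h.mu_beta0
            store["sigma.beta0"][chain, draw] = h.sigma_beta0
            store["mu.beta1"][chain, draw] = h.mu_beta1
            store["sigma.beta1"][chain, draw] = h.sigma_beta1
            store["mu.habitat"][chain, draw] = h.mu_habitat
            store["sigma.habitat"][chain, draw] = h.sigma_habitat
            store["mu.alpha0"][chain, draw] = h.mu_alpha0
            store["sigma.alpha0"][chain, draw] = h.sigma_alpha0
            store["mu.alpha1"][chain, draw] = h.mu_alpha1
            store["sigma.alpha1"][chain, draw] = h.sigma_alpha1
            store["omega"][chain, draw] = h.omega
            store["w"][chain, draw] = lat.w
            store["site_richness"][chain, draw] = lat.z.sum(axis=0)
            t_obs, t_rep = sampler.freeman_tukey_pair()
            store["ft_obs"][chain, draw] = t_obs
            store["ft_rep"][chain, draw] = t_rep
            draw += 1
    return sampler.acceptance_rates()


def run_mcmc(data: ModelData, config: McmcConfig | None = None,
             prior: PriorConfig | None = None) -> PosteriorDraws:
    """Fit the model: independent chains, adaptation discarded, thinned.

    Returns PosteriorDraws with all parameter blocks, the inclusion
    matrix w, per-draw site richness, and the Freeman-Tukey discrepancy
    pair per retained draw.  Fully reproducible from ``config.seed``.
    """
    config = config or McmcConfig()
    prior = prior or PriorConfig()
    C = config.n_chains
    D = config.n_retained_per_chain
    K, I = data.n_species, data.n_stations
    if D < 1:
        raise ValueError("protocol retains no draws (n_iter < thin)")

    store = {
        "beta0": np.empty((C, D, K, N_AREAS)),
        "beta1": np.empty((C, D, K, N_AREAS)),
        "beta_habitat": np.empty((C, D, K, N_HABITAT)),
        "alpha0": np.empty((C, D, K, N_AREAS, N_FEATURES)),
        "alpha1": np.empty((C, D, K, N_AREAS)),
        "mu.beta0": np.empty((C, D, N_AREAS)),
        "sigma.beta0": np.empty((C, D, N_AREAS)),
        "mu.beta1": np.empty((C, D, N_AREAS)),
        "sigma.beta1": np.empty((C, D, N_AREAS)),
        "mu.habitat": np.empty((C, D, N_HABITAT)),
        "sigma.habitat": np.empty((C, D, N_HABITAT)),
        "mu.alpha0": np.empty((C, D, N_FEATURES)),
        "sigma.alpha0": np.empty((C, D, N_FEATURES)),
        "mu.alpha1": np.empty((C, D)),
        "sigma.alpha1": np.empty((C, D)),
        "omega": np.empty((C, D)),
        "w": np.empty((C, D, K, N_AREAS), dtype=np.int8),
        "site_richness": np.empty((C, D, I), dtype=np.int16),
        "ft_obs": np.empty((C, D)),
        "ft_rep": np.empty((C, D)),
    }
    seed_seqs = np.random.SeedSequence(config.seed).spawn(C)
    acceptance = []
    for chain, seq in enumerate(seed_seqs):
        logger.info("running chain %d/%d", chain + 1, C)
        acceptance.append(_run_chain(data, config, prior, seq, store, chain))

    det_counts = np.zeros((K, N_AREAS), dtype=int)
    y_tot = (data.y.astype(int) * data.active[None]).sum(axis=2)
    for a in range(N_AREAS):
        det_counts[:, a] = y_tot[:, data.area_idx == a].sum(axis=1)

    site_richness = store.pop("site_richness")
    ft_obs = store.pop("ft_obs")
    ft_rep = store.pop("ft_rep")
    meta = {
        "config": asdict(config),
        "prior": asdict(prior),
        "seed": config.seed,
        "species_index": list(data.species_index),
        "station_index": list(data.detection.station_index),
        "area_idx": data.area_idx.copy(),
        "access_raw": data.design.access_raw.copy(),
        "standardization": data.design.standardization,
        "cov_range_std": {k: np.asarray(v)
                          for k, v in data.design.cov_range_std.items()},
        "det_counts": det_counts,
        "acceptance": acceptance,
    }
    draws = PosteriorDraws(params=store, site_richness=site_richness,
                           ft_obs=ft_obs, ft_rep=ft_rep, meta=meta)
    for name in _SPECIES_BLOCKS + ("omega",):
        if not np.all(np.isfinite(draws.params[name])):
            raise RuntimeError(f"non-finite retained draws in {name}")
    return draws


# ---------------------------------------------------------------------------
# convergence diagnostics


def rhat(draws: PosteriorDraws, include_species: bool = True,
         threshold: float = 1.1) -> pd.DataFrame:
    """Split-chain Gelman-Rubin statistic per scalar parameter.

    Zero-variance (constant) chains are reported as 1.0 with a flag;
    parameters at or above ``threshold`` are flagged as not converged.
    Requires at least 2 chains and 4 draws per chain.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("Rhat requires at least 2 chains")
    if draws.n_draws < 4:
        raise ValueError("Rhat requires at least 4 draws per chain")
    flat = draws.flat_params(include_species=include_species)
    names = list(flat)
    stacked = np.stack([flat[n] for n in names])  # (P, C, D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(
            stacked.transpose(1, 2, 0), group="posterior")
        r = az.rhat(ds, method="split")["x"].to_numpy()
    zero_var = ~np.isfinite(r)
    r = np.where(zero_var, 1.0, r)
    return pd.DataFrame({
        "rhat": r,
        "zero_variance": zero_var,
        "flagged": r >= threshold,
    }, index=pd.Index(names, name="parameter"))


# ---------------------------------------------------------------------------
# persistence


def draws_long_frame(draws: PosteriorDraws,
                     include_species: bool = False) -> pd.DataFrame:
    """Long-format (chain, draw, parameter, value) table of the draws."""
    flat = draws.flat_params(include_species=include_species)
    frames = []
    C, D = draws.n_chains, draws.n_draws
    chain_col = np.repeat(np.arange(C), D)
    draw_col = np.tile(np.arange(D), C)
    for name, arr in flat.items():
        frames.append(pd.DataFrame({
            "chain": chain_col, "draw": draw_col,
            "parameter": name, "value": arr.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def save_draws(draws: PosteriorDraws, path) -> None:
    """Binary cache of a PosteriorDraws (npz + JSON metadata)."""
    arrays = {f"param::{k}": v for k, v in draws.params.items()}
    arrays["site_richness"] = draws.site_richness
    arrays["ft_obs"] = draws.ft_obs
    arrays["ft_rep"] = draws.ft_rep
    meta = draws.meta
    arrays["meta::area_idx"] = meta["area_idx"]
    arrays["meta::access_raw"] = meta["access_raw"]
    arrays["meta::det_counts"] = meta["det_counts"]
    arrays["meta::std_mean"] = meta["standardization"].mean
    arrays["meta::std_sd"] = meta["standardization"].sd
    for k, v in meta["cov_range_std"].items():
        arrays[f"meta::range::{k}"] = v
    json_meta = {
        "config": meta["config"], "prior": meta["prior"],
        "seed": meta["seed"],
        "species_index": meta["species_index"],
        "station_index": meta["station_index"],
        "std_names": list(meta["standardization"].names),
        "acceptance": meta["acceptance"],
    }
    arrays["meta::json"] = np.frombuffer(
        json.dumps(json_meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_draws(path) -> PosteriorDraws:
    with np.load(path) as npz:
        params = {k.split("::", 1)[1]: npz[k]
                  for k in npz.files if k.startswith("param::")}
        json_meta = json.loads(bytes(npz["meta::json"]).decode())
        std = StandardizationParams(
            names=tuple(json_meta["std_names"]),
            mean=npz["meta::std_mean"], sd=npz["meta::std_sd"])
        ranges = {k.split("::", 2)[2]: npz[k]
                  for k in npz.files if k.startswith("meta::range::")}
        meta = {
            "config": json_meta["config"], "prior": json_meta["prior"],
            "seed": json_meta["seed"],
            "species_index": json_meta["species_index"],
            "station_index": json_meta["station_index"],
            "area_idx": npz["meta::area_idx"],
            "access_raw": npz["meta::access_raw"],
            "det_counts": npz["meta::det_counts"],
            "standardization": std,
            "cov_range_std": ranges,
            "acceptance": json_meta["acceptance"],
        }
        return PosteriorDraws(
            params=params, site_richness=npz["site_richness"],
            ft_obs=npz["ft_obs"], ft_rep=npz["ft_rep"], meta=meta)
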