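"""Probability model for the two-area multispecies occupancy analysis.

The model is a Dorazio–Royle community occupancy model with data
augmentation over a fixed species list.  For species ``k`` at station
``i`` in area ``a(i)``::

    logit psi_ki  = beta0[k,a] + beta1[k,a]*access_i
                    + beta2[k]*canopy_i + beta3[k]*evi_i + beta4[k]*d2w_i
                    + beta5[k]*slope_i + beta6[k]*elev_i
    logit p_kij   = alpha0[k,a,f(i)] + alpha1[k,a]*day_ij

with occupancy state ``z_ik ~ Bern(w_ka * psi_ki)``, detections
``y_kij ~ Bern(z_ik * p_kij)`` over active occasions, and community
membership ``w_ka ~ Bern(Omega)``.

Species-level coefficients are random effects drawn from community
hyperdistributions: the occupancy intercept and access slope have
area-specific means/SDs, the five habitat slopes are shared between
areas, the detection intercepts have feature-specific means/SDs (shared
between areas), and the detection day slope has a single community mean.

All covariates enter on the standardized (pooled z-score) scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import expit, log_expit

AREAS = ("UAX", "MRANP")
FEATURES = ("road", "water", "forest")
#: site covariates in design-column order; access is column 0
COVARIATES = ("access", "canopy", "evi", "d2w", "slope", "elev")

N_AREAS = len(AREAS)
N_FEATURES = len(FEATURES)
N_HABITAT = len(COVARIATES) - 1  # canopy..elev, shared slopes beta2..beta6


def area_index(area: str | int) -> int:
    if isinstance(area, str):
        return AREAS.index(area)
    return int(area)


def feature_index(feature: str | int) -> int:
    if isinstance(feature, str):
        return FEATURES.index(feature)
    return int(feature)


@dataclass
class SpeciesParams:
    """Species-level coefficients for all K species.

    beta0, beta1 : (K, 2) occupancy intercept / access slope per area
    beta_habitat : (K, 5) shared slopes for canopy, EVI, D2W, slope, elevation
    alpha0       : (K, 2, 3) detection intercept per area x feature
    alpha1       : (K, 2) detection day (seasonality) slope per area
    """

    beta0: np.ndarray
    beta1: np.ndarray
    beta_habitat: np.ndarray
    alpha0: np.ndarray
    alpha1: np.ndarray

    @property
    def n_species(self) -> int:
        return self.beta0.shape[0]

    def copy(self) -> "SpeciesParams":
        return SpeciesParams(
            self.beta0.copy(), self.beta1.copy(), self.beta_habitat.copy(),
            self.alpha0.copy(), self.alpha1.copy(),
        )

    def validate(self) -> None:
        K = self.n_species
        shapes = {
            "beta0": (K, N_AREAS), "beta1": (K, N_AREAS),
            "beta_habitat": (K, N_HABITAT),
            "alpha0": (K, N_AREAS, N_FEATURES), "alpha1": (K, N_AREAS),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @classmethod
    def zeros(cls, n_species: int) -> "SpeciesParams":
        return cls(
            beta0=np.zeros((n_species, N_AREAS)),
            beta1=np.zeros((n_species, N_AREAS)),
            beta_habitat=np.zeros((n_species, N_HABITAT)),
            alpha0=np.zeros((n_species, N_AREAS, N_FEATURES)),
            alpha1=np.zeros((n_species, N_AREAS)),
        )


@dataclass
class CommunityHyperparams:
    """Means/SDs of the community random-effect distributions plus Omega.

    mu_beta0, sigma_beta0 : (2,) per area      (occupancy intercept)
    mu_beta1, sigma_beta1 : (2,) per area      (access slope)
    mu_habitat, sigma_habitat : (5,) pooled    (habitat slopes)
    mu_alpha0, sigma_alpha0 : (3,) per feature (detection intercept)
    mu_alpha1, sigma_alpha1 : scalar           (day slope)
    omega : community inclusion probability in (0, 1)
    """

    mu_beta0: np.ndarray
    sigma_beta0: np.ndarray
    mu_beta1: np.ndarray
    sigma_beta1: np.ndarray
    mu_habitat: np.ndarray
    sigma_habitat: np.ndarray
    mu_alpha0: np.ndarray
    sigma_alpha0: np.ndarray
    mu_alpha1: float
    sigma_alpha1: float
    omega: float

    def copy(self) -> "CommunityHyperparams":
        return CommunityHyperparams(
            self.mu_beta0.copy(), self.sigma_beta0.copy(),
            self.mu_beta1.copy(), self.sigma_beta1.copy(),
            self.mu_habitat.copy(), self.sigma_habitat.copy(),
            self.mu_alpha0.copy(), self.sigma_alpha0.copy(),
            float(self.mu_alpha1), float(self.sigma_alpha1), float(self.omega),
        )

    @classmethod
    def default_init(cls) -> "CommunityHyperparams":
        return cls(
            mu_beta0=np.zeros(N_AREAS), sigma_beta0=np.ones(N_AREAS),
            mu_beta1=np.zeros(N_AREAS), sigma_beta1=np.ones(N_AREAS),
            mu_habitat=np.zeros(N_HABITAT), sigma_habitat=np.ones(N_HABITAT),
            mu_alpha0=np.zeros(N_FEATURES), sigma_alpha0=np.ones(N_FEATURES),
            mu_alpha1=0.0, sigma_alpha1=1.0, omega=0.5,
        )


@dataclass
class LatentState:
    """Latent occupancy matrix z (K, I) and inclusion matrix w (K, 2)."""

    z: np.ndarray
    w: np.ndarray

    def copy(self) -> "LatentState":
        return LatentState(self.z.copy(), self.w.copy())


@dataclass
class PriorConfig:
    """Hyperpriors.

    ``omega ~ beta(0.001, 1)``; every hyper-mean has a normal prior with
    location 0 and spread 0.2 read in the JAGS convention as a
    *precision* (SD = sqrt(5) ~ 2.236; set ``mean_spread_is_precision``
    False to read it as an SD); every hyper-SD is uniform on (0, 5].
    """

    omega_shape1: float = 0.001
    omega_shape2: float = 1.0
    mean_loc: float = 0.0
    mean_spread: float = 0.2
    mean_spread_is_precision: bool = True
    sigma_upper: float = 5.0

    def __post_init__(self) -> None:
        if self.omega_shape1 <= 0 or self.omega_shape2 <= 0:
            raise ValueError("beta prior shapes must be positive")
        if self.mean_spread <= 0 or self.sigma_upper <= 0:
            raise ValueError("prior spreads must be positive")

    @property
    def mean_sd(self) -> float:
        if self.mean_spread_is_precision:
            return 1.0 / np.sqrt(self.mean_spread)
        return self.mean_spread


# ---------------------------------------------------------------------------
# probability computations


def occupancy_logits(params: SpeciesParams, X: np.ndarray,
                     area_idx: np.ndarray) -> np.ndarray:
    """Occupancy linear predictor for all species x stations, shape (K, I).

    X is the (I, 6) standardized design (access first), area_idx the
    per-station area index.
    """
    return (
        params.beta0[:, area_idx]
        + params.beta1[:, area_idx] * X[:, 0][None, :]
        + params.beta_habitat @ X[:, 1:].T
    )


def detection_logits(params: SpeciesParams, day_std: np.ndarray,
                     area_idx: np.ndarray, feature_idx: np.ndarray) -> np.ndarray:
    """Detection linear predictor, shape (K, I, J)."""
    a0 = params.alpha0[:, area_idx, feature_idx]  # (K, I)
    a1 = params.alpha1[:, area_idx]  # (K, I)
    return a0[:, :, None] + a1[:, :, None] * day_std[None, :, :]


def occupancy_prob(params: SpeciesParams, species: int, site_covs: np.ndarray,
                   area: str | int) -> float:
    """psi for one species at one station given its standardized covariates."""
    site_covs = np.asarray(site_covs, dtype=float)
    if site_covs.shape != (len(COVARIATES),):
        raise ValueError(f"site_covs must have length {len(COVARIATES)}")
    if not np.all(np.isfinite(site_covs)):
        raise ValueError("site covariates must be finite")
    a = area_index(area)
    lp = (params.beta0[species, a]
          + params.beta1[species, a] * site_covs[0]
          + params.beta_habitat[species] @ site_covs[1:])
    return float(expit(lp))


def detection_prob(params: SpeciesParams, species: int, feature: str | int,
                   day: float, area: str | int) -> float:
    """Per-occasion detection probability p = logit^-1(alpha0 + alpha1*day)."""
    a = area_index(area)
    f = feature_index(feature)
    lp = params.alpha0[species, a, f] + params.alpha1[species, a] * day
    return float(expit(lp))


def _bern_logpmf(x: np.ndarray, logit_p: np.ndarray) -> np.ndarray:
    # log Bern(x | expit(logit_p)) = x*lp - log(1 + e^lp), stable via log_expit
    return np.where(x > 0, log_expit(logit_p), log_expit(-logit_p))


def log_complete_likelihood(params: SpeciesParams, latent: LatentState,
                            hypers: CommunityHyperparams, data) -> float:
    """Complete-data log density of (w, z, y) given species parameters.

    Three Bernoulli layers: w | Omega, z | w*psi, y | z*p.  Returns -inf
    when the latent state contradicts the data (a detection with z=0 or
    occupancy in an excluded community).
    """
    z = latent.z.astype(bool)
    w = latent.w.astype(bool)
    y = data.y.astype(bool)
    active = data.active
    area_idx = data.area_idx

    det_any = (y & active[None, :, :]).any(axis=2)  # (K, I)
    if np.any(det_any & ~z):
        return -np.inf
    if np.any(z & ~w[:, area_idx]):
        return -np.inf

    omega = float(hypers.omega)
    ll = float(np.sum(np.where(w, np.log(omega), np.log1p(-omega))))

    psi_l = occupancy_logits(params, data.X, area_idx)
    w_site = w[:, area_idx]
    z_ll = np.where(z, log_expit(psi_l), log_expit(-psi_l))
    ll += float(np.sum(np.where(w_site, z_ll, 0.0)))

    p_l = detection_logits(params, data.day_std, area_idx, data.feature_idx)
    y_ll = np.where(y, log_expit(p_l), log_expit(-p_l))
    mask = z[:, :, None] & active[None, :, :]
    ll += float(np.sum(np.where(mask, y_ll, 0.0)))
    return ll


def iter_latent_states(n_species: int, n_stations: int) -> Iterable[LatentState]:
    """All 2^(K*2) x 2^(K*I) latent configurations (test-scale only)."""
    for w_bits in itertools.product((0, 1), repeat=n_species * N_AREAS):
        w = np.array(w_bits, dtype=np.int8).reshape(n_species, N_AREAS)
        for z_bits in itertools.product((0, 1), repeat=n_species * n_stations):
            z = np.array(z_bits, dtype=np.int8).reshape(n_species, n_stations)
            yield LatentState(z=z, w=w)


def marginal_loglik_bruteforce(params: SpeciesParams,
                               hypers: CommunityHyperparams, data,
                               max_bits: int = 16) -> float:
    """Exact marginal log likelihood of y by enumerating every (w, z).

    Only feasible on tiny instances; refuses when the latent space
    exceeds 2**max_bits configurations.
    """
    K = params.n_species
    I = data.n_stations
    bits = K * N_AREAS + K * I
    if bits > max_bits:
        raise ValueError(
            f"instance too large to enumerate: {bits} latent bits > {max_bits}")
    terms = [
        log_complete_likelihood(params, latent, hypers, data)
        for latent in iter_latent_states(K, I)
    ]
    terms = np.array(terms)
    finite = terms[np.isfinite(terms)]
    if finite.size == 0:
        return -np.inf
    m = finite.max()
    return float(m + np.log(np.sum(np.exp(finite - m))))
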