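"""Shared fixtures: hand-buildable model data and a small fitted run."""

import numpy as np
import pytest

import msoccupancy as mo
from msoccupancy.ingest import (
    DetectionData,
    ModelData,
    SiteDesign,
    StandardizationParams,
)
from msoccupancy.model import AREAS, COVARIATES, N_AREAS, N_FEATURES, N_HABITAT
from msoccupancy.sampler import PosteriorDraws


def build_model_data(y, area=None, feature=None, X=None, day_std=None,
                     effort_days=None, access_sd=1.0):
    """ModelData from a raw (K, I, J) detection array with simple defaults."""
    y = np.asarray(y, dtype=np.int8)
    K, I, J = y.shape
    if effort_days is None:
        effort_days = np.full((I, J), 3, dtype=int)
    else:
        effort_days = np.asarray(effort_days, dtype=int)
    day = np.where(effort_days > 0, 100.0, np.nan)
    detection = DetectionData(
        y=y, effort_days=effort_days, day=day,
        partial=np.zeros((I, J), dtype=bool),
        species_index=[f"sp{k + 1:02d}" for k in range(K)],
        station_index=[f"st{i + 1:03d}" for i in range(I)],
        area_idx=np.asarray(area if area is not None else [0] * I),
        feature_idx=np.asarray(feature if feature is not None else [0] * I),
    )
    std = StandardizationParams(
        names=tuple(COVARIATES) + ("day",),
        mean=np.append(np.zeros(6), 100.0),
        sd=np.append(np.full(6, access_sd), 1.0))
    design = SiteDesign(
        X=np.zeros((I, 6)) if X is None else np.asarray(X, dtype=float),
        day_std=(np.zeros((I, J)) if day_std is None
                 else np.asarray(day_std, dtype=float)),
        standardization=std,
        access_raw=np.zeros(I),
        cov_range_std={"pooled": np.tile([-1.0, 1.0], (6, 1))},
    )
    return ModelData(detection=detection, design=design)


def build_draws(n=500, n_species=2, beta0=None, beta1=None, w=None,
                site_richness=None, ft_obs=None, ft_rep=None,
                access_sd=6.0, seed=0):
    """Minimal PosteriorDraws (1 chain) with controllable blocks."""
    rng = np.random.default_rng(seed)
    K = n_species

    def fill(x, shape):
        if x is None:
            return np.zeros((1, n) + shape)
        x = np.asarray(x, dtype=float)
        if x.shape == (1, n) + shape:
            return x
        return np.broadcast_to(x, (1, n) + shape).copy()

    params = {
        "beta0": fill(beta0, (K, N_AREAS)),
        "beta1": fill(beta1, (K, N_AREAS)),
        "beta_habitat": fill(None, (K, N_HABITAT)),
        "alpha0": fill(None, (K, N_AREAS, N_FEATURES)),
        "alpha1": fill(None, (K, N_AREAS)),
        "mu.beta0": fill(None, (N_AREAS,)),
        "sigma.beta0": fill(None, (N_AREAS,)) + 1,
        "mu.beta1": fill(None, (N_AREAS,)),
        "sigma.beta1": fill(None, (N_AREAS,)) + 1,
        "mu.habitat": fill(None, (N_HABITAT,)),
        "sigma.habitat": fill(None, (N_HABITAT,)) + 1,
        "mu.alpha0": fill(None, (N_FEATURES,)),
        "sigma.alpha0": fill(None, (N_FEATURES,)) + 1,
        "mu.alpha1": np.zeros((1, n)),
        "sigma.alpha1": np.ones((1, n)),
        "omega": np.full((1, n), 0.5),
        "w": (np.ones((1, n, K, N_AREAS), dtype=np.int8) if w is None
              else np.broadcast_to(
                  np.asarray(w, np.int8), (1, n, K, N_AREAS)).copy()),
    }
    I = 4
    std = StandardizationParams(
        names=tuple(COVARIATES) + ("day",),
        mean=np.append(np.zeros(6), 100.0),
        sd=np.append([access_sd] + [1.0] * 5, 1.0))
    meta = {
        "species_index": [f"sp{k + 1:02d}" for k in range(K)],
        "station_index": [f"st{i + 1:03d}" for i in range(I)],
        "area_idx": np.array([0, 0, 1, 1]),
        "access_raw": np.array([2.0, 8.0, 12.0, 20.0]),
        "standardization": std,
        "cov_range_std": {
            "pooled": np.tile([-2.0, 2.0], (6, 1)),
            "UAX": np.tile([-2.0, 2.0], (6, 1)),
            "MRANP": np.tile([-2.0, 2.0], (6, 1)),
        },
        "det_counts": np.full((K, N_AREAS), 20),
        "config": {}, "prior": {}, "seed": seed, "acceptance": [],
    }
    return PosteriorDraws(
        params=params,
        site_richness=(np.zeros((1, n, I), dtype=np.int16)
                       if site_richness is None else site_richness),
        ft_obs=np.zeros((1, n)) if ft_obs is None else np.asarray(ft_obs),
        ft_rep=np.zeros((1, n)) if ft_rep is None else np.asarray(ft_rep),
        meta=meta,
    )


@pytest.fixture(scope="session")
def small_survey():
    """A small but non-trivial synthetic survey (6 species, 45 stations)."""
    cfg = mo.ScenarioConfig(n_species=6, stations_per_area=(25, 20), seed=7)
    return cfg, mo.simulate_survey(cfg)


@pytest.fixture(scope="session")
def small_fit(small_survey):
    """MCMC fit of the small survey, shared across summary tests."""
    cfg, sv = small_survey
    data = mo.assemble_model_data(sv.stations, sv.detection)
    draws = mo.run_mcmc(data, mo.McmcConfig(
        n_chains=2, n_iter=1500, n_adapt=400, thin=5, seed=42))
    return sv, data, draws
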