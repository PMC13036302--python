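"""Synthetic camera-trap surveys with known truth.

Generates complete two-area surveys with the exact statistical
structure the model assumes: stations stratified along a walking-hours
access gradient, road/water/forest camera features, 21-25-day
deployments binned into 3-day occasions, species-level coefficients
drawn from community hyperdistributions, and detection events emitted
as a camtrapR-style record table so the full ingest path is exercised.

Defaults emulate the Maya Biosphere Reserve survey the package was
built around: 28 species, 188 + 138 stations, access spanning
0.5-16.5 walking hours in the community-managed area (UAX) and
8.8-25.3 h in the protected area (MRANP), and true hyperparameters in
the regime of mean community occupancy ~0.35-0.45 with per-occasion
detection ~0.1-0.3.  Hexagon-grid geometry is not modelled; the
stratified design is emulated with equal station quotas per access
band, since spatial coordinates never enter the likelihood.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .ingest import DetectionData, SiteDesign, occasion_grid, standardize_covariates
from .model import (
    AREAS,
    FEATURES,
    N_AREAS,
    N_FEATURES,
    N_HABITAT,
    CommunityHyperparams,
    LatentState,
    SpeciesParams,
    detection_logits,
    occupancy_logits,
)

GUILDS = ("large herbivore", "small herbivore", "large carnivore",
          "mesocarnivore", "omnivore", "insectivore")


def default_true_hypers() -> CommunityHyperparams:
    """True community hyperparameters for the default scenario."""
    return CommunityHyperparams(
        mu_beta0=np.array([-0.8, -0.4]),
        sigma_beta0=np.array([1.0, 1.0]),
        mu_beta1=np.array([0.5, 0.25]),
        sigma_beta1=np.array([0.6, 0.6]),
        mu_habitat=np.array([0.15, 0.0, 0.0, 0.0, 0.0]),
        sigma_habitat=np.full(N_HABITAT, 0.3),
        mu_alpha0=np.array([-1.2, -1.4, -1.8]),
        sigma_alpha0=np.full(N_FEATURES, 0.5),
        mu_alpha1=0.0,
        sigma_alpha1=0.3,
        omega=0.9,
    )


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic survey."""

    n_species: int = 28
    stations_per_area: tuple = (188, 138)
    deploy_days: tuple = (21, 25)
    occasion_len: int = 3
    access_range: dict = field(default_factory=lambda: {
        "UAX": (0.5, 16.5), "MRANP": (8.8, 25.3)})
    n_access_bands: int = 4
    feature_mix: tuple = (1 / 3, 1 / 3, 1 / 3)
    season_start: dict = field(default_factory=lambda: {
        "UAX": ("2018-03-01", "2018-06-05"),
        "MRANP": ("2019-04-01", "2019-05-05")})
    true_hypers: CommunityHyperparams = field(
        default_factory=default_true_hypers)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if abs(sum(self.feature_mix) - 1.0) > 1e-9 or min(self.feature_mix) < 0:
            raise ValueError("feature proportions must be >= 0 and sum to 1")
        for area, (lo, hi) in self.access_range.items():
            if hi < lo:
                raise ValueError(f"access range not ordered for {area}")
        lo, hi = self.deploy_days
        if not (1 <= lo <= hi <= 60):
            raise ValueError("deployment lengths must lie in [1, 60]")

    @property
    def species_ids(self) -> list:
        return [f"sp{k + 1:02d}" for k in range(self.n_species)]


@dataclass
class TruthRecord:
    """Everything the generator sampled, for recovery tests."""

    params: SpeciesParams
    hypers: CommunityHyperparams
    latent: LatentState
    y: np.ndarray  # (K, I, J) true detection histories

    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a).tolist()
        payload = {
            "params": {k: arr(v) for k, v in asdict(self.params).items()},
            "hypers": {k: arr(v) for k, v in asdict(self.hypers).items()},
            "z": arr(self.latent.z), "w": arr(self.latent.w),
            "y": arr(self.y),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        params = SpeciesParams(**{k: np.asarray(v, dtype=float)
                                  for k, v in d["params"].items()})
        h = {k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
             for k, v in d["hypers"].items()}
        return cls(
            params=params, hypers=CommunityHyperparams(**h),
            latent=LatentState(z=np.asarray(d["z"], dtype=np.int8),
                               w=np.asarray(d["w"], dtype=np.int8)),
            y=np.asarray(d["y"], dtype=np.int8),
        )


@dataclass
class SyntheticSurvey:
    stations: pd.DataFrame
    species: pd.DataFrame
    records: pd.DataFrame
    detection: DetectionData  # true histories (the generator's y)
    design: SiteDesign
    truth: TruthRecord


# ---------------------------------------------------------------------------


def simulate_landscape(config: ScenarioConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Station table: areas, access bands, habitat covariates, features,
    deployment windows.  Stratification into equal quotas per access
    band emulates the hexagon-stratified sampling design."""
    frames = []
    for a, area in enumerate(AREAS):
        n = config.stations_per_area[a]
        lo, hi = config.access_range[area]
        edges = np.linspace(lo, hi, config.n_access_bands + 1)
        band = np.arange(n) % config.n_access_bands
        access = edges[band] + rng.random(n) * (edges[band + 1] - edges[band])
        access = rng.permutation(access)

        counts = np.floor(np.asarray(config.feature_mix) * n).astype(int)
        while counts.sum() < n:
            counts[int(np.argmin(counts))] += 1
        features = rng.permutation(np.repeat(FEATURES, counts))

        s0, s1 = (pd.Timestamp(d) for d in config.season_start[area])
        span = max((s1 - s0).days, 1)
        starts = s0 + pd.to_timedelta(rng.integers(0, span, n), unit="D")
        lengths = rng.integers(config.deploy_days[0],
                               config.deploy_days[1] + 1, n)

        frames.append(pd.DataFrame({
            "station_id": [f"{area}{i + 1:03d}" for i in range(n)],
            "area": area,
            "feature": features,
            "deploy_start": starts,
            "deploy_end": starts + pd.to_timedelta(lengths - 1, unit="D"),
            "access_hours": access,
            "canopy_m": np.clip(rng.normal(20.0, 4.0, n), 2.0, None),
            "evi": rng.normal(0.55, 0.08, n),
            "d2w_m": np.abs(rng.normal(1200.0, 900.0, n)),
            "slope_deg": np.abs(rng.normal(5.0, 4.0, n)),
            "elev_m": rng.normal(250.0, 60.0, n),
        }))
    return pd.concat(frames, ignore_index=True)


def species_table(config: ScenarioConfig) -> pd.DataFrame:
    """Fixed species list with guild and hunted metadata."""
    ids = config.species_ids
    return pd.DataFrame({
        "species_id": ids,
        "common_name": [f"species {k + 1:02d}" for k in range(len(ids))],
        "guild": [GUILDS[k % len(GUILDS)] for k in range(len(ids))],
        "hunted": [(k % 3 == 0) for k in range(len(ids))],
    })


def sample_community(config: ScenarioConfig, design: SiteDesign,
                     area_idx: np.ndarray, rng: np.random.Generator,
                     overrides: dict | None = None):
    """Draw species coefficients from the community hyperdistributions
    and the latent states (w ~ Bern(Omega), z ~ Bern(w * psi)).

    ``overrides`` may pin whole coefficient blocks (e.g. a beta1 array)
    for effect-direction fixtures.
    """
    h = config.true_hypers
    K = config.n_species
    params = SpeciesParams(
        beta0=rng.normal(h.mu_beta0, h.sigma_beta0, (K, N_AREAS)),
        beta1=rng.normal(h.mu_beta1, h.sigma_beta1, (K, N_AREAS)),
        beta_habitat=rng.normal(h.mu_habitat, h.sigma_habitat, (K, N_HABITAT)),
        alpha0=rng.normal(h.mu_alpha0, h.sigma_alpha0,
                          (K, N_AREAS, N_FEATURES)),
        alpha1=rng.normal(h.mu_alpha1, h.sigma_alpha1, (K, N_AREAS)),
    )
    for name, value in (overrides or {}).items():
        getattr(params, name)[...] = value

    w = (rng.random((K, N_AREAS)) < h.omega).astype(np.int8)
    psi = expit(occupancy_logits(params, design.X, area_idx))
    z = ((rng.random(psi.shape) < psi) & (w[:, area_idx] > 0)).astype(np.int8)
    return params, LatentState(z=z, w=w)


def simulate_detections(params: SpeciesParams, latent: LatentState,
                        stations: pd.DataFrame, stub: DetectionData,
                        design: SiteDesign, rng: np.random.Generator,
                        occasion_len: int = 3):
    """Bernoulli detections per active occasion plus a record table.

    For every detection a synthetic record with a timestamp uniformly
    inside the occasion is emitted so that ingest can rebuild the exact
    same histories.
    """
    p = expit(detection_logits(params, design.day_std, stub.area_idx,
                               stub.feature_idx))
    active = stub.active
    occupied = latent.z[:, :, None] > 0
    y = ((rng.random(p.shape) < p) & occupied & active[None]).astype(np.int8)

    starts = stations["deploy_start"].reset_index(drop=True)
    rows = []
    for k, i, j in zip(*np.nonzero(y)):
        day_off = int(j) * occasion_len + int(
            rng.integers(0, stub.effort_days[i, j]))
        seconds = int(rng.integers(0, 86400))
        ts = starts[int(i)] + pd.Timedelta(days=day_off, seconds=seconds)
        rows.append({
            "Station": stub.station_index[int(i)],
            "Species": stub.species_index[int(k)],
            "DateTimeOriginal": ts,
        })
    records = pd.DataFrame(rows, columns=["Station", "Species",
                                          "DateTimeOriginal"])
    if len(records):
        records = records.sort_values(
            ["Station", "DateTimeOriginal", "Species"]).reset_index(drop=True)
    return records, y


def simulate_survey(config: ScenarioConfig | None = None,
                    seed: int | None = None) -> SyntheticSurvey:
    """End-to-end generation: landscape, community, detections, records."""
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    stations = simulate_landscape(config, rng)
    effort_days, day, partial = occasion_grid(stations, config.occasion_len)
    K = config.n_species
    stub = DetectionData(
        y=np.zeros((K, len(stations), effort_days.shape[1]), dtype=np.int8),
        effort_days=effort_days, day=day, partial=partial,
        species_index=config.species_ids,
        station_index=list(stations["station_id"]),
        area_idx=np.array([AREAS.index(a) for a in stations["area"]]),
        feature_idx=np.array([FEATURES.index(f) for f in stations["feature"]]),
    )
    design = standardize_covariates(stations, stub)
    params, latent = sample_community(config, design, stub.area_idx, rng)
    records, y = simulate_detections(params, latent, stations, stub, design,
                                     rng, config.occasion_len)
    detection = DetectionData(
        y=y, effort_days=effort_days, day=day, partial=partial,
        species_index=stub.species_index, station_index=stub.station_index,
        area_idx=stub.area_idx, feature_idx=stub.feature_idx)
    truth = TruthRecord(params=params, hypers=config.true_hypers.copy(),
                        latent=latent, y=y)
    return SyntheticSurvey(
        stations=stations, species=species_table(config), records=records,
        detection=detection, design=design, truth=truth)


def write_survey(survey: SyntheticSurvey, output_dir) -> dict:
    """Write records/stations/species CSVs + truth JSON; returns paths.

    Output is byte-identical for identical seeds.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "stations": out / "stations.csv",
        "species": out / "species.csv",
        "truth": out / "truth.json",
    }
    rec = survey.records.copy()
    rec["DateTimeOriginal"] = rec["DateTimeOriginal"].dt.strftime(
        "%Y-%m-%d %H:%M:%S")
    rec.to_csv(paths["records"], index=False)
    st = survey.stations.copy()
    for col in ("deploy_start", "deploy_end"):
        st[col] = st[col].dt.strftime("%Y-%m-%d")
    st.to_csv(paths["stations"], index=False)
    survey.species.to_csv(paths["species"], index=False)
    paths["truth"].write_text(survey.truth.to_json())
    return paths
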