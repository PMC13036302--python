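"""Camera-trap survey ingest.

Reads camtrapR-style record tables and station tables, bins detections
into fixed-length (default 3-day) occasions tiled from each station's
deployment start, standardizes site and occasion covariates on the
pooled (both-areas) scale, and summarizes survey effort.

Conventions
-----------
* Occasions are labelled 1-based in all user-facing output; arrays are
  0-based internally.
* A trailing partial occasion (deployment length not divisible by the
  occasion length) is retained and flagged; detection probability is not
  effort-adjusted within an occasion.
* The occasion-level seasonality covariate is the Julian day (day of
  year) of the occasion's first day.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AREAS, COVARIATES, FEATURES

logger = logging.getLogger(__name__)

STATION_COVARIATE_COLUMNS = {
    "access": "access_hours",
    "canopy": "canopy_m",
    "evi": "evi",
    "d2w": "d2w_m",
    "slope": "slope_deg",
    "elev": "elev_m",
}

DEFAULT_RECORD_COLUMNS = {
    "station": "Station",
    "species": "Species",
    "timestamp": "DateTimeOriginal",
}


@dataclass
class RecordTable:
    """Validated detection records plus ingest drop counts."""

    records: pd.DataFrame  # columns: station_id, species_id, timestamp
    n_dropped_window: int = 0
    n_dropped_offlist: int = 0

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class StandardizationParams:
    """Pooled mean/SD per covariate (six site covariates + 'day')."""

    names: tuple
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, name: str, values: np.ndarray) -> np.ndarray:
        i = self.names.index(name)
        return (np.asarray(values, dtype=float) - self.mean[i]) / self.sd[i]

    def invert(self, name: str, values: np.ndarray) -> np.ndarray:
        i = self.names.index(name)
        return np.asarray(values, dtype=float) * self.sd[i] + self.mean[i]


@dataclass
class DetectionData:
    """Species x station x occasion detection histories with effort mask."""

    y: np.ndarray            # (K, I, J) int8
    effort_days: np.ndarray  # (I, J) int, 0 where occasion inactive
    day: np.ndarray          # (I, J) Julian day of occasion start, NaN inactive
    partial: np.ndarray      # (I, J) bool, True for trailing partial occasions
    species_index: list
    station_index: list
    area_idx: np.ndarray     # (I,)
    feature_idx: np.ndarray  # (I,)

    @property
    def active(self) -> np.ndarray:
        return self.effort_days > 0

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_stations(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> np.ndarray:
        return self.active.sum(axis=1)

    def validate(self) -> None:
        if np.any(self.y[:, ~self.active]):
            raise ValueError("detections recorded in inactive occasions")
        act = self.active
        if not np.all(np.isfinite(self.day[act])):
            raise ValueError("day covariate not finite on active occasions")


@dataclass
class SiteDesign:
    """Standardized design arrays ready for the likelihood."""

    X: np.ndarray        # (I, 6) standardized site covariates, access first
    day_std: np.ndarray  # (I, J) standardized day, 0 where inactive
    standardization: StandardizationParams
    access_raw: np.ndarray                   # (I,) walking hours
    cov_range_std: dict = field(default_factory=dict)
    # cov_range_std: {"pooled": (6,2), "UAX": (6,2), "MRANP": (6,2)} min/max


@dataclass
class ModelData:
    """DetectionData + SiteDesign bundled for likelihood computations."""

    detection: DetectionData
    design: SiteDesign

    # pass-throughs used throughout the model and sampler
    @property
    def y(self):
        return self.detection.y

    @property
    def active(self):
        return self.detection.active

    @property
    def area_idx(self):
        return self.detection.area_idx

    @property
    def feature_idx(self):
        return self.detection.feature_idx

    @property
    def X(self):
        return self.design.X

    @property
    def day_std(self):
        return self.design.day_std

    @property
    def n_species(self):
        return self.detection.n_species

    @property
    def n_stations(self):
        return self.detection.n_stations

    @property
    def species_index(self):
        return self.detection.species_index


@dataclass
class EffortSummary:
    stations_per_area: dict
    total_stations: int
    trap_nights_per_area: dict
    total_trap_nights: int
    species_frequencies: pd.DataFrame  # species_id x area record counts
    surveyed: pd.DataFrame | None = None  # area, surveyed_km2, total_km2, pct

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"area": a, "stations": self.stations_per_area[a],
             "trap_nights": self.trap_nights_per_area[a]}
            for a in self.stations_per_area
        ]
        rows.append({"area": "total", "stations": self.total_stations,
                     "trap_nights": self.total_trap_nights})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers


def read_stations(path) -> pd.DataFrame:
    """Read and validate the station table.

    Required columns: station_id, area, feature, deploy_start,
    deploy_end, access_hours, canopy_m, evi, d2w_m, slope_deg, elev_m.
    """
    df = pd.read_csv(path)
    required = ["station_id", "area", "feature", "deploy_start", "deploy_end",
                *STATION_COVARIATE_COLUMNS.values()]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"station table missing columns: {missing}")
    df = df.copy()
    df["station_id"] = df["station_id"].astype(str)
    df["deploy_start"] = pd.to_datetime(df["deploy_start"]).dt.normalize()
    df["deploy_end"] = pd.to_datetime(df["deploy_end"]).dt.normalize()
    validate_stations(df)
    return df


def validate_stations(df: pd.DataFrame) -> None:
    bad_area = set(df["area"]) - set(AREAS)
    if bad_area:
        raise ValueError(f"unknown areas: {sorted(bad_area)} (expected {AREAS})")
    bad_feat = set(df["feature"]) - set(FEATURES)
    if bad_feat:
        raise ValueError(
            f"unknown features: {sorted(bad_feat)} (expected {FEATURES})")
    if df["station_id"].duplicated().any():
        dup = df.loc[df["station_id"].duplicated(), "station_id"].tolist()
        raise ValueError(f"duplicate station ids: {dup}")
    length = (df["deploy_end"] - df["deploy_start"]).dt.days + 1
    if (length < 1).any() or (length > 60).any():
        bad = df.loc[(length < 1) | (length > 60), "station_id"].tolist()
        raise ValueError(f"deployment length outside [1, 60] days at: {bad}")
    outside = (length < 21) | (length > 25)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} deployments outside the typical 21-25 day "
            "window; accepted", stacklevel=2)
    covs = list(STATION_COVARIATE_COLUMNS.values())
    if df[covs].isna().any().any():
        bad = [c for c in covs if df[c].isna().any()]
        raise ValueError(f"missing covariate values in: {bad}")


def read_species_list(path) -> pd.DataFrame:
    """Read the fixed species list (species_id, common_name, guild, hunted)."""
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise ValueError("species list must have a species_id column")
    df = df.copy()
    df["species_id"] = df["species_id"].astype(str)
    if df["species_id"].duplicated().any():
        raise ValueError("duplicate species ids in species list")
    return df


def read_records(path, stations: pd.DataFrame, species: Sequence[str],
                 columns: Mapping[str, str] | None = None) -> RecordTable:
    """Read a camtrapR-style record table and filter it against the survey.

    Rows whose timestamp falls outside the station's deployment window
    are dropped and counted; rows for species absent from the fixed
    species list are dropped with a warning.  Unknown station ids are an
    error.
    """
    cols = dict(DEFAULT_RECORD_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    out = pd.DataFrame({
        "station_id": df[cols["station"]].astype(str),
        "species_id": df[cols["species"]].astype(str),
        "timestamp": pd.to_datetime(df[cols["timestamp"]]),
    })
    return filter_records(out, stations, species)


def filter_records(records: pd.DataFrame, stations: pd.DataFrame,
                   species: Sequence[str]) -> RecordTable:
    """Apply the RecordTable invariants to an in-memory record frame."""
    known = set(stations["station_id"])
    unknown = sorted(set(records["station_id"]) - known)
    if unknown:
        raise ValueError(f"records reference unknown stations: {unknown}")

    species = [str(s) for s in species]
    on_list = records["species_id"].isin(species)
    n_offlist = int((~on_list).sum())
    if n_offlist:
        off = sorted(records.loc[~on_list, "species_id"].unique())
        warnings.warn(
            f"dropped {n_offlist} records of species not on the fixed list: "
            f"{off}", stacklevel=2)
    records = records[on_list]

    st = stations.set_index("station_id")
    start = st.loc[records["station_id"], "deploy_start"].to_numpy()
    end = st.loc[records["station_id"], "deploy_end"].to_numpy()
    ts = records["timestamp"].dt.normalize().to_numpy()
    in_window = (ts >= start) & (ts <= end)
    n_window = int((~in_window).sum())
    if n_window:
        logger.info("dropped %d records outside deployment windows", n_window)
    records = records[in_window].reset_index(drop=True)
    return RecordTable(records=records, n_dropped_window=n_window,
                       n_dropped_offlist=n_offlist)


# ---------------------------------------------------------------------------
# detection histories


def occasion_grid(stations: pd.DataFrame, occasion_len: int = 3):
    """Tile each deployment window into occasions of ``occasion_len`` days.

    Returns (effort_days, day, partial): (I, J) arrays where J is the
    maximum occasion count; effort_days is 0 for inactive cells and the
    day array holds the Julian day (day of year) of each occasion's
    first day.
    """
    if occasion_len < 1:
        raise ValueError("occasion_len must be >= 1")
    if len(stations) == 0:
        raise ValueError("empty station table")
    lengths = ((stations["deploy_end"] - stations["deploy_start"]).dt.days
               + 1).to_numpy()
    n_occ = np.array([ceil(L / occasion_len) for L in lengths])
    J = int(n_occ.max())
    I = len(stations)
    effort_days = np.zeros((I, J), dtype=int)
    day = np.full((I, J), np.nan)
    partial = np.zeros((I, J), dtype=bool)
    starts = stations["deploy_start"].to_numpy()
    for i in range(I):
        L = int(lengths[i])
        start_doy = pd.Timestamp(starts[i]).dayofyear
        for j in range(n_occ[i]):
            d = min(occasion_len, L - j * occasion_len)
            effort_days[i, j] = d
            day[i, j] = start_doy + j * occasion_len
            if d < occasion_len:
                partial[i, j] = True
    return effort_days, day, partial


def build_detection_histories(records: RecordTable | pd.DataFrame,
                              stations: pd.DataFrame,
                              species: Sequence[str],
                              occasion_len: int = 3) -> DetectionData:
    """Collapse records into binary species x station x occasion histories.

    ``y[k, i, j] = 1`` iff at least one record of species k at station i
    fell inside occasion j; occasions tile the deployment window from
    deploy_start.
    """
    if isinstance(records, RecordTable):
        rec = records.records
    else:
        rec = records
    species = [str(s) for s in species]
    effort_days, day, partial = occasion_grid(stations, occasion_len)
    I, J = effort_days.shape
    K = len(species)
    y = np.zeros((K, I, J), dtype=np.int8)

    sp_pos = {s: k for k, s in enumerate(species)}
    st_pos = {s: i for i, s in enumerate(stations["station_id"])}
    starts = stations.set_index("station_id")["deploy_start"]
    if len(rec):
        offsets = (rec["timestamp"].dt.normalize().to_numpy()
                   - starts.loc[rec["station_id"]].to_numpy())
        occ = (offsets / np.timedelta64(1, "D")).astype(int) // occasion_len
        for sid, spid, j in zip(rec["station_id"], rec["species_id"], occ):
            y[sp_pos[spid], st_pos[sid], j] = 1

    data = DetectionData(
        y=y, effort_days=effort_days, day=day, partial=partial,
        species_index=list(species),
        station_index=list(stations["station_id"]),
        area_idx=np.array([AREAS.index(a) for a in stations["area"]]),
        feature_idx=np.array([FEATURES.index(f) for f in stations["feature"]]),
    )
    data.validate()
    return data


def standardize_covariates(stations: pd.DataFrame,
                           detection: DetectionData) -> SiteDesign:
    """Center/scale the six site covariates and day on pooled moments.

    Pooling is across all stations in both areas.  Raises on a
    zero-variance covariate (naming it).
    """
    names = tuple(COVARIATES) + ("day",)
    raw = np.column_stack([
        stations[STATION_COVARIATE_COLUMNS[c]].to_numpy(dtype=float)
        for c in COVARIATES
    ])
    act = detection.active
    day_vals = detection.day[act]
    means = np.append(raw.mean(axis=0), day_vals.mean())
    sds = np.append(raw.std(axis=0, ddof=0), day_vals.std(ddof=0))
    for name, sd in zip(names, sds):
        if not sd > 0:
            raise ValueError(f"zero-variance covariate: {name}")
    params = StandardizationParams(names=names, mean=means, sd=sds)

    X = (raw - means[:-1]) / sds[:-1]
    day_std = np.zeros_like(detection.day)
    day_std[act] = (detection.day[act] - means[-1]) / sds[-1]

    ranges = {"pooled": np.column_stack([X.min(axis=0), X.max(axis=0)])}
    for a, name in enumerate(AREAS):
        sel = detection.area_idx == a
        if sel.any():
            ranges[name] = np.column_stack(
                [X[sel].min(axis=0), X[sel].max(axis=0)])
    return SiteDesign(
        X=X, day_std=day_std, standardization=params,
        access_raw=raw[:, 0], cov_range_std=ranges,
    )


def assemble_model_data(stations: pd.DataFrame, detection: DetectionData,
                        design: SiteDesign | None = None) -> ModelData:
    if design is None:
        design = standardize_covariates(stations, detection)
    return ModelData(detection=detection, design=design)


# ---------------------------------------------------------------------------
# effort summaries


def summarize_effort(stations: pd.DataFrame, detection: DetectionData,
                     records: RecordTable | pd.DataFrame | None = None,
                     region_areas: Mapping[str, Mapping[str, float]] | None = None
                     ) -> EffortSummary:
    """Station counts, trap nights, raw capture frequencies, area coverage.

    ``region_areas`` maps an area name to ``{"surveyed_km2": ..,
    "total_km2": ..}``; percentages are surveyed/total * 100.
    """
    per_area_n = {}
    per_area_tn = {}
    for a, name in enumerate(AREAS):
        sel = detection.area_idx == a
        per_area_n[name] = int(sel.sum())
        per_area_tn[name] = int(detection.effort_days[sel].sum())

    if isinstance(records, RecordTable):
        rec = records.records
    elif records is not None:
        rec = records
    else:
        rec = None
    freq = pd.DataFrame(0, index=detection.species_index, columns=list(AREAS))
    if rec is not None and len(rec):
        st_area = stations.set_index("station_id")["area"]
        counts = (rec.assign(area=st_area.loc[rec["station_id"]].to_numpy())
                  .groupby(["species_id", "area"]).size())
        for (sp, ar), n in counts.items():
            if sp in freq.index:
                freq.loc[sp, ar] = int(n)
    else:
        # fall back to detection events (binary per occasion)
        for a, name in enumerate(AREAS):
            sel = detection.area_idx == a
            freq[name] = detection.y[:, sel, :].sum(axis=(1, 2))
    freq.index.name = "species_id"

    surveyed = None
    if region_areas:
        rows = []
        for name, sizes in region_areas.items():
            s, t = float(sizes["surveyed_km2"]), float(sizes["total_km2"])
            rows.append({"area": name, "surveyed_km2": s, "total_km2": t,
                         "pct_surveyed": 100.0 * s / t})
        surveyed = pd.DataFrame(rows)

    return EffortSummary(
        stations_per_area=per_area_n,
        total_stations=int(sum(per_area_n.values())),
        trap_nights_per_area=per_area_tn,
        total_trap_nights=int(sum(per_area_tn.values())),
        species_frequencies=freq,
        surveyed=surveyed,
    )


def detection_long_frame(detection: DetectionData) -> pd.DataFrame:
    """Long-format detection histories (1-based occasion labels)."""
    K, I, J = detection.y.shape
    rows = []
    for i in range(I):
        for j in range(J):
            if detection.effort_days[i, j] == 0:
                continue
            for k in range(K):
                rows.append({
                    "species": detection.species_index[k],
                    "station": detection.station_index[i],
                    "occasion": j + 1,
                    "y": int(detection.y[k, i, j]),
                    "effort_days": int(detection.effort_days[i, j]),
                    "day": float(detection.day[i, j]),
                })
    return pd.DataFrame(rows)
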