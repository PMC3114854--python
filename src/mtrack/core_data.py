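"""Domain types, coordinate conventions and I/O shared by every pipeline stage.

Coordinate conventions
----------------------
Longitudes are stored internally in ``[0, 360)`` so that tracks crossing the
antimeridian (the study region spans roughly 160°E–225°E) remain monotone in
longitude.  Latitudes are in ``[-90, 90]``.  Distances are great-circle
distances on a sphere of radius 6371 km — the few-per-mille error relative to
an ellipsoid is negligible against satellite-tag location error.

Times are decimal days since each animal's release (UTC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0  # 111.19492664...

#: Argos quality classes ordered best → worst, plus GL = light/SST geolocation.
LOC_CLASSES = ("3", "2", "1", "0", "A", "B", "GL")
_CLASS_RANK = {c: i for i, c in enumerate(LOC_CLASSES)}


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------

def normalize_lon(lon):
    """Map longitudes (degrees, either sign convention) into [0, 360)."""
    return np.asarray(lon, dtype=float) % 360.0


def haversine_km(p, q):
    """Great-circle distance in km between lon/lat pairs ``p`` and ``q``.

    Accepts scalars or arrays; either longitude convention.
    """
    lon1, lat1 = np.radians(normalize_lon(p[0])), np.radians(np.asarray(p[1], float))
    lon2, lat2 = np.radians(normalize_lon(q[0])), np.radians(np.asarray(q[1], float))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def initial_bearing_rad(p, q):
    """Initial great-circle bearing from ``p`` to ``q`` (radians, 0 = north,
    positive clockwise/east), array-friendly."""
    lon1, lat1 = np.radians(normalize_lon(p[0])), np.radians(np.asarray(p[1], float))
    lon2, lat2 = np.radians(normalize_lon(q[0])), np.radians(np.asarray(q[1], float))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def destination_point(lon, lat, bearing_rad, distance_km):
    """Point reached from (lon, lat) travelling ``distance_km`` on initial
    bearing ``bearing_rad`` along a great circle.  Returns (lon, lat) degrees
    with lon in [0, 360)."""
    delta = np.asarray(distance_km, float) / EARTH_RADIUS_KM
    phi1 = np.radians(np.asarray(lat, float))
    lam1 = np.radians(normalize_lon(lon))
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(bearing_rad)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(bearing_rad) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return normalize_lon(np.degrees(lam2)), np.degrees(phi2)


class LocalProjection:
    """Azimuthal-equidistant tangent plane (km) on the 6371-km sphere.

    Each animal's track is projected onto a plane centred on the track
    midpoint before state-space filtering; distortion over the few thousand km
    a single track covers is small compared to location error.
    ``x`` points east, ``y`` north.
    """

    def __init__(self, center_lon: float, center_lat: float):
        self.center_lon = float(normalize_lon(center_lon))
        self.center_lat = float(center_lat)
        self._lam0 = np.radians(self.center_lon)
        self._phi0 = np.radians(self.center_lat)

    def forward(self, lon, lat):
        lam = np.radians(normalize_lon(lon))
        phi = np.radians(np.asarray(lat, float))
        dlam = lam - self._lam0
        cos_c = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), -> 1 as c -> 0
        k = np.where(c > 1e-12, c / np.where(c > 1e-12, np.sin(c), 1.0), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(self._phi0) * np.sin(phi) - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS_KM
        with np.errstate(invalid="ignore"):
            sin_c, cos_c = np.sin(c), np.cos(c)
            phi = np.arcsin(
                np.clip(
                    cos_c * np.sin(self._phi0)
                    + np.where(rho > 1e-12, y * sin_c * np.cos(self._phi0) / np.where(rho > 1e-12, rho, 1.0), 0.0),
                    -1.0,
                    1.0,
                )
            )
            lam = self._lam0 + np.arctan2(
                x * sin_c,
                rho * np.cos(self._phi0) * cos_c - y * np.sin(self._phi0) * sin_c,
            )
        lon = normalize_lon(np.degrees(np.where(rho > 1e-12, lam, self._lam0)))
        lat = np.degrees(np.where(rho > 1e-12, phi, self._phi0))
        return lon, lat


# ---------------------------------------------------------------------------
# observation records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocationObs:
    """A single error-prone position fix."""

    animal_id: str
    t: float          # decimal days since release, >= 0
    lon: float        # degrees in [0, 360)
    lat: float        # degrees in [-90, 90]
    loc_class: str    # one of LOC_CLASSES


@dataclass
class ObservationSet:
    """Per-animal, time-sorted location observations.

    Backed by a DataFrame with columns ``animal_id, t, lon, lat, loc_class``;
    ``t`` is strictly increasing within each animal.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"animal_id", "t", "lon", "lat", "loc_class"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"ObservationSet missing columns: {sorted(missing)}")

    def __len__(self):
        return len(self.df)

    @property
    def animal_ids(self) -> list[str]:
        return list(self.df["animal_id"].unique())

    def for_animal(self, animal_id: str) -> pd.DataFrame:
        return self.df[self.df["animal_id"] == animal_id].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[LocationObs]) -> "ObservationSet":
        rows = [(r.animal_id, r.t, r.lon, r.lat, r.loc_class) for r in records]
        df = pd.DataFrame(rows, columns=["animal_id", "t", "lon", "lat", "loc_class"])
        return cls(_canonicalize(df))


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (animal, t), normalize longitude, collapse duplicate timestamps
    keeping the better location class, validate latitude."""
    bad_lat = df.index[(df["lat"].abs() > 90.0)]
    if len(bad_lat):
        i = bad_lat[0]
        raise ValueError(
            f"latitude out of range at row {i}: lat={df.loc[i, 'lat']} "
            f"(animal {df.loc[i, 'animal_id']}, t={df.loc[i, 't']})"
        )
    df = df.copy()
    df["lon"] = normalize_lon(df["lon"].to_numpy())
    df["loc_class"] = df["loc_class"].astype(str)
    unknown = ~df["loc_class"].isin(LOC_CLASSES)
    if unknown.any():
        for i in df.index[unknown]:
            logger.warning(
                "dropping row with unknown location class %r (animal %s, t=%s)",
                df.loc[i, "loc_class"], df.loc[i, "animal_id"], df.loc[i, "t"],
            )
        df = df[~unknown]
    df["_rank"] = df["loc_class"].map(_CLASS_RANK)
    df = df.sort_values(["animal_id", "t", "_rank"], kind="mergesort")
    dup = df.duplicated(subset=["animal_id", "t"], keep="first")
    if dup.any():
        for i in df.index[dup]:
            logger.info(
                "discarding duplicate-timestamp observation (animal %s, t=%s, class %s)",
                df.loc[i, "animal_id"], df.loc[i, "t"], df.loc[i, "loc_class"],
            )
        df = df[~dup]
    return df.drop(columns="_rank").reset_index(drop=True)


def read_locations(path, delimiter: str = ",", release_times: dict[str, pd.Timestamp] | None = None) -> ObservationSet:
    """Read a location CSV into an :class:`ObservationSet`.

    Expected columns: ``animal_id, timestamp, lon, lat, loc_class`` with
    ISO-8601 timestamps, or ``animal_id, t, lon, lat, loc_class`` with ``t``
    already in decimal days since release.  Timestamps are converted to
    decimal days since each animal's first observation (or the release time
    supplied in ``release_times``).
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"animal_id": str, "loc_class": str})
    if "t" not in df.columns:
        if "timestamp" not in df.columns:
            raise ValueError("location file needs a 't' or 'timestamp' column")
        ts = pd.to_datetime(df["timestamp"], utc=True)
        t = np.empty(len(df))
        for aid, idx in df.groupby("animal_id").groups.items():
            t0 = release_times.get(aid) if release_times else None
            if t0 is None:
                t0 = ts.loc[idx].min()
            t0 = pd.Timestamp(t0)
            if t0.tzinfo is None:
                t0 = t0.tz_localize("UTC")
            t[df.index.get_indexer(idx)] = (ts.loc[idx] - t0).dt.total_seconds() / 86400.0
        df = df.assign(t=t)
    df = df[["animal_id", "t", "lon", "lat", "loc_class"]]
    return ObservationSet(_canonicalize(df))


def write_locations(obs: ObservationSet, path, delimiter: str = ",") -> None:
    """Write the canonical (t in decimal days) location table."""
    obs.df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# measurement-error model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Class-dependent location-error scales.

    ``base_sd_lon_km``/``base_sd_lat_km`` set the scale of the reference
    (class-3) Argos fix; ``k_mult`` maps each class to (k_lon, k_lat)
    multipliers; geolocation (class GL) has its own absolute scales with the
    characteristic latitude ≫ longitude error of light-based positions, and a
    Student-t tail index ``gl_t_df`` used by the simulator.

    The per-class multipliers of the source error tables are not public;
    these defaults reproduce the standard Argos ordering and the reported
    geolocation deviation magnitudes (56.8 km lon / 112.2 km lat).
    """

    base_sd_lon_km: float = 0.5
    base_sd_lat_km: float = 0.5
    k_mult: dict = field(default_factory=lambda: {
        "3": (1.0, 1.0), "2": (1.5, 1.5), "1": (3.0, 3.0),
        "0": (6.0, 6.0), "A": (12.0, 12.0), "B": (24.0, 24.0),
    })
    gl_sd_lon_km: float = 56.8
    gl_sd_lat_km: float = 112.2
    gl_t_df: float = 3.0

    def __post_init__(self):
        if self.base_sd_lon_km <= 0 or self.base_sd_lat_km <= 0:
            raise ValueError("base SDs must be positive")
        if self.gl_t_df <= 0:
            raise ValueError("gl_t_df must be positive")
        if self.gl_sd_lat_km < self.gl_sd_lon_km:
            raise ValueError("GL latitude scale must be >= GL longitude scale")
        ks = [self.k_mult[c] for c in ("3", "2", "1", "0", "A", "B")]
        for (a_lon, a_lat), (b_lon, b_lat) in zip(ks, ks[1:]):
            if b_lon < a_lon or b_lat < a_lat:
                raise ValueError("multipliers must be non-decreasing from class 3 to B")

    def sd_km(self, loc_class: str) -> tuple[float, float]:
        """(sd_lon_km, sd_lat_km) for one location class."""
        if loc_class == "GL":
            return self.gl_sd_lon_km, self.gl_sd_lat_km
        k_lon, k_lat = self.k_mult[loc_class]
        return self.base_sd_lon_km * k_lon, self.base_sd_lat_km * k_lat

    def sd_km_arrays(self, loc_classes) -> tuple[np.ndarray, np.ndarray]:
        pairs = [self.sd_km(c) for c in loc_classes]
        arr = np.array(pairs, dtype=float).reshape(-1, 2)
        return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# deployment summary (printed Table 1)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagSummaryRow:
    marlin_id: str
    weight_kg: float
    start_date: pd.Timestamp
    start_lat: float
    start_lon: float
    end_lat: float
    end_lon: float
    days_at_liberty: int
    slrt_days: int
    psat_days: int
    max_gap_days: float
    flag: str = ""

    def __post_init__(self):
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        if min(self.days_at_liberty, self.slrt_days, self.psat_days, self.max_gap_days) < 0:
            raise ValueError("day counts must be non-negative")


@dataclass(frozen=True)
class DeploymentSummary:
    n_animals: int
    mean_weight_kg: float
    total_days_at_liberty: int
    mean_days_at_liberty: float
    total_slrt_days: int
    mean_slrt_days: float
    total_psat_days: int
    mean_psat_days: float
    mean_max_gap_days: float
    counts_by_year: dict
    n_double_tagged: int
    n_slrt_only: int


def read_table1_fixture() -> list[TagSummaryRow]:
    """The packaged 25-animal deployment table (verbatim transcription)."""
    with resources.files("mtrack.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh, dtype={"marlin_id": str}, keep_default_na=False)
    if len(df) != 25:
        raise RuntimeError(f"deployment fixture corrupt: expected 25 rows, got {len(df)}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(TagSummaryRow(
            marlin_id=rec.marlin_id,
            weight_kg=float(rec.weight_kg),
            start_date=pd.Timestamp(rec.start_date),
            start_lat=float(rec.start_lat),
            start_lon=float(normalize_lon(rec.start_lon)),
            end_lat=float(rec.end_lat),
            end_lon=float(normalize_lon(rec.end_lon)),
            days_at_liberty=int(rec.days_at_liberty),
            slrt_days=int(rec.slrt_days),
            psat_days=int(rec.psat_days),
            max_gap_days=float(rec.max_gap_days),
            flag=str(rec.flag),
        ))
    return rows


def summarize_deployments(rows: list[TagSummaryRow]) -> DeploymentSummary:
    """Arithmetic means/totals over a deployment table."""
    if not rows:
        raise ValueError("summarize_deployments needs at least one row")
    n = len(rows)
    w = np.array([r.weight_kg for r in rows])
    dal = np.array([r.days_at_liberty for r in rows])
    slrt = np.array([r.slrt_days for r in rows])
    psat = np.array([r.psat_days for r in rows])
    gap = np.array([r.max_gap_days for r in rows])
    years = pd.Series([r.start_date.year for r in rows]).value_counts().sort_index()
    n_slrt_only = int((psat == 0).sum())
    return DeploymentSummary(
        n_animals=n,
        mean_weight_kg=float(w.mean()),
        total_days_at_liberty=int(dal.sum()),
        mean_days_at_liberty=float(dal.mean()),
        total_slrt_days=int(slrt.sum()),
        mean_slrt_days=float(slrt.mean()),
        total_psat_days=int(psat.sum()),
        mean_psat_days=float(psat.mean()),
        mean_max_gap_days=float(gap.mean()),
        counts_by_year={int(y): int(c) for y, c in years.items()},
        n_double_tagged=n - n_slrt_only,
        n_slrt_only=n_slrt_only,
    )
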