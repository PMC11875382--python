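"""Nocturnal wind-assisted dispersal projection.

A simplified Lagrangian trajectory projector for a nocturnally migrating
moth: from each source, one forward trajectory per night, starting at dusk
and limited to 12 hours of continuous flight at a fixed altitude band
(500 m AGL start, 1500 m AGL ceiling).  Trajectories are advected by the
gridded wind field with explicit midpoint (RK2) integration, bilinear spatial
and linear temporal interpolation, on a local-tangent (flat-earth)
approximation — adequate for the < 500 km nightly ranges involved —
with great-circle formulas used for reported displacements and bearings.

Nights are averaged into an occupancy grid: the percentage of nightly
trajectories entering each grid cell, the standard frequency-distribution
display of ensemble trajectory runs.  Consecutive-night flights are not
chained; each night starts fresh from the source.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "FlightConfig",
    "Trajectory",
    "OccupancyGrid",
    "DirectionalityStats",
    "integrate_trajectory",
    "nightly_ensemble",
    "directionality_stats",
    "great_circle_km",
    "initial_bearing_deg",
]

EARTH_RADIUS_KM = 6371.0
_M_PER_DEG_LAT = EARTH_RADIUS_KM * 1000.0 * math.pi / 180.0


@dataclass(frozen=True)
class FlightConfig:
    """Nightly flight constraints.

    ``dusk_hour`` is cosmetic bookkeeping (local solar time of departure);
    integration time runs in hours from dusk.  Altitude is held at
    ``start_altitude_m`` (single-level wind mode), clamped to the ceiling.
    """

    duration_h: float = 12.0
    start_altitude_m: float = 500.0
    max_altitude_m: float = 1500.0
    step_min: float = 10.0
    dusk_hour: float = 19.0

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.start_altitude_m <= self.max_altitude_m:
            raise ValueError("require 0 < start altitude <= max altitude")
        if self.step_min <= 0:
            raise ValueError("integration step must be positive")


@dataclass
class Trajectory:
    """Timestamped path of one night's flight."""

    times_h: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    exited_grid: bool = False

    @property
    def endpoint(self) -> tuple:
        return float(self.lats[-1]), float(self.lons[-1])

    def to_geojson(self) -> dict:
        return {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [
                    [float(lo), float(la)] for la, lo in zip(self.lats, self.lons)
                ],
            },
            "properties": {
                "exited_grid": self.exited_grid,
                "hours": [float(t) for t in self.times_h],
            },
        }


@dataclass
class OccupancyGrid:
    """Per-cell percentage of trajectories entering the cell."""

    lats: np.ndarray  # cell-centre latitudes
    lons: np.ndarray
    frequency: np.ndarray  # (lat, lon), percent in [0, 100]
    n_trajectories: int

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"frequency": (("lat", "lon"), self.frequency)},
            coords={"lat": self.lats, "lon": self.lons},
            attrs={"n_trajectories": self.n_trajectories},
        )

    def cell_of(self, lat: float, lon: float) -> tuple:
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return i, j


@dataclass(frozen=True)
class DirectionalityStats:
    mean_bearing_deg: float
    resultant_length: float  # circular R in [0, 1]
    mean_displacement_km: float


def _interpolators(wind: xr.Dataset):
    times = wind["time"].values.astype(float)
    lats = wind["lat"].values.astype(float)
    lons = wind["lon"].values.astype(float)
    u = RegularGridInterpolator(
        (times, lats, lons), wind["u_ms"].values, bounds_error=False, fill_value=np.nan
    )
    v = RegularGridInterpolator(
        (times, lats, lons), wind["v_ms"].values, bounds_error=False, fill_value=np.nan
    )
    return u, v, (lats[0], lats[-1], lons[0], lons[-1], times[0], times[-1])


def integrate_trajectory(
    start: tuple,
    wind: xr.Dataset,
    cfg: FlightConfig = FlightConfig(),
) -> Trajectory:
    """Integrate one nightly trajectory through a wind field.

    Explicit midpoint (RK2) on dx/dt = wind(x, t): a half step with the wind
    at the current position, then a full step with the wind sampled at the
    midpoint.  Wind components are bilinearly interpolated in space and
    linearly in time.  The trajectory terminates early (flagged) when it
    leaves the wind grid or runs past the field's time coverage.
    """
    lat0, lon0 = float(start[0]), float(start[1])
    u_i, v_i, (la0, la1, lo0, lo1, t0, t1) = _interpolators(wind)
    if not (la0 <= lat0 <= la1 and lo0 <= lon0 <= lo1):
        raise ValueError(f"start {start} outside wind grid")
    if t1 < cfg.duration_h:
        raise ValueError(
            f"wind field covers {t1} h but flight lasts {cfg.duration_h} h"
        )
    dt_h = cfg.step_min / 60.0
    n_steps = int(math.ceil(cfg.duration_h / dt_h))
    times = [0.0]
    lats = [lat0]
    lons = [lon0]
    exited = False

    def deg_rates(lat: float, lon: float, t: float) -> tuple | None:
        uv = (float(u_i([t, lat, lon])[0]), float(v_i([t, lat, lon])[0]))
        if any(map(math.isnan, uv)):
            return None
        dlat = uv[1] * 3600.0 / _M_PER_DEG_LAT  # deg/h
        dlon = uv[0] * 3600.0 / (_M_PER_DEG_LAT * math.cos(math.radians(lat)))
        return dlat, dlon

    lat, lon, t = lat0, lon0, 0.0
    for k in range(n_steps):
        h = min(dt_h, cfg.duration_h - t)
        r1 = deg_rates(lat, lon, t)
        if r1 is None:
            exited = True
            break
        mid_lat = lat + 0.5 * h * r1[0]
        mid_lon = lon + 0.5 * h * r1[1]
        r2 = deg_rates(mid_lat, mid_lon, t + 0.5 * h)
        if r2 is None:
            exited = True
            break
        lat += h * r2[0]
        lon += h * r2[1]
        t += h
        if not (la0 <= lat <= la1 and lo0 <= lon <= lo1):
            exited = True
            times.append(t)
            lats.append(lat)
            lons.append(lon)
            break
        times.append(t)
        lats.append(lat)
        lons.append(lon)
    return Trajectory(
        times_h=np.array(times), lats=np.array(lats), lons=np.array(lons),
        exited_grid=exited,
    )


def nightly_ensemble(
    start: tuple,
    wind_by_night: Sequence[xr.Dataset],
    cfg: FlightConfig = FlightConfig(),
) -> tuple:
    """One trajectory per night, averaged into an occupancy-frequency grid.

    A cell counts as entered by a night if any segment of that night's path
    intersects it; segments are super-sampled at half the grid spacing so
    fast crossings cannot skip cells.  Frequencies are percentages of nights;
    the source cell is entered by every trajectory, hence always 100.

    Returns ``(OccupancyGrid, list_of_trajectories)``.
    """
    if not wind_by_night:
        raise ValueError("need at least one night of wind data")
    grid = wind_by_night[0]
    lats = grid["lat"].values.astype(float)
    lons = grid["lon"].values.astype(float)
    dlat = float(np.min(np.diff(lats)))
    dlon = float(np.min(np.diff(lons)))
    counts = np.zeros((len(lats), len(lons)))
    trajectories = []
    for wind in wind_by_night:
        traj = integrate_trajectory(start, wind, cfg)
        trajectories.append(traj)
        visited = set()
        for a_lat, a_lon, b_lat, b_lon in zip(
            traj.lats[:-1], traj.lons[:-1], traj.lats[1:], traj.lons[1:]
        ):
            seg_n = 1 + int(
                2 * max(abs(b_lat - a_lat) / dlat, abs(b_lon - a_lon) / dlon)
            )
            for f in np.linspace(0.0, 1.0, seg_n + 1):
                la = a_lat + f * (b_lat - a_lat)
                lo = a_lon + f * (b_lon - a_lon)
                i = int(np.argmin(np.abs(lats - la)))
                j = int(np.argmin(np.abs(lons - lo)))
                visited.add((i, j))
        if len(traj.lats) == 1:  # degenerate single-point path
            i = int(np.argmin(np.abs(lats - traj.lats[0])))
            j = int(np.argmin(np.abs(lons - traj.lons[0])))
            visited.add((i, j))
        for i, j in visited:
            counts[i, j] += 1
    freq = 100.0 * counts / len(wind_by_night)
    return (
        OccupancyGrid(lats=lats, lons=lons, frequency=freq,
                      n_trajectories=len(wind_by_night)),
        trajectories,
    )


# ---------------------------------------------------------------------------
# spherical geometry + circular statistics
# ---------------------------------------------------------------------------


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in km (Earth radius 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def initial_bearing_deg(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Initial great-circle bearing from point 1 to point 2, degrees from north."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    x = math.sin(dl) * math.cos(p2)
    y = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
    return math.degrees(math.atan2(x, y)) % 360.0


def directionality_stats(
    endpoints: Sequence[tuple],
    source: tuple,
) -> DirectionalityStats:
    """Circular summary of trajectory endpoints relative to their source.

    Mean bearing and resultant length R (1 = perfectly aligned endpoints,
    ~0 = isotropic scatter) of the endpoint bearings, plus mean great-circle
    displacement.  Endpoints coincident with the source contribute zero
    displacement and are excluded from the bearing statistics (their bearing
    is undefined); if all endpoints coincide with the source, R = 0.
    """
    if not endpoints:
        raise ValueError("need at least one endpoint")
    s_lat, s_lon = source
    bearings = []
    dists = []
    for lat, lon in endpoints:
        d = great_circle_km(s_lat, s_lon, lat, lon)
        dists.append(d)
        if d > 0:
            bearings.append(math.radians(initial_bearing_deg(s_lat, s_lon, lat, lon)))
    if not bearings:
        return DirectionalityStats(0.0, 0.0, float(np.mean(dists)))
    c = np.mean(np.cos(bearings))
    s = np.mean(np.sin(bearings))
    r = float(math.hypot(c, s))
    mean_bearing = math.degrees(math.atan2(s, c)) % 360.0
    return DirectionalityStats(mean_bearing, r, float(np.mean(dists)))


def trajectories_to_geojson(trajectories: Sequence[Trajectory]) -> str:
    """GeoJSON FeatureCollection of trajectory LineStrings."""
    return json.dumps(
        {
            "type": "FeatureCollection",
            "features": [t.to_geojson() for t in trajectories],
        }
    )
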