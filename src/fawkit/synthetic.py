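"""Synthetic data generators with known ground truth.

The study designs this package re-implements rest on three external data
streams that are not publicly deposited: field-collected specimen sequences,
gridded historical climatology, and gridded wind reanalysis.  This module
generates controllable stand-ins for all three so that every downstream stage
(marker typing, profile comparison, climate suitability, trajectory
projection) can be scored against exact ground truth.

All randomness flows from one explicit integer seed per call; there is no
global random state, and identical spec + seed gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from . import refseqs
from .iupac import merge_sequences
from .markers import ReferenceHaplotypeSet, SpecimenSequence

__all__ = [
    "PopulationSpec",
    "ClimateScenario",
    "WindFieldSpec",
    "gen_population_sequences",
    "gen_climate",
    "gen_climate_grid",
    "gen_windfield",
    "gen_wind_nights",
    "CSH_LABELS",
]

#: the COIB haplotype label universe (CSh3 retained even though rarely seen)
CSH_LABELS = ("CSh1", "CSh2", "CSh3", "CSh4")

WEEKS_PER_YEAR = 52  # 7-day blocks; day 365 discarded (weekly model time step)


def _check_freqs(freqs: Mapping[str, float], what: str) -> None:
    if not freqs:
        raise ValueError(f"{what}: empty frequency map")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what}: frequencies sum to {total}, not 1")
    if any(f < 0 for f in freqs.values()):
        raise ValueError(f"{what}: negative frequency")


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth composition of one synthetic collection.

    ``heterozygosity_rate`` is the probability that a Tpi specimen carries two
    distinct intron haplotypes (Tpi is Z-linked, so ZZ males are diploid for
    it); its consensus read then shows IUPAC ambiguity codes, or collapses at
    a length difference.
    """

    collection_id: str
    n: int
    csh_freqs: Mapping[str, float]
    tpi_hap_freqs: Mapping[str, float]
    heterozygosity_rate: float = 0.0
    seed: int = 0
    year: int = 2016
    state: str = ""
    country: str = "Mexico"

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0.0 <= self.heterozygosity_rate <= 1.0:
            raise ValueError("heterozygosity_rate must be in [0, 1]")
        _check_freqs(self.csh_freqs, "csh_freqs")
        _check_freqs(self.tpi_hap_freqs, "tpi_hap_freqs")


def gen_population_sequences(
    spec: PopulationSpec,
    ref_coib: str | None = None,
    ref_tpi: str | None = None,
    tpi_hap_library: ReferenceHaplotypeSet | None = None,
) -> list[SpecimenSequence]:
    """Simulate one collection: n COI and n Tpi specimen sequences.

    Each specimen's realized haplotype is recorded in ``metadata`` as ground
    truth (``true_csh``, ``true_tpi_haps``, ``true_strain``, ``heterozygous``)
    so downstream classification can be scored exactly.  With probability
    ``heterozygosity_rate`` a Tpi specimen is built from two distinct intron
    haplotypes merged position-wise into IUPAC ambiguity codes; a length
    difference truncates the merged read at the first discordant position,
    mimicking chromatogram collapse.

    ``ref_coib``/``ref_tpi`` accept drop-in replacement amplicon backbones;
    the shipped synthetic references are used by default.
    """
    if tpi_hap_library is None:
        tpi_hap_library = refseqs.TPI_HAPLOTYPE_LIBRARY
    known = set(tpi_hap_library.labels)
    unknown = set(spec.tpi_hap_freqs) - known
    if unknown:
        raise KeyError(f"unknown Tpi haplotype labels: {sorted(unknown)}")
    csh_map = {
        "CSh1": ("A", "A"), "CSh2": ("A", "G"),
        "CSh3": ("G", "A"), "CSh4": ("G", "G"),
        "R-strain": ("T", "A"),
    }
    bad = set(spec.csh_freqs) - set(csh_map)
    if bad:
        raise KeyError(f"unknown CSh labels: {sorted(bad)}")

    rng = np.random.default_rng(spec.seed)
    csh_labels = sorted(spec.csh_freqs)
    csh_p = np.array([spec.csh_freqs[l] for l in csh_labels])
    tpi_labels = sorted(spec.tpi_hap_freqs)
    tpi_p = np.array([spec.tpi_hap_freqs[l] for l in tpi_labels])

    def make_coi(i: int) -> SpecimenSequence:
        label = csh_labels[rng.choice(len(csh_labels), p=csh_p)]
        amp = (
            refseqs.coi_amplicon(*csh_map[label])
            if ref_coib is None
            else _substitute_coi(ref_coib, csh_map[label])
        )
        return SpecimenSequence(
            specimen_id=f"{spec.collection_id}-{i:04d}",
            gene="COI",
            seq=amp,
            collection_id=spec.collection_id,
            year=spec.year,
            metadata={"true_csh": label,
                      "true_strain": "R" if label == "R-strain" else "C",
                      "state": spec.state, "country": spec.country},
        )

    def make_tpi(i: int) -> SpecimenSequence:
        het = rng.random() < spec.heterozygosity_rate
        lab1 = tpi_labels[rng.choice(len(tpi_labels), p=tpi_p)]
        strain = tpi_hap_library.strain_of(lab1)
        if het and len(tpi_labels) > 1:
            lab2 = lab1
            while lab2 == lab1:
                lab2 = tpi_labels[rng.choice(len(tpi_labels), p=tpi_p)]
            a = _tpi_seq(lab1, tpi_hap_library, ref_tpi)
            b = _tpi_seq(lab2, tpi_hap_library, ref_tpi)
            truncated = len(a) != len(b)
            if truncated:
                cut = next(
                    (k for k, (x, y) in enumerate(zip(a, b)) if x != y),
                    min(len(a), len(b)),
                )
                seq = a[:cut]
            else:
                seq = merge_sequences(a, b)
            meta = {"true_tpi_haps": tuple(sorted((lab1, lab2))),
                    "heterozygous": True, "truncated": truncated}
        else:
            seq = _tpi_seq(lab1, tpi_hap_library, ref_tpi)
            meta = {"true_tpi_haps": (lab1,), "heterozygous": False,
                    "truncated": False}
        meta.update({"true_strain": strain, "state": spec.state,
                     "country": spec.country})
        return SpecimenSequence(
            specimen_id=f"{spec.collection_id}-{i:04d}",
            gene="Tpi",
            seq=seq,
            collection_id=spec.collection_id,
            year=spec.year,
            metadata=meta,
        )

    out: list[SpecimenSequence] = []
    for i in range(spec.n):
        out.append(make_coi(i))
    for i in range(spec.n):
        out.append(make_tpi(i))
    return out


def _substitute_coi(backbone: str, alleles: tuple) -> str:
    seq = list(backbone)
    seq[refseqs.COI_SITE_OFFSETS["mCOI1164D"]] = alleles[0]
    seq[refseqs.COI_SITE_OFFSETS["mCOI1287R"]] = alleles[1]
    return "".join(seq)


def _tpi_seq(label: str, library: ReferenceHaplotypeSet, ref_tpi: str | None) -> str:
    intron = library.sequence_of(label)
    strain = library.strain_of(label)
    if ref_tpi is not None:
        start, end = refseqs.TPI_INTRON_SPAN
        return ref_tpi[:start] + intron + ref_tpi[end:]
    return refseqs.tpi_amplicon(intron, strain)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------


@dataclass
class ClimateScenario:
    """A 52-week climate series (optionally a lat/lon grid of them).

    ``weekly`` has columns week (1..52), tmin_c, tmax_c, rain_mm and an
    optional soil_moisture column (fraction of bucket capacity).  When
    soil_moisture is present the suitability engine uses it directly instead
    of running the rainfall bucket — this is how controlled scenarios pin the
    moisture index.
    """

    name: str
    weekly: pd.DataFrame | None = None
    grid: xr.Dataset | None = None
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.weekly is not None:
            df = self.weekly
            if len(df) != WEEKS_PER_YEAR:
                raise ValueError(f"expected {WEEKS_PER_YEAR} weeks, got {len(df)}")
            if (df["tmin_c"] > df["tmax_c"]).any():
                raise ValueError("Tmin > Tmax in some week")
            if (df["rain_mm"] < 0).any():
                raise ValueError("negative rainfall")


_SCENARIOS = ("incubator", "cold", "arid", "seasonal", "custom")


def gen_climate(
    name: str,
    seed: int = 0,
    mean_temp: float = 20.0,
    amplitude: float = 10.0,
    noise_sd: float = 0.5,
    diurnal_range: float = 8.0,
) -> ClimateScenario:
    """Generate a named 52-week climate scenario.

    * ``incubator`` — constant 27 °C mean, soil moisture pinned at 1.0:
      optimal temperature and moisture year-round, zero stress.
    * ``cold`` — constant 5 °C mean: below the 12 °C development threshold
      every week, so the temperature index is 0 all year and cold stress
      accumulates.
    * ``arid`` — optimal temperatures but zero rainfall: the soil-moisture
      bucket drains and dry stress accumulates.
    * ``seasonal`` — sinusoidal mean temperature (``mean_temp`` ±
      ``amplitude``) plus seeded Gaussian noise, seasonal rainfall.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {_SCENARIOS}")
    weeks = np.arange(1, WEEKS_PER_YEAR + 1)
    rng = np.random.default_rng(seed)
    half = diurnal_range / 2.0
    sm = None
    if name == "incubator":
        mean = np.full(WEEKS_PER_YEAR, 27.0)
        rain = np.full(WEEKS_PER_YEAR, 60.0)
        sm = np.full(WEEKS_PER_YEAR, 1.0)
    elif name == "cold":
        mean = np.full(WEEKS_PER_YEAR, 5.0)
        rain = np.full(WEEKS_PER_YEAR, 40.0)
        sm = np.full(WEEKS_PER_YEAR, 1.0)
    elif name == "arid":
        mean = np.full(WEEKS_PER_YEAR, 27.0)
        rain = np.zeros(WEEKS_PER_YEAR)
    elif name == "seasonal":
        mean = (
            mean_temp
            + amplitude * np.sin(2 * np.pi * (weeks - 13) / WEEKS_PER_YEAR)
            + (rng.normal(0, noise_sd, WEEKS_PER_YEAR) if noise_sd > 0 else 0.0)
        )
        # rainfall in phase with temperature, sized so the annual water balance
        # of the single-bucket soil model stays mid-range rather than pinning
        # at a clamp boundary
        rain = np.clip(
            12 + 8 * np.sin(2 * np.pi * (weeks - 13) / WEEKS_PER_YEAR)
            + (rng.normal(0, 3 * noise_sd, WEEKS_PER_YEAR) if noise_sd > 0 else 0.0),
            0, None,
        )
    else:  # custom: flat series at the requested mean, caller edits afterwards
        mean = np.full(WEEKS_PER_YEAR, float(mean_temp))
        rain = np.full(WEEKS_PER_YEAR, 40.0)
    df = pd.DataFrame(
        {"week": weeks, "tmin_c": mean - half, "tmax_c": mean + half,
         "rain_mm": rain}
    )
    if sm is not None:
        df["soil_moisture"] = sm
    scenario = ClimateScenario(name=name, weekly=df,
                               params={"seed": seed, "mean_temp": mean_temp,
                                       "amplitude": amplitude})
    scenario.validate()
    return scenario


def gen_climate_grid(
    nlat: int = 8,
    nlon: int = 6,
    lat0: float = 15.0,
    lat1: float = 32.0,
    lon0: float = -110.0,
    lon1: float = -92.0,
    temp_south: float = 26.0,
    temp_north: float = 6.0,
    seed: int = 0,
) -> xr.Dataset:
    """A latitude-gradient climate grid: warm lowland south, cold north.

    Emulates the qualitative structure behind continental suitability maps —
    a monotone south-to-north cooling so cold stress rises with latitude and
    year-round suitability is confined to the warm end.
    """
    lats = np.linspace(lat0, lat1, nlat)
    lons = np.linspace(lon0, lon1, nlon)
    weeks = np.arange(1, WEEKS_PER_YEAR + 1)
    frac = (lats - lat0) / (lat1 - lat0)
    mean_by_lat = temp_south + frac * (temp_north - temp_south)
    seasonal = 6.0 * np.sin(2 * np.pi * (weeks - 13) / WEEKS_PER_YEAR)
    tmean = mean_by_lat[:, None, None] + seasonal[None, None, :]
    tmean = np.broadcast_to(tmean, (nlat, nlon, WEEKS_PER_YEAR)).copy()
    rain = np.full((nlat, nlon, WEEKS_PER_YEAR), 50.0)
    sm = np.full((nlat, nlon, WEEKS_PER_YEAR), 1.0)
    return xr.Dataset(
        {
            "tmin_c": (("lat", "lon", "week"), tmean - 4.0),
            "tmax_c": (("lat", "lon", "week"), tmean + 4.0),
            "rain_mm": (("lat", "lon", "week"), rain),
            "soil_moisture": (("lat", "lon", "week"), sm),
        },
        coords={"lat": lats, "lon": lons, "week": weeks},
        attrs={"seed": seed},
    )


# ---------------------------------------------------------------------------
# wind
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindFieldSpec:
    """Specification of a synthetic gridded wind field.

    ``bearing`` is the direction the wind blows *toward*, in degrees
    clockwise from north (bearing 90 → wind toward the east: u > 0, v = 0).
    ``directional_concentration`` is a von Mises κ controlling night-to-night
    bearing scatter in the ``seasonal_mean`` pattern (κ → ∞ is a constant
    bearing, κ = 0 is isotropic).
    """

    pattern: str = "uniform"  # uniform | rotational | seasonal_mean
    speed: float = 5.0  # m/s
    bearing: float = 0.0  # degrees from north, blowing toward
    directional_concentration: float = 4.0
    lat0: float = 20.0
    lat1: float = 32.0
    lon0: float = -104.0
    lon1: float = -92.0
    n_lat: int = 25
    n_lon: int = 25
    duration_h: float = 12.0
    step_min: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in ("uniform", "rotational", "seasonal_mean"):
            raise ValueError(f"unknown wind pattern {self.pattern!r}")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.n_lat < 2 or self.n_lon < 2:
            raise ValueError("grid must have at least 2 nodes per axis")
        if self.lat1 <= self.lat0 or self.lon1 <= self.lon0:
            raise ValueError("grid extent must be positive")


def _bearing_uv(speed: float, bearing_deg: float) -> tuple[float, float]:
    rad = math.radians(bearing_deg)
    return speed * math.sin(rad), speed * math.cos(rad)


def gen_windfield(spec: WindFieldSpec, bearing: float | None = None) -> xr.Dataset:
    """One night's gridded wind field (u, v in m/s; time in hours from dusk).

    * ``uniform`` — identical (u, v) at every node and time step.
    * ``rotational`` — solid-body rotation about the grid centre at angular
      speed such that the rim of the grid moves at ``spec.speed``; the exact
      centre is a fixed point with zero wind.
    * ``seasonal_mean`` — uniform field whose bearing is drawn per night from
      a von Mises distribution around ``spec.bearing`` (see
      :func:`gen_wind_nights`); for a single call the mean bearing is used
      unless ``bearing`` overrides it.
    """
    lats = np.linspace(spec.lat0, spec.lat1, spec.n_lat)
    lons = np.linspace(spec.lon0, spec.lon1, spec.n_lon)
    n_steps = int(round(spec.duration_h * 60.0 / spec.step_min)) + 1
    times = np.linspace(0.0, spec.duration_h, n_steps)
    shape = (len(times), len(lats), len(lons))
    if spec.pattern == "rotational":
        lat_c = 0.5 * (spec.lat0 + spec.lat1)
        lon_c = 0.5 * (spec.lon0 + spec.lon1)
        # metres offset from centre on the local tangent plane
        r_earth = 6371000.0
        dy = (lats[:, None] - lat_c) * np.pi / 180.0 * r_earth
        dx = (lons[None, :] - lon_c) * np.pi / 180.0 * r_earth * np.cos(
            np.radians(lat_c)
        )
        rmax = np.hypot(dx, dy).max()
        omega = spec.speed / rmax if rmax > 0 else 0.0
        u2d = -omega * dy
        v2d = omega * dx
        u = np.broadcast_to(u2d, shape).copy()
        v = np.broadcast_to(v2d, shape).copy()
    else:
        b = spec.bearing if bearing is None else bearing
        u0, v0 = _bearing_uv(spec.speed, b)
        u = np.full(shape, u0)
        v = np.full(shape, v0)
    return xr.Dataset(
        {"u_ms": (("time", "lat", "lon"), u), "v_ms": (("time", "lat", "lon"), v)},
        coords={"time": times, "lat": lats, "lon": lons},
        attrs={"pattern": spec.pattern, "speed": spec.speed,
               "bearing": spec.bearing},
    )


def gen_wind_nights(spec: WindFieldSpec, n_nights: int) -> list[xr.Dataset]:
    """Per-night wind fields; the ensemble input of the trajectory projector.

    For ``seasonal_mean`` each night's bearing is an independent von Mises
    draw around the mean bearing with concentration κ; other patterns repeat
    the same field every night.
    """
    if n_nights < 1:
        raise ValueError("need at least one night")
    if spec.pattern != "seasonal_mean":
        one = gen_windfield(spec)
        return [one] * n_nights
    rng = np.random.default_rng(spec.seed)
    kappa = spec.directional_concentration
    mu = math.radians(spec.bearing)
    if kappa >= 1e8 or kappa == np.inf:
        bearings = np.full(n_nights, spec.bearing)
    else:
        bearings = np.degrees(rng.vonmises(mu, kappa, n_nights))
    return [gen_windfield(spec, bearing=b) for b in bearings]
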