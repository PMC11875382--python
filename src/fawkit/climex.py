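"""CLIMEX-style Compare-Locations climate suitability engine.

Estimates where a semi-tropical insect such as fall armyworm can grow
seasonally or persist year-round from a 52-week climate series.  Weekly
temperature (TI) and moisture (MI) indices — trapezoids over the development
thresholds — multiply into a weekly Growth Index; its annual mean scaled to
0-100 is GI_A.  Four stress accumulators (cold, heat, dry, wet) build up
whenever climate exceeds the species' tolerance thresholds, each displayed on
a 0-1000 scale with 1000 as maximum stress.  The Ecoclimatic Index discounts
GI_A by the stresses and is gated by the degree-day requirement of a complete
generation (PDD): EI in [0, 100], 100 meaning incubator-like suitability all
year.

The shipped parameter set is the published fall armyworm parameterization
(thresholds 12/25/30/36 °C, moisture 0.15/0.8/1.5/2.0, PDD 400 °C·days,
stress thresholds/rates as published, top-up irrigation of 2.5 mm/day in
weeks with under 25 mm of rain).  The published cold-stress temperature
threshold prints as 98 °C, which is not biologically plausible; no default is
trusted, the value is a required parameter, and the preset uses 9.8 °C
(reading the printed value as a decimal-point slip).  A degree-day
cold-stress mode is available as an alternative interpretation.

The soil-moisture bucket and the multiplicative EI combination are this
package's model choices (the commercial hydrology and combination formulas
are proprietary); they are documented contracts, not published facts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import xarray as xr

from .synthetic import WEEKS_PER_YEAR, ClimateScenario

__all__ = [
    "ClimexParams",
    "SuitabilityResult",
    "FAW_PARAMS",
    "temperature_index",
    "moisture_index",
    "update_soil_moisture",
    "soil_moisture_series",
    "growth_index",
    "accumulate_stress",
    "degree_days",
    "ecoclimatic_index",
    "run_location",
    "run_grid",
]

STRESS_CAP = 1000.0  # display scale maximum
DAYS_PER_WEEK = 7


@dataclass(frozen=True)
class ClimexParams:
    """Species parameter block (fall armyworm values as defaults where trusted).

    Thresholds: SM0<SM1<SM2<SM3 (soil moisture, fraction of bucket capacity),
    DV0<DV1<DV2<DV3 (°C).  Stress rates are weekly accumulation magnitudes;
    published sign conventions (negative for cold/dry) are interpreted as
    magnitudes applied in the stress-increasing direction.  ``ttcs`` has no
    trusted default (the printed value is implausible) and must be supplied;
    ``cold_stress_mode`` selects between a temperature threshold ("temperature")
    and a weekly degree-day threshold ("degree_day", ``ttcs`` then in
    °C·days/week).
    """

    ttcs: float  # cold stress threshold — required, no trusted default
    sm0: float = 0.15
    sm1: float = 0.8
    sm2: float = 1.5
    sm3: float = 2.0
    dv0: float = 12.0
    dv1: float = 25.0
    dv2: float = 30.0
    dv3: float = 36.0
    thcs: float = 0.005  # cold stress rate, week^-1 (magnitude)
    tths: float = 39.0  # heat stress temperature threshold, °C
    thhs: float = 0.0025  # heat stress rate, week^-1
    smds: float = 0.1  # dry stress soil moisture threshold
    hds: float = 0.005  # dry stress rate, week^-1 (magnitude)
    smws: float = 3.0  # wet stress soil moisture threshold
    hws: float = 0.002  # wet stress rate, week^-1
    pdd: float = 400.0  # degree-days per generation, °C·days
    irrigation_topup: float = 2.5  # mm/day
    irrigation_rain_threshold: float = 25.0  # mm/week
    bucket_capacity: float = 100.0  # mm
    evap_coefficient: float = 0.6  # mm/week per °C of weekly mean above 0
    cold_stress_mode: str = "temperature"
    stress_display_scale: float = 100.0

    def __post_init__(self):
        if not self.sm0 < self.sm1 < self.sm2 < self.sm3:
            raise ValueError("require SM0 < SM1 < SM2 < SM3")
        if not self.dv0 < self.dv1 < self.dv2 < self.dv3:
            raise ValueError("require DV0 < DV1 < DV2 < DV3")
        if self.pdd <= 0:
            raise ValueError("PDD must be positive")
        for name in ("thcs", "thhs", "hds", "hws"):
            if getattr(self, name) < 0:
                raise ValueError(f"stress rate {name} must be a magnitude >= 0")
        if self.cold_stress_mode not in ("temperature", "degree_day"):
            raise ValueError("cold_stress_mode must be 'temperature' or 'degree_day'")


#: published fall armyworm parameter block; TTCS = 9.8 °C is this package's
#: reading of the implausibly printed threshold
FAW_PARAMS = ClimexParams(ttcs=9.8)


@dataclass
class SuitabilityResult:
    """Weekly indices, annual aggregates and stresses for one location."""

    ti: np.ndarray  # weekly temperature index, [0,1]
    mi: np.ndarray  # weekly moisture index, [0,1]
    gi: np.ndarray  # weekly growth index, [0,1]
    gi_a: float  # annual growth index, [0,100]
    degree_days: float  # annual °C·days above DV0
    cs: float  # cold stress, [0,1000]
    hs: float  # heat stress
    ds: float  # dry stress
    ws: float  # wet stress
    ei: float  # ecoclimatic index, [0,100]
    soil_moisture: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_row(self) -> dict:
        return {
            "GI_A": self.gi_a, "EI": self.ei, "CS": self.cs, "HS": self.hs,
            "DS": self.ds, "WS": self.ws, "DD": self.degree_days,
        }


def _trapezoid(x: np.ndarray, lo: float, opt_lo: float, opt_hi: float, hi: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    rising = (x > lo) & (x < opt_lo)
    out[rising] = (x[rising] - lo) / (opt_lo - lo)
    out[(x >= opt_lo) & (x <= opt_hi)] = 1.0
    falling = (x > opt_hi) & (x < hi)
    out[falling] = (hi - x[falling]) / (hi - opt_hi)
    return out


def temperature_index(weekly_mean_t, params: ClimexParams) -> np.ndarray:
    """Weekly temperature index: trapezoid over (DV0, DV1, DV2, DV3)."""
    return _trapezoid(np.atleast_1d(weekly_mean_t), params.dv0, params.dv1,
                      params.dv2, params.dv3)


def moisture_index(sm, params: ClimexParams) -> np.ndarray:
    """Weekly moisture index: trapezoid over (SM0, SM1, SM2, SM3)."""
    return _trapezoid(np.atleast_1d(sm), params.sm0, params.sm1,
                      params.sm2, params.sm3)


def update_soil_moisture(
    prev_sm: float,
    rain_mm: float,
    evap_mm: float,
    params: ClimexParams,
    irrigated: bool = False,
) -> float:
    """One weekly step of the single-bucket soil moisture model.

    Top-up irrigation adds 2.5 mm/day (17.5 mm/week) whenever the week's
    rainfall is under 25 mm; soil moisture is a fraction of bucket capacity,
    clamped to [0, SM3].
    """
    if rain_mm < 0:
        raise ValueError("negative rainfall")
    effective_rain = rain_mm
    if irrigated and rain_mm < params.irrigation_rain_threshold:
        effective_rain += params.irrigation_topup * DAYS_PER_WEEK
    sm = prev_sm + (effective_rain - evap_mm) / params.bucket_capacity
    return float(np.clip(sm, 0.0, params.sm3))


def soil_moisture_series(
    rain_mm: np.ndarray,
    weekly_mean_t: np.ndarray,
    params: ClimexParams,
    irrigated: bool = False,
    initial_sm: float = 0.5,
    spinup_years: int = 1,
) -> np.ndarray:
    """52-week soil moisture from the bucket model.

    Weekly evaporative demand is ``evap_coefficient`` mm per °C of weekly mean
    temperature above 0 °C.  The year is cycled ``spinup_years`` times first
    so the reported series is (approximately) the cyclic steady state rather
    than an artifact of the initial condition.
    """
    evap = params.evap_coefficient * np.clip(weekly_mean_t, 0.0, None)
    sm = initial_sm
    for _ in range(spinup_years):
        for r, e in zip(rain_mm, evap):
            sm = update_soil_moisture(sm, float(r), float(e), params, irrigated)
    out = np.empty(len(rain_mm))
    for i, (r, e) in enumerate(zip(rain_mm, evap)):
        sm = update_soil_moisture(sm, float(r), float(e), params, irrigated)
        out[i] = sm
    return out


def growth_index(ti: np.ndarray, mi: np.ndarray) -> tuple:
    """Weekly GI = TI × MI; annual GI_A = 100 × mean weekly GI."""
    ti = np.asarray(ti, dtype=float)
    mi = np.asarray(mi, dtype=float)
    if ti.shape != mi.shape:
        raise ValueError("TI and MI series must have equal length")
    gi = ti * mi
    return gi, float(100.0 * gi.mean())


def accumulate_stress(
    driver: np.ndarray,
    threshold: float,
    rate: float,
    direction: str,
    display_scale: float = 100.0,
) -> float:
    """Linear-cumulative stress accumulation with the 0-1000 display cap.

    Weekly exceedance e_w = max(0, threshold − x_w) for ``direction="below"``
    (x_w − threshold for ``"above"``).  Each week's contribution
    |rate| × e_w is weighted by the number of weeks elapsed since the year
    began — stress compounds the longer the season has run — summed, scaled
    to the display range and capped at 1000.  Zero iff the threshold is never
    crossed.
    """
    x = np.asarray(driver, dtype=float)
    if direction == "below":
        e = np.clip(threshold - x, 0.0, None)
    elif direction == "above":
        e = np.clip(x - threshold, 0.0, None)
    else:
        raise ValueError("direction must be 'below' or 'above'")
    weeks_elapsed = np.arange(1, len(x) + 1, dtype=float)
    raw = float((abs(rate) * e * weeks_elapsed).sum())
    return min(display_scale * raw, STRESS_CAP)


def degree_days(weekly_mean_t: np.ndarray, dv0: float) -> float:
    """Annual degree-days above DV0; each week expands to 7 equal days."""
    t = np.asarray(weekly_mean_t, dtype=float)
    return float((np.clip(t - dv0, 0.0, None) * DAYS_PER_WEEK).sum())


def ecoclimatic_index(
    gi_a: float,
    stresses: Iterable[float],
    annual_dd: float,
    params: ClimexParams,
) -> float:
    """EI = GI_A × Π(1 − S_i/1000), zeroed when annual degree-days < PDD.

    Multiplicative stress discounting is this engine's fixed contract; any
    stress at the 1000 cap forces EI to 0, and EI can never exceed GI_A.
    """
    if annual_dd < params.pdd:
        return 0.0
    ei = gi_a
    for s in stresses:
        ei *= max(0.0, 1.0 - s / STRESS_CAP)
    return float(np.clip(ei, 0.0, 100.0))


def run_location(
    climate: ClimateScenario | pd.DataFrame,
    params: ClimexParams,
    irrigated: bool = False,
) -> SuitabilityResult:
    """Full Compare-Locations run for one 52-week climate series.

    Weekly mean temperature is (Tmin + Tmax)/2.  If the series carries a
    ``soil_moisture`` column it is used directly (controlled scenarios pin
    moisture this way); otherwise the rainfall bucket model generates it.
    """
    df = climate.weekly if isinstance(climate, ClimateScenario) else climate
    if df is None or len(df) != WEEKS_PER_YEAR:
        raise ValueError(f"climate must provide exactly {WEEKS_PER_YEAR} weeks")
    tmean = ((df["tmin_c"] + df["tmax_c"]) / 2.0).to_numpy(dtype=float)
    rain = df["rain_mm"].to_numpy(dtype=float)
    if "soil_moisture" in df.columns and df["soil_moisture"].notna().all():
        sm = df["soil_moisture"].to_numpy(dtype=float)
    else:
        sm = soil_moisture_series(rain, tmean, params, irrigated)
    ti = temperature_index(tmean, params)
    mi = moisture_index(sm, params)
    gi, gi_a = growth_index(ti, mi)
    dd = degree_days(tmean, params.dv0)
    scale = params.stress_display_scale
    if params.cold_stress_mode == "temperature":
        cs = accumulate_stress(tmean, params.ttcs, params.thcs, "below", scale)
    else:
        weekly_dd = np.clip(tmean - params.dv0, 0.0, None) * DAYS_PER_WEEK
        cs = accumulate_stress(weekly_dd, params.ttcs, params.thcs, "below", scale)
    hs = accumulate_stress(tmean, params.tths, params.thhs, "above", scale)
    ds = accumulate_stress(sm, params.smds, params.hds, "below", scale)
    ws = accumulate_stress(sm, params.smws, params.hws, "above", scale)
    ei = ecoclimatic_index(gi_a, (cs, hs, ds, ws), dd, params)
    return SuitabilityResult(
        ti=ti, mi=mi, gi=gi, gi_a=gi_a, degree_days=dd,
        cs=cs, hs=hs, ds=ds, ws=ws, ei=ei, soil_moisture=sm,
    )


def run_grid(
    grid: xr.Dataset,
    params: ClimexParams,
    irrigated: bool = False,
) -> xr.Dataset:
    """Map :func:`run_location` over every cell of a climate grid.

    Cells are independent (no spatial smoothing).  Returns a Dataset with
    GI_A, EI, CS, HS, DS, WS and DD per (lat, lon).
    """
    lats = grid["lat"].values
    lons = grid["lon"].values
    fields = {k: np.zeros((len(lats), len(lons))) for k in
              ("GI_A", "EI", "CS", "HS", "DS", "WS", "DD")}
    for i in range(len(lats)):
        for j in range(len(lons)):
            cols = {
                "week": grid["week"].values,
                "tmin_c": grid["tmin_c"].values[i, j],
                "tmax_c": grid["tmax_c"].values[i, j],
                "rain_mm": grid["rain_mm"].values[i, j],
            }
            if "soil_moisture" in grid:
                cols["soil_moisture"] = grid["soil_moisture"].values[i, j]
            res = run_location(pd.DataFrame(cols), params, irrigated)
            row = res.as_row()
            for k in fields:
                fields[k][i, j] = row[k]
    return xr.Dataset(
        {k: (("lat", "lon"), v) for k, v in fields.items()},
        coords={"lat": lats, "lon": lons},
    )
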