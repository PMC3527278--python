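"""Daily outdoor drivers and indoor exposures.

Outdoor weather (temperature, RH, NO2, PM2.5) is generated as seasonal
sinusoids with day-to-day noise for a Boston-like climate, or can be imported
from CSV.  Indoor combustion-pollutant concentrations come from a steady-state
one-compartment box model; indoor humidity from a moisture mass balance; mold
growth from a daily-stepped index model for wooden surfaces (pine-sapwood
parameterization), whose 2/4 thresholds define the reversible/permanent
"damp" classification; cockroach allergen from truncated lognormal
distributions keyed to the household's holes x housekeeping category.

All per-day operations broadcast over numpy arrays, so a household's whole
multi-year exposure series is produced in vectorized form by
:func:`simulate_household_environment`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    AllergenParams,
    BoxModelParams,
    ClimateParams,
    MoistureParams,
    MoldParams,
    ScenarioConfig,
)
from .cohort import Household

__all__ = [
    "SEASON_NAMES",
    "season_of_month",
    "generate_weather",
    "weather_to_csv",
    "weather_from_csv",
    "effective_ach",
    "indoor_no2",
    "indoor_pm25",
    "indoor_rh",
    "saturation_humidity_gm3",
    "critical_rh",
    "mold_growth_rate",
    "update_mold_index",
    "simulate_mold",
    "classify_damp",
    "sample_cockroach",
    "effective_exposure",
    "effective_allergen",
    "HouseholdEnvironment",
    "simulate_household_environment",
]

SEASON_NAMES = ("winter", "spring", "summer", "fall")
_MONTH_TO_SEASON = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3, 0])  # index by month 1..12

#: cumulative days at the start of each month (non-leap calendar year)
_MONTH_STARTS = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30])


def season_of_month(month) -> np.ndarray | int:
    """Meteorological season index (0=winter, 1=spring, 2=summer, 3=fall)."""
    return _MONTH_TO_SEASON[np.asarray(month)] if np.ndim(month) else int(_MONTH_TO_SEASON[month])


def _day_of_year(day_index: np.ndarray) -> np.ndarray:
    return day_index % 365 + 1


def _month_of_doy(doy: np.ndarray) -> np.ndarray:
    return np.searchsorted(_MONTH_STARTS, doy, side="right")


def generate_weather(rng: np.random.Generator, n_days: int,
                     climate: ClimateParams | None = None) -> pd.DataFrame:
    """Synthetic daily weather series starting January 1.

    Columns: ``day`` (0-based), ``doy``, ``month``, ``season`` (index),
    ``temp_f`` (24-h mean), ``rh_pct``, ``no2_ppb``, ``pm25_ugm3``.
    Deterministic under a fixed generator state.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    c = climate or ClimateParams()
    day = np.arange(n_days)
    doy = _day_of_year(day)
    # +1 in summer, -1 in winter
    seasonal = -np.cos(2.0 * np.pi * (doy - c.coldest_doy) / 365.25)
    temp = c.temp_mean_f + c.temp_amplitude_f * seasonal + rng.normal(0.0, c.temp_noise_sd_f, n_days)
    rh = c.rh_mean + c.rh_amplitude * seasonal + rng.normal(0.0, c.rh_noise_sd, n_days)
    rh = np.clip(rh, 15.0, 100.0)
    no2 = c.no2_mean - c.no2_amplitude * seasonal + rng.normal(0.0, c.no2_noise_sd, n_days)
    no2 = np.clip(no2, 1.0, None)
    pm = c.pm25_mean + c.pm25_amplitude * seasonal + rng.normal(0.0, c.pm25_noise_sd, n_days)
    pm = np.clip(pm, 2.0, None)
    month = _month_of_doy(doy)
    return pd.DataFrame({
        "day": day,
        "doy": doy,
        "month": month,
        "season": _MONTH_TO_SEASON[month],
        "temp_f": temp,
        "rh_pct": rh,
        "no2_ppb": no2,
        "pm25_ugm3": pm,
    })


def weather_to_csv(weather: pd.DataFrame, path) -> None:
    weather.to_csv(path, index=False)


def weather_from_csv(path) -> pd.DataFrame:
    """Load a measured or exported weather series.

    Requires columns day, temp_f, rh_pct, no2_ppb, pm25_ugm3; doy/month/season
    are derived if absent.
    """
    df = pd.read_csv(path)
    required = {"day", "temp_f", "rh_pct", "no2_ppb", "pm25_ugm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    if "doy" not in df.columns:
        df["doy"] = _day_of_year(df["day"].to_numpy())
    if "month" not in df.columns:
        df["month"] = _month_of_doy(df["doy"].to_numpy())
    if "season" not in df.columns:
        df["season"] = _MONTH_TO_SEASON[df["month"].to_numpy()]
    return df


# ---------------------------------------------------------------------------
# one-compartment box model
# ---------------------------------------------------------------------------

def effective_ach(household: Household, box: BoxModelParams | None = None) -> float:
    """Effective air-exchange rate (/h): leakiness x stack effect + fan boost."""
    box = box or BoxModelParams()
    base = {"I": box.ach_leak_1, "II": box.ach_leak_2, "III": box.ach_leak_3}[household.leakiness]
    level = (box.upper_level_ach_factor if household.apartment_level == "upper"
             else box.lower_level_ach_factor)
    ach = base * level
    if household.fans_operational:
        ach += box.fan_ach_boost
    return ach


def indoor_no2(household: Household, outdoor_no2, outdoor_temp_f,
               box: BoxModelParams | None = None, source_noise=1.0):
    """24-h average indoor NO2 (ppb), steady-state box model.

    ``infiltration * outdoor + sources / (V * a_eff)`` with a gas-stove
    cooking source every day the home has a gas stove, plus an oven source on
    supplemental-heat days (24-h mean outdoor temperature below 32 F).
    ``source_noise`` is an optional day-to-day emission multiplier.
    """
    box = box or BoxModelParams()
    ach = effective_ach(household, box)
    source = 0.0
    if household.gas_stove:
        source = source + box.stove_no2 * np.asarray(source_noise)
    if household.supplemental_heat_user:
        cold = np.asarray(outdoor_temp_f) < box.supplemental_heat_temp_f
        source = source + box.oven_no2 * cold * np.asarray(source_noise)
    return box.infiltration_no2 * np.asarray(outdoor_no2) + source / (box.volume_m3 * ach)


def indoor_pm25(household: Household, outdoor_pm25,
                box: BoxModelParams | None = None,
                cooking_factor=1.0, cooking_noise=1.0, smoking_noise=1.0):
    """24-h average indoor PM2.5 (ug/m3), steady-state box model.

    Sources: cooking (all homes; ``cooking_factor`` is the between-home
    intensity multiplier) and environmental tobacco smoke (light or heavy
    smoker), both with optional day-to-day multipliers.
    """
    box = box or BoxModelParams()
    ach = effective_ach(household, box)
    source = box.cooking_pm25 * np.asarray(cooking_factor) * np.asarray(cooking_noise)
    if household.smoker == "light":
        source = source + box.smoker_light_pm25 * np.asarray(smoking_noise)
    elif household.smoker == "heavy":
        source = source + box.smoker_heavy_pm25 * np.asarray(smoking_noise)
    return box.infiltration_pm25 * np.asarray(outdoor_pm25) + source / (box.volume_m3 * ach)


# ---------------------------------------------------------------------------
# indoor humidity and temperature
# ---------------------------------------------------------------------------

def saturation_humidity_gm3(temp_c):
    """Saturation water-vapor density (g/m3) via the Magnus formula."""
    t = np.asarray(temp_c, dtype=float)
    es_hpa = 6.112 * np.exp(17.62 * t / (243.12 + t))
    return 216.7 * es_hpa / (t + 273.15)


def indoor_rh(household: Household, outdoor_temp_f, outdoor_rh,
              box: BoxModelParams | None = None,
              moisture: MoistureParams | None = None,
              moisture_g_h: float | None = None):
    """Indoor relative humidity (%) and indoor temperature (C).

    Indoor absolute humidity = outdoor absolute humidity + occupant moisture
    generation divided by ventilation (V * a_eff); indoor temperature follows
    a heated-building comfort profile (floor 20 C, mild tracking of warm
    outdoor temperatures).  RH is bounded to [0, 100].
    """
    box = box or BoxModelParams()
    m = moisture or MoistureParams()
    g = m.moisture_median_g_h if moisture_g_h is None else moisture_g_h
    t_out_c = (np.asarray(outdoor_temp_f, dtype=float) - 32.0) / 1.8
    t_in = np.clip(m.t_in_intercept_c + m.t_in_slope * t_out_c, m.t_in_min_c, m.t_in_max_c)
    ah_out = np.asarray(outdoor_rh) / 100.0 * saturation_humidity_gm3(t_out_c)
    ach = effective_ach(household, box)
    ah_in = ah_out + g / (box.volume_m3 * ach)
    rh = np.clip(100.0 * ah_in / saturation_humidity_gm3(t_in), 0.0, 100.0)
    return rh, t_in


# ---------------------------------------------------------------------------
# mold index
# ---------------------------------------------------------------------------

def critical_rh(temp_c, mold: MoldParams | None = None):
    """Critical RH (%) above which mold can grow, as a function of temperature."""
    mold = mold or MoldParams()
    t = np.asarray(temp_c, dtype=float)
    poly = -0.00267 * t ** 3 + 0.160 * t ** 2 - 3.13 * t + 100.0
    return np.where(t <= 20.0, np.maximum(poly, mold.rh_crit_min), mold.rh_crit_min)


def _t_m_weeks(temp_c, rh, mold: MoldParams):
    """Response time (weeks) to reach mold index 1 under constant conditions."""
    return np.exp(-0.68 * np.log(temp_c) - 13.9 * np.log(rh)
                  + 0.14 * mold.wood_species - 0.33 * mold.surface_quality + 66.02)


def _t_v_weeks(temp_c, rh, mold: MoldParams):
    """Response time (weeks) to reach visual growth (index 3)."""
    return np.exp(-0.74 * np.log(temp_c) - 12.72 * np.log(rh)
                  + 0.06 * mold.wood_species + 61.50)


def mold_growth_rate(m, rh, temp_c, mold: MoldParams | None = None):
    """Daily change of the mold index under the given conditions.

    Growth (favourable: temperature in (0, 50) C and RH at or above the
    critical humidity) follows 1/(7 t_m) per day attenuated by the k1 stage
    factor above index 1 and the k2 approach to the RH-dependent maximum
    index; otherwise the index declines at a constant daily rate.
    """
    mold = mold or MoldParams()
    m = np.asarray(m, dtype=float)
    rh = np.asarray(rh, dtype=float)
    t = np.asarray(temp_c, dtype=float)
    favourable = (t > 0.1) & (t < 50.0) & (rh >= critical_rh(t, mold))
    ts = np.clip(t, 0.1, 50.0)
    rhs = np.clip(rh, 1.0, 100.0)
    tm = _t_m_weeks(ts, rhs, mold)
    tv = _t_v_weeks(ts, rhs, mold)
    base = 1.0 / (7.0 * tm)
    ratio = np.maximum(tv / tm, 1.02)
    k1 = np.where(m < 1.0, 1.0, 2.0 / (ratio - 1.0))
    x = np.clip((critical_rh(ts, mold) - rhs) / (critical_rh(ts, mold) - 100.0), 0.0, 1.0)
    m_max = mold.mmax_a + mold.mmax_b * x - mold.mmax_c * x ** 2
    k2 = np.maximum(1.0 - np.exp(2.3 * (m - m_max)), 0.0)
    return np.where(favourable, base * k1 * k2, -mold.decline_per_day)


def update_mold_index(m: float, rh: float, temp_c: float,
                      mold: MoldParams | None = None) -> float:
    """One daily Euler step of the mold index, clamped to [0, 6]."""
    mold = mold or MoldParams()
    if not mold.m_min <= m <= mold.m_max:
        raise ValueError(f"mold index must be in [{mold.m_min}, {mold.m_max}], got {m!r}")
    dm = float(mold_growth_rate(m, rh, temp_c, mold))
    return float(np.clip(m + dm, mold.m_min, mold.m_max))


def classify_damp(m: float, permanently_damp: bool,
                  mold: MoldParams | None = None) -> tuple[bool, bool]:
    """Damp/permanent state machine: damp at M >= 2, latched at M >= 4."""
    mold = mold or MoldParams()
    if not mold.m_min <= m <= mold.m_max:
        raise ValueError(f"mold index must be in [{mold.m_min}, {mold.m_max}], got {m!r}")
    permanent = permanently_damp or m >= mold.permanent_threshold
    return (m >= mold.damp_threshold) or permanent, permanent


def simulate_mold(rh: np.ndarray, temp_c: np.ndarray,
                  mold: MoldParams | None = None, m0: float = 0.0):
    """Mold-index trajectory and damp flags over a daily RH/temperature series.

    Returns ``(M, damp, permanently_damp)`` arrays.  The sequential Euler loop
    uses precomputed vector pieces (growth rates only depend on the index via
    the k1/k2 factors), so per-day work is a handful of scalar operations.
    """
    mold = mold or MoldParams()
    rh = np.asarray(rh, dtype=float)
    t = np.asarray(temp_c, dtype=float)
    n = rh.shape[0]
    favourable = (t > 0.1) & (t < 50.0) & (rh >= critical_rh(t, mold))
    ts = np.clip(t, 0.1, 50.0)
    rhs = np.clip(rh, 1.0, 100.0)
    base = 1.0 / (7.0 * _t_m_weeks(ts, rhs, mold))
    ratio = np.maximum(_t_v_weeks(ts, rhs, mold) / _t_m_weeks(ts, rhs, mold), 1.02)
    k1_post = 2.0 / (ratio - 1.0)
    rc = critical_rh(ts, mold)
    x = np.clip((rc - rhs) / (rc - 100.0), 0.0, 1.0)
    m_max_arr = mold.mmax_a + mold.mmax_b * x - mold.mmax_c * x ** 2

    m_arr = np.empty(n)
    damp = np.empty(n, dtype=bool)
    perm = np.empty(n, dtype=bool)
    m = float(m0)
    p = False
    lo, hi = mold.m_min, mold.m_max
    decline = mold.decline_per_day
    d_thr, p_thr = mold.damp_threshold, mold.permanent_threshold
    fav = favourable.tolist()
    base_l = base.tolist()
    k1_l = k1_post.tolist()
    mmax_l = m_max_arr.tolist()
    for i in range(n):
        if fav[i]:
            k1 = 1.0 if m < 1.0 else k1_l[i]
            gap = m - mmax_l[i]
            k2 = 1.0 - math.exp(2.3 * gap) if gap < 0.0 else 0.0
            m += base_l[i] * k1 * (k2 if k2 > 0.0 else 0.0)
            if m > hi:
                m = hi
        else:
            m -= decline
            if m < lo:
                m = lo
        if m >= p_thr:
            p = True
        m_arr[i] = m
        damp[i] = p or m >= d_thr
        perm[i] = p
    return m_arr, damp, perm


# ---------------------------------------------------------------------------
# cockroach allergen
# ---------------------------------------------------------------------------

def sample_cockroach(rng: np.random.Generator, category: int,
                     allergen: AllergenParams | None = None, size=None):
    """Daily Bla g 1 / Bla g 2 concentrations (U/g dust) for a household category.

    Independent lognormal draws with the category's geometric mean/GSD,
    truncated at +/- 1 SD on the log scale (all draws lie in
    [GM/GSD, GM*GSD]).
    """
    a = allergen or AllergenParams()
    if category not in (1, 2, 3):
        raise ValueError(f"unknown allergen category {category!r}")
    i = category - 1
    z1 = _truncated_standard_normal(rng, a.truncation_sd, size)
    z2 = _truncated_standard_normal(rng, a.truncation_sd, size)
    blag1 = a.blag1_gm[i] * a.blag1_gsd[i] ** z1
    blag2 = a.blag2_gm[i] * a.blag2_gsd[i] ** z2
    return blag1, blag2


def _truncated_standard_normal(rng: np.random.Generator, bound: float, size):
    """Standard normal truncated to [-bound, bound] via inverse-CDF sampling."""
    from scipy.stats import truncnorm
    u = rng.random(size)
    return truncnorm.ppf(u, -bound, bound)


# ---------------------------------------------------------------------------
# effective (time-weighted) exposure
# ---------------------------------------------------------------------------

def effective_exposure(indoor, outdoor, time_indoors: float = 0.7):
    """Time-activity weighting for pollutants present indoors and outdoors."""
    return time_indoors * np.asarray(indoor) + (1.0 - time_indoors) * np.asarray(outdoor)


def effective_allergen(indoor, time_indoors: float = 0.7):
    """Time-activity weighting for allergens (no exposure away from home)."""
    return time_indoors * np.asarray(indoor)


# ---------------------------------------------------------------------------
# full household series
# ---------------------------------------------------------------------------

@dataclass
class HouseholdEnvironment:
    """Daily indoor environment and effective exposures for one household."""

    no2: np.ndarray  # indoor, ppb
    pm25: np.ndarray  # indoor, ug/m3
    rh: np.ndarray  # indoor, %
    temp_c: np.ndarray  # indoor, C
    mold_index: np.ndarray
    damp: np.ndarray  # bool
    permanently_damp: np.ndarray  # bool
    blag1: np.ndarray  # U/g
    blag2: np.ndarray  # U/g
    eff_no2: np.ndarray
    eff_pm25: np.ndarray
    eff_blag1: np.ndarray
    eff_blag2: np.ndarray


def simulate_household_environment(rng: np.random.Generator, household: Household,
                                   weather: pd.DataFrame,
                                   cfg: ScenarioConfig) -> HouseholdEnvironment:
    """Generate the full daily environment series for one household."""
    n = len(weather)
    box = cfg.box
    temp_f = weather["temp_f"].to_numpy()
    rh_out = weather["rh_pct"].to_numpy()
    no2_out = weather["no2_ppb"].to_numpy()
    pm_out = weather["pm25_ugm3"].to_numpy()

    def _lognoise(sigma: float, size: int) -> np.ndarray:
        # unit-mean lognormal day-to-day multiplier
        return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size))

    no2_noise = _lognoise(box.no2_source_day_sigma, n)
    cook_noise = _lognoise(box.pm25_source_day_sigma, n)
    smoke_noise = _lognoise(box.pm25_source_day_sigma, n)
    cook_home = float(np.exp(rng.normal(-0.5 * box.cooking_home_sigma ** 2,
                                        box.cooking_home_sigma)))
    moisture_g = float(cfg.moisture.moisture_median_g_h
                       * np.exp(rng.normal(0.0, cfg.moisture.moisture_sigma)))

    no2 = indoor_no2(household, no2_out, temp_f, box, source_noise=no2_noise)
    pm25 = indoor_pm25(household, pm_out, box, cooking_factor=cook_home,
                       cooking_noise=cook_noise, smoking_noise=smoke_noise)
    rh_in, t_in = indoor_rh(household, temp_f, rh_out, box, cfg.moisture,
                            moisture_g_h=moisture_g)
    t_in = np.broadcast_to(np.asarray(t_in, dtype=float), (n,)).copy()
    # mold-prone surfaces see a buffered humidity (hygroscopic storage)
    bd = cfg.moisture.buffering_days
    rh_surface = (pd.Series(rh_in).rolling(bd, min_periods=1).mean().to_numpy()
                  if bd > 1 else rh_in)
    m_idx, damp, perm = simulate_mold(rh_surface, t_in, cfg.mold)
    blag1, blag2 = sample_cockroach(rng, household.allergen_category, cfg.allergen, size=n)

    ti = cfg.response.time_indoors
    return HouseholdEnvironment(
        no2=no2, pm25=pm25, rh=rh_in, temp_c=t_in, mold_index=m_idx,
        damp=damp, permanently_damp=perm, blag1=blag1, blag2=blag2,
        eff_no2=effective_exposure(no2, no2_out, ti),
        eff_pm25=effective_exposure(pm25, pm_out, ti),
        eff_blag1=effective_allergen(blag1, ti),
        eff_blag2=effective_allergen(blag2, ti),
    )
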