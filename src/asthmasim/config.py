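"""Model constants and scenario configuration.

Every coefficient of the exposure-response and outcome equations, the Table-1
population probabilities, the box-model / climate / mold parameters and the
scenario settings (cohort size, horizon, seed, intervention overrides) live in
the dataclasses below, in one auditable place.  Values fall into two groups:

* **Literature constants** -- printed in the source material the model is
  built from (Table-1 prevalences, exposure-response slopes, risk-equation
  cubics, decline schedule, infiltration factors).  These should normally not
  be changed.
* **Calibration constants** -- parameters of the one-compartment box model,
  the indoor-moisture surrogate and the synthetic weather generator.  Their
  defaults were calibrated once so that a baseline cohort reproduces the
  published indoor-concentration summaries (indoor NO2 mean 54 ppb / SD 23
  ppb, indoor PM2.5 mean 55 ug/m3 / SD 34 ug/m3, ~19% damp homes after ten
  years).  They are deliberately exposed in configuration rather than being
  buried in code.

Configurations round-trip through YAML (``parse_config`` / ``write_config``)
and support dotted-path overrides (``ScenarioConfig.with_overrides``) for
intervention scenarios, e.g. ``{"population.fans_operational": 1.0}``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "PopulationParams",
    "BoxModelParams",
    "ClimateParams",
    "MoistureParams",
    "MoldParams",
    "AllergenParams",
    "ExposureResponseParams",
    "DeclineSchedule",
    "MedicationParams",
    "RiskParams",
    "ScenarioConfig",
    "ConfigError",
    "parse_config",
    "write_config",
    "config_hash",
    "get_logger",
]

_log_configured = False


def get_logger(name: str = "asthmasim") -> logging.Logger:
    """Package logger; emits to stderr, INFO by default."""
    global _log_configured
    logger = logging.getLogger(name)
    if not _log_configured:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root = logging.getLogger("asthmasim")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
        _log_configured = True
    return logger


class ConfigError(ValueError):
    """Raised for unknown keys or malformed values in a configuration."""


@dataclass
class PopulationParams:
    """Occupant and household prevalences for the simulated population.

    Marginal probabilities for low-income multi-family (public-housing-like)
    households with an asthmatic child.  Attributes are sampled independently;
    no joint distribution is published.
    """

    male: float = 0.50
    age_min: int = 6
    age_max: int = 17
    #: White / African American / Latino / Asian
    race_probs: tuple = (0.49, 0.25, 0.15, 0.11)
    race_labels: tuple = ("white", "african_american", "latino", "asian")
    #: observed (pre-rebaseline) baseline FEV1 fraction of predicted
    baseline_fev1_mean: float = 0.884
    baseline_fev1_sd: float = 0.116
    gas_stove: float = 0.89
    supplemental_heat: float = 0.38
    below_average_housekeeping: float = 0.25
    smoker: float = 0.34
    heavy_smoker_given_smoker: float = 0.50
    upper_level: float = 0.50
    #: leakiness categories I / II / III (I = tightest, lowest air exchange)
    leakiness_probs: tuple = (0.20, 0.50, 0.30)
    fans_operational: float = 0.13
    holes_in_walls: float = 0.73
    #: category assigned to the "no holes & below-average housekeeping" cell
    #: that arises under independent sampling but has no published allergen
    #: distribution; 1 (the worst) is the conservative default.
    no_holes_below_average_category: int = 1


@dataclass
class BoxModelParams:
    """Steady-state one-compartment box model of the apartment.

    Indoor concentration = infiltration * outdoor + sum(sources) / (V * a_eff)
    where a_eff is the effective air-exchange rate (leakiness category, stack
    effect of the apartment level, and exhaust-fan boost when operational).

    Source strengths are 24-h average whole-apartment emission rates expressed
    as concentration-volume per hour (ppb*m3/h for NO2, ug/h for PM2.5); they
    are calibration constants (see module docstring).
    """

    volume_m3: float = 163.3  # 703 ft2 footprint x 2.5 m ceiling
    infiltration_no2: float = 0.58
    infiltration_pm25: float = 0.72
    #: air exchange per leakiness category, /h
    ach_leak_1: float = 0.30
    ach_leak_2: float = 0.50
    ach_leak_3: float = 0.70
    #: extra air exchange when kitchen+bathroom exhaust fans are operational, /h
    fan_ach_boost: float = 0.80
    #: mild stack-effect modifier on air exchange by apartment level
    upper_level_ach_factor: float = 1.05
    lower_level_ach_factor: float = 0.95
    #: gas-stove cooking NO2 source, ppb*m3/h (calibrated)
    stove_no2: float = 3900.0
    #: gas-oven supplemental-heat NO2 source, ppb*m3/h, active only on days
    #: with 24-h mean outdoor temperature below ``supplemental_heat_temp_f``
    oven_no2: float = 2800.0
    supplemental_heat_temp_f: float = 32.0
    #: cooking PM2.5 source, ug/h (calibrated)
    cooking_pm25: float = 3290.0
    #: environmental tobacco smoke PM2.5 sources, ug/h
    smoker_light_pm25: float = 1010.0
    smoker_heavy_pm25: float = 2960.0
    #: day-to-day lognormal variability (sigma of log) of combustion sources
    no2_source_day_sigma: float = 0.15
    pm25_source_day_sigma: float = 0.40
    #: between-home lognormal variability of cooking intensity
    cooking_home_sigma: float = 0.35


@dataclass
class ClimateParams:
    """Synthetic daily weather for a Boston-like climate.

    Seasonal sinusoids plus i.i.d. day-to-day noise; a stand-in for measured
    meteorology (a measured series can be supplied as CSV instead).  Phase:
    coldest around mid-January (day-of-year 14).
    """

    temp_mean_f: float = 51.0
    temp_amplitude_f: float = 22.0
    temp_noise_sd_f: float = 7.0
    coldest_doy: int = 14
    rh_mean: float = 65.0
    rh_amplitude: float = 6.0  # peaks in summer (moist air)
    rh_noise_sd: float = 8.0
    #: outdoor NO2 (ppb): urban background, winter-peaking
    no2_mean: float = 20.0
    no2_amplitude: float = 4.0
    no2_noise_sd: float = 6.0
    #: outdoor PM2.5 (ug/m3): summer-peaking secondary aerosol
    pm25_mean: float = 12.0
    pm25_amplitude: float = 2.0
    pm25_noise_sd: float = 5.0


@dataclass
class MoistureParams:
    """Surrogate indoor humidity model.

    Indoor absolute humidity = outdoor absolute humidity + occupant moisture
    generation G / (V * a_eff); indoor temperature follows a heated-building
    comfort profile.  G (breathing, showering, cooking, dishwashing) varies
    between households (lognormal); its median is a calibration constant tuned
    so ~19% of homes are damp after a ten-year run.
    """

    t_in_intercept_c: float = 12.0
    t_in_slope: float = 0.45
    t_in_min_c: float = 20.0
    t_in_max_c: float = 26.0
    #: median household moisture generation, g/h (calibrated)
    moisture_median_g_h: float = 135.0
    #: between-home lognormal sigma of moisture generation
    moisture_sigma: float = 0.80
    #: hygroscopic buffering: trailing mean (days) of indoor RH seen by
    #: mold-prone surfaces (moisture storage in furnishings and finishes)
    buffering_days: int = 7


@dataclass
class MoldParams:
    """Daily mold-index dynamics on wooden surfaces (pine-sapwood parameters).

    The index M in [0, 6] grows when indoor RH exceeds the temperature-
    dependent critical humidity and declines otherwise; M >= 2 classifies the
    home as damp (reversible) and M >= 4 latches the damp state permanently.
    """

    wood_species: float = 0.0  # 0 = pine
    surface_quality: float = 0.0  # 0 = sawn surface
    #: M_max = a + b*x - c*x^2 with x = (RH_crit - RH) / (RH_crit - 100)
    mmax_a: float = 1.0
    mmax_b: float = 7.0
    mmax_c: float = 2.0
    #: daily decline of the index under non-growth conditions
    decline_per_day: float = 0.023
    rh_crit_min: float = 80.0
    damp_threshold: float = 2.0
    permanent_threshold: float = 4.0
    m_min: float = 0.0
    m_max: float = 6.0


@dataclass
class AllergenParams:
    """Cockroach allergen (Bla g 1 / Bla g 2) settled-dust distributions.

    Geometric mean / geometric SD (U/g dust) per household category
    (1 = holes & below-average housekeeping, 2 = holes & average-or-above,
    3 = no holes & average-or-above); daily draws are lognormal truncated at
    one SD on the log scale.
    """

    blag1_gm: tuple = (143.5, 42.7, 8.2)
    blag1_gsd: tuple = (3.6, 6.2, 14.6)
    blag2_gm: tuple = (691.4, 117.3, 21.9)
    blag2_gsd: tuple = (8.6, 9.0, 12.5)
    truncation_sd: float = 1.0


@dataclass
class ExposureResponseParams:
    """Exposure-response slopes linking daily exposures to FEV1% decrements.

    Stored as positive decrement magnitudes, percentage points of FEV1%:
    per ppb NO2, per ug/m3 PM2.5, per log10(U/g) allergen, and for damp
    housing.  The allergen slopes are on the percent scale (5.5 pp per log10
    unit); set ``allergen_printed_scale`` to use the raw printed 0.055/0.027
    reading instead (a x100 difference, see docs/methods.md).
    """

    beta_no2: float = 0.093  # pp per ppb
    beta_pm25: float = 0.077  # pp per ug/m3
    beta_blag1: float = 5.5  # pp per log10 U/g
    beta_blag2: float = 2.7  # pp per log10 U/g
    use_blag1: bool = True
    use_blag2: bool = True
    allergen_printed_scale: bool = False
    damp_effect: float = 10.6  # pp while home is damp
    #: daily random variation of FEV1% (fraction scale)
    daily_sd: float = 0.05
    #: fraction of the day spent at home indoors
    time_indoors: float = 0.7
    #: floor on allergen concentration entering log10 (keeps decrement >= 0)
    allergen_log_floor: float = 1.0
    #: risk equations valid for clamped FEV1 in this range
    fev1_valid_min: float = 0.5
    fev1_valid_max: float = 1.2
    #: optional 5-day rolling mean of combustion exposures before the
    #: decrement (source epidemiology used 5-day averages); default daily.
    pollutant_rolling_days: int = 1


@dataclass
class DeclineSchedule:
    """Long-term yearly FEV1% decline (pp/year, stored positive).

    Keyed by age group (5-10 vs 11-17), controller-medication compliance and
    whether a severe asthma-related event (SARE = hospitalization or ER visit)
    occurred within the last ``sare_window_days``.
    """

    young_base: float = 0.8
    young_sare_compliant: float = 0.8
    young_sare_noncompliant: float = 2.1
    old_base: float = 0.0
    old_sare_compliant: float = 0.3
    old_sare_noncompliant: float = 1.0
    sare_window_days: int = 1095  # 3 years
    age_group_switch: int = 11
    days_per_year: float = 365.25


@dataclass
class MedicationParams:
    """Medication prescription / compliance and baseline rebaselining."""

    #: logistic P(prescribed & taking controller) = expit(b0 + b1 * FEV1)
    pmed_intercept: float = 2.228
    pmed_slope: float = -2.854
    #: no-exposure correction added to observed baseline FEV1 (fraction)
    rebaseline_offset: float = 0.198
    fev1_cap: float = 1.20
    #: severity cutoffs (fractions): tier 1 above mild_cutoff, tier 3 below
    #: severe_cutoff, tier 2 between
    mild_cutoff: float = 0.80
    severe_cutoff: float = 0.60


@dataclass
class RiskParams:
    """Daily outcome risk equations as a function of clamped FEV1%.

    The symptom cubic is used as printed.  The serious-event, hospitalization
    and ER cubics are reconstructed as exact interpolants through the four
    (FEV1 midpoint, category probability) points, anchored to the annual base
    rates at the 0.9 reference category; the printed (rounded) cubics are kept
    for cross-checking only.
    """

    #: printed symptom-day cubic, descending powers
    symptom_cubic: tuple = (2.95, -6.93, 4.68, -0.27)
    #: FEV1 category midpoints and daily serious-event probabilities
    serious_midpoints: tuple = (0.5, 0.7, 0.9, 1.1)
    serious_probs: tuple = (0.0068, 0.0032, 0.0022, 0.0017)
    #: printed (rounded) cubics, for cross-check tests
    printed_serious_cubic: tuple = (-0.045, 0.1277, -0.1224, 0.0417)
    printed_hosp_cubic: tuple = (-0.0013, 0.0037, -0.0036, 0.0012)
    printed_er_cubic: tuple = (-0.0057, 0.0162, -0.0155, 0.0053)
    #: odds multiplier for serious events given hospitalization in the last
    #: 12 months, descending powers; 1 if no recent hospitalization
    hosp_odds_cubic: tuple = (-45.7, 129.7, -124.4, 42.4)
    hosp_window_days: int = 365
    #: annual base rates anchored at the 0.9 FEV1 category
    hosp_rate_per_year: float = 0.023
    er_rate_per_year: float = 0.1
    reference_category: int = 2  # index of the 0.9 midpoint
    #: fraction of ER visits NOT ending in admission (avoids double counting)
    er_nonadmission_factor: float = 0.92
    #: seasonal multipliers on the serious-event probability
    season_spring: float = 1.11
    season_summer: float = 0.60
    season_fall: float = 1.23
    season_winter: float = 1.05
    days_per_year: float = 365.25


@dataclass
class ScenarioConfig:
    """A complete simulation scenario: cohort, horizon, seed and parameters."""

    n_children: int = 2000
    years: float = 10.0
    seed: int = 0
    out_dir: str | None = None
    population: PopulationParams = field(default_factory=PopulationParams)
    box: BoxModelParams = field(default_factory=BoxModelParams)
    climate: ClimateParams = field(default_factory=ClimateParams)
    moisture: MoistureParams = field(default_factory=MoistureParams)
    mold: MoldParams = field(default_factory=MoldParams)
    allergen: AllergenParams = field(default_factory=AllergenParams)
    response: ExposureResponseParams = field(default_factory=ExposureResponseParams)
    decline: DeclineSchedule = field(default_factory=DeclineSchedule)
    medication: MedicationParams = field(default_factory=MedicationParams)
    risk: RiskParams = field(default_factory=RiskParams)

    # -- validation -------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_children < 1:
            raise ConfigError("n_children must be >= 1")
        if self.years < 1:
            raise ConfigError("horizon must be at least 1 year")
        p = self.population
        for name in ("male", "gas_stove", "supplemental_heat", "below_average_housekeeping",
                     "smoker", "heavy_smoker_given_smoker", "upper_level",
                     "fans_operational", "holes_in_walls"):
            v = getattr(p, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"population.{name} must be a probability in [0,1], got {v!r}")
        if abs(sum(p.leakiness_probs) - 1.0) > 1e-9:
            raise ConfigError("population.leakiness_probs must sum to 1")
        if abs(sum(p.race_probs) - 1.0) > 1e-9:
            raise ConfigError("population.race_probs must sum to 1")
        b = self.box
        if not (0.0 < b.infiltration_no2 <= 1.0 and 0.0 < b.infiltration_pm25 <= 1.0):
            raise ConfigError("infiltration factors must be in (0, 1]")
        for name in ("volume_m3", "ach_leak_1", "ach_leak_2", "ach_leak_3"):
            if getattr(b, name) <= 0:
                raise ConfigError(f"box.{name} must be positive")
        for gm, gsd in ((self.allergen.blag1_gm, self.allergen.blag1_gsd),
                        (self.allergen.blag2_gm, self.allergen.blag2_gsd)):
            if any(g <= 0 for g in gm) or any(s <= 1 for s in gsd):
                raise ConfigError("allergen GM must be > 0 and GSD > 1")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ScenarioConfig":
        return _dataclass_from_dict(cls, data, path="")

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ScenarioConfig":
        """Return a copy with dotted-path overrides applied.

        >>> cfg.with_overrides({"population.fans_operational": 1.0})
        """
        data = self.to_dict()
        for key, value in overrides.items():
            parts = key.split(".")
            node = data
            for part in parts[:-1]:
                if not isinstance(node, dict) or part not in node:
                    raise ConfigError(f"unknown override key {key!r}")
                node = node[part]
            if not isinstance(node, dict) or parts[-1] not in node:
                raise ConfigError(f"unknown override key {key!r}")
            node[parts[-1]] = value
        return ScenarioConfig.from_dict(data)


def _dataclass_from_dict(cls, data: Mapping[str, Any], path: str):
    if not isinstance(data, Mapping):
        raise ConfigError(f"expected a mapping at {path or '<root>'}, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown key {(path + '.' if path else '') + key!r}")
        f = fields[key]
        if dataclasses.is_dataclass(f.type) or (isinstance(f.default_factory, type)
                                                and dataclasses.is_dataclass(f.default_factory)):
            kwargs[key] = _dataclass_from_dict(f.default_factory, value,
                                               path=(path + "." if path else "") + key)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # malformed value types
        raise ConfigError(str(exc)) from exc


def parse_config(path: str | Path) -> ScenarioConfig:
    """Read a YAML scenario configuration with full key validation."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed configuration {path}: {exc}") from exc
    return ScenarioConfig.from_dict(data)


def write_config(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario configuration as YAML (round-trips with parse_config)."""
    data = cfg.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(_tuples_to_lists(data), fh, sort_keys=False)


def _tuples_to_lists(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def config_hash(cfg: ScenarioConfig) -> str:
    """Stable short hash of a configuration, recorded in run manifests."""
    payload = json.dumps(_tuples_to_lists(cfg.to_dict()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
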