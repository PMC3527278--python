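"""Daily lung function: exposure decrements, random variation, long-term decline.

Daily FEV1% is a normal draw centred on the child's (rebaselined) baseline
with SD 5 percentage points, minus the additive exposure decrement of the
day.  A clamped copy restricted to [0.5, 1.2] feeds the outcome risk
equations, which are only valid on that range.  The baseline itself declines
slowly: a yearly rate (converted to a daily rate over 365.25 days) selected
by age group, controller-medication compliance, and whether a severe
asthma-related event (SARE) occurred within the previous three years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import DeclineSchedule, ExposureResponseParams, MedicationParams
from .cohort import classify_severity

__all__ = [
    "LungState",
    "exposure_decrement",
    "daily_fev1",
    "clamp_fev1",
    "yearly_decline_pp",
    "daily_decline",
    "annual_review",
]


@dataclass
class LungState:
    """Evolving lung-function state of one simulated child."""

    baseline_fev1: float  # rebaselined entry baseline (fraction)
    current_baseline: float  # baseline after accumulated long-term decline
    last_sare_day: Optional[int] = None
    hospitalization_days: list = field(default_factory=list)  # rolling 12-month window
    year_start_fev1: float = 0.0
    year_fev1_sum: float = 0.0
    year_fev1_days: int = 0

    def prune_hospitalizations(self, day: int, window: int = 365) -> None:
        self.hospitalization_days = [d for d in self.hospitalization_days if day - d < window]


def exposure_decrement(eff_no2, eff_pm25, eff_blag1, eff_blag2, damp,
                       er: ExposureResponseParams | None = None):
    """Additive FEV1% decrement (percentage points) for one day's exposures.

    ``beta_no2*E_NO2 + beta_pm25*E_PM25 + beta_b1*log10(E_B1) +
    beta_b2*log10(E_B2) + damp_effect*1{damp}``; allergen concentrations are
    floored at 1 U/g before the log10 so trace levels never yield a negative
    decrement.  Broadcasts over day arrays.
    """
    er = er or ExposureResponseParams()
    e_no2 = np.asarray(eff_no2, dtype=float)
    e_pm = np.asarray(eff_pm25, dtype=float)
    e_b1 = np.asarray(eff_blag1, dtype=float)
    e_b2 = np.asarray(eff_blag2, dtype=float)
    if np.any(e_no2 < 0) or np.any(e_pm < 0) or np.any(e_b1 < 0) or np.any(e_b2 < 0):
        raise ValueError("effective exposures must be non-negative")
    scale = 0.01 if er.allergen_printed_scale else 1.0
    dec = er.beta_no2 * e_no2 + er.beta_pm25 * e_pm
    if er.use_blag1:
        dec = dec + scale * er.beta_blag1 * np.log10(np.maximum(e_b1, er.allergen_log_floor))
    if er.use_blag2:
        dec = dec + scale * er.beta_blag2 * np.log10(np.maximum(e_b2, er.allergen_log_floor))
    dec = dec + er.damp_effect * np.asarray(damp, dtype=float)
    return dec


def daily_fev1(rng: np.random.Generator, baseline: float, decrement_pp,
               er: ExposureResponseParams | None = None):
    """Daily FEV1 draw(s): Normal(baseline, 0.05) minus the decrement.

    Returns ``(raw, clamped)`` where ``clamped`` is restricted to the
    validity range of the risk equations.  ``decrement_pp`` may be an array,
    in which case one draw per day is returned.
    """
    er = er or ExposureResponseParams()
    dec = np.asarray(decrement_pp, dtype=float)
    raw = rng.normal(baseline, er.daily_sd, size=dec.shape or None) - dec / 100.0
    return raw, clamp_fev1(raw, er)


def clamp_fev1(fev1, er: ExposureResponseParams | None = None):
    """Clamp FEV1 to the risk-equation validity range [0.5, 1.2]."""
    er = er or ExposureResponseParams()
    return np.clip(fev1, er.fev1_valid_min, er.fev1_valid_max)


def yearly_decline_pp(age_years: float, compliant: bool, sare_recent: bool,
                      schedule: DeclineSchedule | None = None) -> float:
    """Yearly FEV1% decline (positive pp/year) for the child's current state.

    Children aged below the 11th birthday use the 5-10 schedule; older
    children (including those aging past 17 before exit) use the 11-17
    schedule.  A SARE within the last three years selects the steeper rates;
    three SARE-free years restore the base rate.
    """
    s = schedule or DeclineSchedule()
    if age_years < 5:
        raise ValueError(f"decline schedule defined for ages >= 5, got {age_years!r}")
    young = age_years < s.age_group_switch
    if young:
        if sare_recent:
            return s.young_sare_compliant if compliant else s.young_sare_noncompliant
        return s.young_base
    if sare_recent:
        return s.old_sare_compliant if compliant else s.old_sare_noncompliant
    return s.old_base


def daily_decline(age_years: float, compliant: bool, sare_recent: bool,
                  schedule: DeclineSchedule | None = None) -> float:
    """Daily baseline decline on the fraction scale (yearly pp / 100 / 365.25)."""
    s = schedule or DeclineSchedule()
    return yearly_decline_pp(age_years, compliant, sare_recent, s) / 100.0 / s.days_per_year


def annual_review(current_tier: int, past_year_mean_fev1: float,
                  med: MedicationParams | None = None) -> int:
    """Yearly medication review: reclassify severity from the past-year mean FEV1.

    The tier can only move toward more severe (evidence indicates declining
    or unchanging lung function in asthmatic children, so children are not
    stepped down).
    """
    if not 1 <= current_tier <= 3:
        raise ValueError(f"invalid medication tier {current_tier!r}")
    return max(current_tier, classify_severity(past_year_mean_fev1, med))
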