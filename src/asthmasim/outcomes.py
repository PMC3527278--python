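"""Daily asthma outcomes: symptom-days and serious events.

Clamped daily FEV1% drives two risk curves: a cubic for the probability of a
symptom day (used exactly as printed in the source regression) and a cubic
for the probability of a "serious asthma event" (oral steroid burst, ER
visit, or hospitalization).  The serious-event curve -- and its
hospitalization and ER components -- are reconstructed here as the unique
cubic interpolants through the four published (FEV1 category midpoint, daily
probability) points, because the printed coefficients are rounded to a
precision at which the small-probability curves lose accuracy (the printed
hospitalization cubic evaluates to 9e-6 at FEV1 0.9 instead of the intended
0.023/365.25 = 6.3e-5).  Component curves are anchored so the 0.9 category
matches the annual base rates (0.023 hospitalizations/yr, 0.1 ER visits/yr);
ER probabilities are scaled by 0.92 because 8% of ER visits end in admission
and are already counted as hospitalizations; oral steroid bursts are the
remainder.

A hospitalization in the previous 12 months raises the serious-event odds by
a cubic odds-ratio in FEV1%; a seasonal multiplier (spring 1.11, summer 0.60,
fall 1.23, winter 1.05) captures respiratory-virus and outdoor-allergen
seasonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RiskParams
from .environment import season_of_month

__all__ = ["RiskFunctions", "EventDay", "sample_day_events"]

EVENT_NONE = "none"
EVENT_HOSP = "hospitalization"
EVENT_ER = "ER"
EVENT_STEROID = "steroid_burst"


@dataclass
class EventDay:
    """Sampled outcomes of one child-day."""

    symptom: bool
    serious: bool
    event_type: str  # hospitalization | ER | steroid_burst | none
    sare: bool  # severe asthma-related event = hospitalization or ER visit
    albuterol_used: bool  # rescue inhaler taken on symptom days

    def __post_init__(self) -> None:
        assert self.serious == (self.event_type != EVENT_NONE)
        assert self.sare == (self.event_type in (EVENT_HOSP, EVENT_ER))


def _interpolating_cubic(xs, ys) -> np.ndarray:
    """Coefficients (descending powers) of the cubic through four points."""
    v = np.vander(np.asarray(xs, dtype=float), 4)
    return np.linalg.solve(v, np.asarray(ys, dtype=float))


class RiskFunctions:
    """All outcome risk equations, constructed from :class:`RiskParams`.

    Attributes ``serious_cubic``, ``hosp_cubic`` and ``er_cubic`` hold the
    refit interpolant coefficients (descending powers); the printed rounded
    versions remain available on the params object for cross-checks.
    """

    def __init__(self, risk: RiskParams | None = None):
        self.params = risk or RiskParams()
        r = self.params
        mids = np.asarray(r.serious_midpoints, dtype=float)
        probs = np.asarray(r.serious_probs, dtype=float)
        self.serious_cubic = _interpolating_cubic(mids, probs)
        ref = r.reference_category
        hosp_daily = r.hosp_rate_per_year / r.days_per_year
        er_daily = r.er_rate_per_year / r.days_per_year
        # component category probabilities proportional to the serious-event
        # profile, anchored at the reference (0.9) category
        if probs[ref] > 0:
            self.hosp_cubic = _interpolating_cubic(mids, probs * (hosp_daily / probs[ref]))
            self.er_cubic = _interpolating_cubic(mids, probs * (er_daily / probs[ref]))
        else:  # degenerate all-zero profile (used to switch events off)
            self.hosp_cubic = np.zeros(4)
            self.er_cubic = np.zeros(4)
        self._season = np.array([r.season_winter, r.season_spring,
                                 r.season_summer, r.season_fall])
        self._domain = (mids[0], 1.2)

    # -- basic curves -----------------------------------------------------
    def _check_domain(self, fev1) -> np.ndarray:
        f = np.asarray(fev1, dtype=float)
        lo, hi = self._domain
        if np.any(f < lo - 1e-12) or np.any(f > hi + 1e-12):
            raise ValueError(f"FEV1 outside risk-equation domain [{lo}, {hi}]; clamp first")
        return f

    def p_symptom_day(self, fev1):
        """Daily probability of a day with asthma symptoms (printed cubic)."""
        f = self._check_domain(fev1)
        return np.clip(np.polyval(self.params.symptom_cubic, f), 0.0, 1.0)

    def p_serious_event(self, fev1):
        """Daily probability of a serious asthma event (refit cubic)."""
        f = self._check_domain(fev1)
        return np.clip(np.polyval(self.serious_cubic, f), 0.0, 1.0)

    def season_factor(self, month):
        """Seasonal multiplier on the serious-event probability."""
        return self._season[season_of_month(month)]

    def hosp_odds_multiplier(self, fev1, hospitalized_last_12mo):
        """Odds multiplier for serious events given a recent hospitalization.

        1 with no hospitalization in the last 12 months, else the published
        odds-ratio cubic (floored at 1).
        """
        f = self._check_domain(fev1)
        odds = np.maximum(np.polyval(self.params.hosp_odds_cubic, f), 1.0)
        return np.where(np.asarray(hospitalized_last_12mo, dtype=bool), odds, 1.0)

    # -- composition ------------------------------------------------------
    def partition_probabilities(self, fev1):
        """(p_hosp, p_er_adjusted, p_steroid) summing to p_serious_event.

        ER probabilities are multiplied by 0.92 (admissions from the ER are
        counted under hospitalization); steroid bursts are the non-negative
        remainder.
        """
        f = self._check_domain(fev1)
        p_serious = self.p_serious_event(f)
        p_hosp = np.clip(np.polyval(self.hosp_cubic, f), 0.0, None)
        p_er = np.clip(np.polyval(self.er_cubic, f), 0.0, None)
        p_er_adj = self.params.er_nonadmission_factor * p_er
        p_steroid = np.maximum(p_serious - p_hosp - p_er_adj, 0.0)
        return p_hosp, p_er_adj, p_steroid

    def adjusted_serious_prob(self, fev1, month, hospitalized_last_12mo):
        """Serious-event probability with history (odds scale) and season applied."""
        p = self.p_serious_event(fev1)
        mult = self.hosp_odds_multiplier(fev1, hospitalized_last_12mo)
        odds = p / (1.0 - p) * mult
        p_adj = odds / (1.0 + odds)
        return np.clip(p_adj * self.season_factor(month), 0.0, 1.0)


def sample_day_events(rng: np.random.Generator, fev1_clamped: float, month: int,
                      recent_hosp: bool, rf: RiskFunctions | None = None) -> EventDay:
    """Sample one child-day of outcomes.

    The symptom day is an independent Bernoulli on the printed cubic; the
    serious event uses the history/season-adjusted probability, and on
    occurrence the event type is drawn proportionally to the component
    probabilities at the day's FEV1%.
    """
    rf = rf or RiskFunctions()
    symptom = bool(rng.random() < rf.p_symptom_day(fev1_clamped))
    p_adj = float(rf.adjusted_serious_prob(fev1_clamped, month, recent_hosp))
    event_type = EVENT_NONE
    if rng.random() < p_adj:
        p_hosp, p_er_adj, p_steroid = (float(x) for x in
                                       rf.partition_probabilities(fev1_clamped))
        total = p_hosp + p_er_adj + p_steroid
        u = rng.random() * total
        if u < p_hosp:
            event_type = EVENT_HOSP
        elif u < p_hosp + p_er_adj:
            event_type = EVENT_ER
        else:
            event_type = EVENT_STEROID
    return EventDay(
        symptom=symptom,
        serious=event_type != EVENT_NONE,
        event_type=event_type,
        sare=event_type in (EVENT_HOSP, EVENT_ER),
        albuterol_used=symptom,
    )
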