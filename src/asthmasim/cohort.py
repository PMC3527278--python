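"""Simulated population: households and asthmatic children.

Households carry the fixed dwelling/occupant attributes that drive indoor
exposures (gas stove, supplemental heating, housekeeping, smoking, apartment
level, envelope leakiness, exhaust fans, holes in walls, and the derived
cockroach-allergen category).  Children carry demographics, baseline lung
function, controller-medication status and a severity tier.

Two baseline FEV1 values are tracked per child:

* ``observed_fev1`` -- the raw draw from the measured distribution
  (mean 88.4%, SD 11.6%), which reflects a population already experiencing
  indoor exposures.  Severity classification and the controller-prescription
  logistic operate on this observed scale.
* ``baseline_fev1`` -- the rebaselined value (observed + 0.198, capped at
  1.20) approximating a no-exposure baseline, so that simulated exposure
  decrements are not double counted.  The lung-function engine evolves this
  value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import MedicationParams, PopulationParams

__all__ = [
    "Household",
    "ChildProfile",
    "allergen_category",
    "sample_household",
    "sample_child",
    "rebaseline_fev1",
    "p_controller",
    "prescribe_controller",
    "classify_severity",
    "cohort_frame",
]

LEAKINESS_LABELS = ("I", "II", "III")


@dataclass
class Household:
    gas_stove: bool
    supplemental_heat_user: bool
    below_average_housekeeping: bool
    smoker: str  # "none" | "light" | "heavy"
    apartment_level: str  # "upper" | "lower"
    leakiness: str  # "I" | "II" | "III"
    fans_operational: bool
    holes_in_walls: bool
    allergen_category: int  # 1 | 2 | 3

    def __post_init__(self) -> None:
        if self.smoker not in ("none", "light", "heavy"):
            raise ValueError(f"invalid smoker type {self.smoker!r}")
        if self.leakiness not in LEAKINESS_LABELS:
            raise ValueError(f"invalid leakiness {self.leakiness!r}")
        if self.allergen_category not in (1, 2, 3):
            raise ValueError(f"invalid allergen category {self.allergen_category!r}")


@dataclass
class ChildProfile:
    age_years: int
    gender: str  # "male" | "female"
    race: str
    observed_fev1: float  # raw baseline draw, fraction of predicted
    baseline_fev1: float  # rebaselined, fraction of predicted, <= 1.20
    compliant: bool
    medication_tier: int  # 1 | 2 | 3 controller medicines
    birthday_offset_days: int  # days from simulation start to next birthday
    household: Optional[Household] = None


def allergen_category(holes_in_walls: bool, below_average_housekeeping: bool,
                      no_holes_below_average_category: int = 1) -> int:
    """Cockroach-allergen category from holes x housekeeping.

    1 = holes & below-average housekeeping, 2 = holes & average-or-above,
    3 = no holes & average-or-above.  The "no holes & below-average" cell has
    no published distribution; it maps to ``no_holes_below_average_category``
    (default 1, the conservative choice).
    """
    if holes_in_walls:
        return 1 if below_average_housekeeping else 2
    return no_holes_below_average_category if below_average_housekeeping else 3


def sample_household(rng: np.random.Generator, pop: PopulationParams | None = None) -> Household:
    """Draw one household with independently sampled attributes."""
    pop = pop or PopulationParams()
    gas = rng.random() < pop.gas_stove
    heat = rng.random() < pop.supplemental_heat
    below = rng.random() < pop.below_average_housekeeping
    if rng.random() < pop.smoker:
        smoker = "heavy" if rng.random() < pop.heavy_smoker_given_smoker else "light"
    else:
        smoker = "none"
        rng.random()  # keep the draw count fixed for common random numbers
    level = "upper" if rng.random() < pop.upper_level else "lower"
    leak = LEAKINESS_LABELS[_categorical(rng, pop.leakiness_probs)]
    fans = rng.random() < pop.fans_operational
    holes = rng.random() < pop.holes_in_walls
    return Household(
        gas_stove=gas,
        supplemental_heat_user=heat,
        below_average_housekeeping=below,
        smoker=smoker,
        apartment_level=level,
        leakiness=leak,
        fans_operational=fans,
        holes_in_walls=holes,
        allergen_category=allergen_category(holes, below, pop.no_holes_below_average_category),
    )


def _categorical(rng: np.random.Generator, probs) -> int:
    u = rng.random()
    acc = 0.0
    for i, p in enumerate(probs):
        acc += p
        if u < acc:
            return i
    return len(probs) - 1


def rebaseline_fev1(raw_baseline: float, offset: float = 0.198, cap: float = 1.20) -> float:
    """Shift an observed baseline FEV1 up by the no-exposure correction.

    Returns ``min(raw_baseline + offset, cap)``; the cap (120% predicted)
    keeps values consistent with normal pulmonary function testing.
    """
    if raw_baseline <= 0:
        raise ValueError(f"baseline FEV1 must be positive, got {raw_baseline!r}")
    return min(raw_baseline + offset, cap)


def p_controller(fev1: float, med: MedicationParams | None = None) -> float:
    """Probability of being prescribed and taking a controller medication.

    Logistic in baseline FEV1 expressed as a *fraction* of predicted
    (e.g. 0.88); a percent-scale input is rejected as a unit error.
    Strictly decreasing in FEV1.
    """
    med = med or MedicationParams()
    if not 0.0 < fev1 <= 1.5:
        raise ValueError(f"FEV1 must be a fraction in (0, 1.5], got {fev1!r}")
    z = med.pmed_intercept + med.pmed_slope * fev1
    return 1.0 / (1.0 + np.exp(-z))


def prescribe_controller(rng: np.random.Generator, fev1: float,
                         med: MedicationParams | None = None) -> bool:
    """Bernoulli compliance draw from the prescription logistic."""
    return bool(rng.random() < p_controller(fev1, med))


def classify_severity(fev1: float, med: MedicationParams | None = None) -> int:
    """Severity tier (number of controller medicines) from FEV1% cutoffs.

    Tier 1 (mild) above 80%, tier 2 (moderate) 60-80%, tier 3 (severe)
    below 60%.
    """
    med = med or MedicationParams()
    if fev1 > med.mild_cutoff:
        return 1
    if fev1 >= med.severe_cutoff:
        return 2
    return 3


def sample_child(rng: np.random.Generator, household: Household,
                 pop: PopulationParams | None = None,
                 med: MedicationParams | None = None) -> ChildProfile:
    """Draw one asthmatic child living in ``household``.

    Age is uniform on {age_min..age_max}; the observed baseline FEV1 draw is
    truncated below at 0.40 (draws that low, ~1e-5 of the distribution, are
    outside the plausible range for ambulatory persistent asthmatics);
    severity and compliance are assigned from the observed value, the engine
    state from the rebaselined one.
    """
    pop = pop or PopulationParams()
    med = med or MedicationParams()
    age = int(rng.integers(pop.age_min, pop.age_max + 1))
    gender = "male" if rng.random() < pop.male else "female"
    race = pop.race_labels[_categorical(rng, pop.race_probs)]
    raw = float(rng.normal(pop.baseline_fev1_mean, pop.baseline_fev1_sd))
    raw = max(raw, 0.40)
    baseline = rebaseline_fev1(raw, med.rebaseline_offset, med.fev1_cap)
    compliant = prescribe_controller(rng, raw, med)
    tier = classify_severity(raw, med)
    birthday = int(rng.integers(1, 366))
    return ChildProfile(
        age_years=age,
        gender=gender,
        race=race,
        observed_fev1=raw,
        baseline_fev1=baseline,
        compliant=compliant,
        medication_tier=tier,
        birthday_offset_days=birthday,
        household=household,
    )


def cohort_frame(children: list[ChildProfile]) -> pd.DataFrame:
    """One row per child with all household and child fields (CSV-stable)."""
    rows = []
    for i, c in enumerate(children):
        h = c.household
        rows.append({
            "child_id": i,
            "age_years": c.age_years,
            "gender": c.gender,
            "race": c.race,
            "observed_fev1": c.observed_fev1,
            "baseline_fev1": c.baseline_fev1,
            "compliant": c.compliant,
            "medication_tier": c.medication_tier,
            "birthday_offset_days": c.birthday_offset_days,
            "gas_stove": h.gas_stove,
            "supplemental_heat_user": h.supplemental_heat_user,
            "below_average_housekeeping": h.below_average_housekeeping,
            "smoker": h.smoker,
            "apartment_level": h.apartment_level,
            "leakiness": h.leakiness,
            "fans_operational": h.fans_operational,
            "holes_in_walls": h.holes_in_walls,
            "allergen_category": h.allergen_category,
        })
    return pd.DataFrame(rows)
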