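"""Cohort engine: per-child daily loop, aggregation, scenario comparison.

Each child is simulated day by day over the horizon (default 10 years) or
until the 18th birthday, whichever comes first; the household environment is
simulated for the full horizon regardless (buildings outlive the follow-up).
The daily loop is organised as a discrete event simulation: between
structural events (a severe asthma-related event, its three-year recovery,
the expiry of the 12-month hospitalization window, the 11th birthday) the
baseline declines linearly and all daily probabilities are evaluated in
vectorized form, so the per-day cost is a few numpy operations rather than a
Python iteration.

Reproducibility: every child owns an independent RNG substream spawned from
the master seed, so results are bit-identical for a given (config, seed) and
individual children's trajectories do not depend on cohort size.  Running an
intervention scenario with the same seed reuses the same substreams (common
random numbers), which makes paired scenario comparisons low-variance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cohort import ChildProfile, cohort_frame, sample_child, sample_household
from .config import ScenarioConfig, config_hash, get_logger
from .environment import (
    HouseholdEnvironment,
    generate_weather,
    simulate_household_environment,
)
from .lung_function import annual_review, exposure_decrement, yearly_decline_pp
from .outcomes import RiskFunctions

__all__ = [
    "ChildResult",
    "CohortResult",
    "run_child",
    "run_cohort",
    "compare_scenarios",
    "calibrate_rebaseline",
    "write_outputs",
]

logger = get_logger(__name__)

FEV1_CATEGORIES = (">80%", "60-80%", "<60%")
OUTCOME_COLUMNS = ("symptom_days", "serious_events", "er_visits",
                   "hospitalizations", "steroid_bursts")


@dataclass
class ChildResult:
    """Per-child follow-up summary returned by :func:`run_child`."""

    n_days: int
    years_followed: float
    symptom_days: int
    serious_events: int
    hospitalizations: int
    er_visits: int
    steroid_bursts: int
    sares: int
    end_fev1: float  # mean daily FEV1 over the final year of follow-up
    mean_fev1: float  # mean daily FEV1 over the whole follow-up
    tier_start: int
    tier_end: int
    worsened: bool
    #: mean per-pollutant FEV1% decrements over follow-up (percentage points)
    dec_no2_pp: float
    dec_pm25_pp: float
    dec_mold_pp: float
    dec_blag1_pp: float
    dec_blag2_pp: float
    mean_eff_no2: float
    mean_eff_pm25: float
    damp_day_fraction: float

    @property
    def fev1_category(self) -> str:
        if self.end_fev1 > 0.80:
            return FEV1_CATEGORIES[0]
        if self.end_fev1 >= 0.60:
            return FEV1_CATEGORIES[1]
        return FEV1_CATEGORIES[2]


def _birthday_day(child: ChildProfile, target_age: int) -> int:
    """Day index (0-based, from simulation start) when the child turns target_age."""
    if target_age <= child.age_years:
        return 0
    return child.birthday_offset_days + round((target_age - child.age_years - 1) * 365.25)


def run_child(rng: np.random.Generator, child: ChildProfile, weather: pd.DataFrame,
              cfg: ScenarioConfig, rf: RiskFunctions | None = None,
              env: HouseholdEnvironment | None = None) -> ChildResult:
    """Simulate one child over the horizon (or until the 18th birthday).

    Daily sequence: indoor environment -> effective exposure -> FEV1%
    decrement -> daily FEV1 draw -> outcome sampling; long-term decline is
    applied to the baseline every day at the schedule's daily rate, switching
    the day after a SARE and reverting after three SARE-free years; the
    medication tier is re-evaluated at each anniversary from the past-year
    mean FEV1%.
    """
    if cfg.years < 1:
        raise ValueError("horizon must be at least 1 year")
    rf = rf or RiskFunctions(cfg.risk)
    er = cfg.response
    horizon = len(weather)
    if env is None:
        env = simulate_household_environment(rng, child.household, weather, cfg)

    n = min(horizon, _birthday_day(child, 18))
    n = max(n, 1)

    # per-pollutant decrement components (percentage points), follow-up days
    scale = 0.01 if er.allergen_printed_scale else 1.0
    dec_no2 = er.beta_no2 * _maybe_roll(env.eff_no2[:n], er.pollutant_rolling_days)
    dec_pm = er.beta_pm25 * _maybe_roll(env.eff_pm25[:n], er.pollutant_rolling_days)
    dec_b1 = (scale * er.beta_blag1
              * np.log10(np.maximum(env.eff_blag1[:n], er.allergen_log_floor))
              if er.use_blag1 else np.zeros(n))
    dec_b2 = (scale * er.beta_blag2
              * np.log10(np.maximum(env.eff_blag2[:n], er.allergen_log_floor))
              if er.use_blag2 else np.zeros(n))
    dec_mold = er.damp_effect * env.damp[:n].astype(float)
    dec = dec_no2 + dec_pm + dec_b1 + dec_b2 + dec_mold

    noise = rng.normal(0.0, er.daily_sd, n)
    u_serious = rng.random(n)
    u_type = rng.random(n)
    u_symptom = rng.random(n)
    season_mult = rf.season_factor(weather["month"].to_numpy()[:n])

    turn_11 = _birthday_day(child, 11) if child.age_years < cfg.decline.age_group_switch else 0
    sare_until = 0  # day index before which the post-SARE decline rate applies
    hosp_until = 0  # day index before which the hospitalization odds apply
    lo, hi = er.fev1_valid_min, er.fev1_valid_max
    ser_c = rf.serious_cubic
    odds_c = np.asarray(cfg.risk.hosp_odds_cubic, dtype=float)

    baseline = np.empty(n)
    b_prev = child.baseline_fev1
    counts = {"hospitalization": 0, "ER": 0, "steroid_burst": 0}
    t = 0
    while t < n:
        young = t < turn_11
        sare_active = t < sare_until
        hosp_active = t < hosp_until
        age_now = 6 if young else cfg.decline.age_group_switch  # group proxy
        rate = yearly_decline_pp(age_now, child.compliant, sare_active, cfg.decline)
        r_day = rate / 100.0 / cfg.decline.days_per_year

        seg_end = n
        if young and turn_11 < seg_end:
            seg_end = turn_11
        if sare_active and sare_until < seg_end:
            seg_end = sare_until
        if hosp_active and hosp_until < seg_end:
            seg_end = hosp_until
        seg_end = max(seg_end, t + 1)
        length = seg_end - t

        b_seg = b_prev - r_day * np.arange(1, length + 1)
        f_seg = noise[t:seg_end] + b_seg - dec[t:seg_end] / 100.0
        fc_seg = np.clip(f_seg, lo, hi)
        p = np.polyval(ser_c, fc_seg)
        if hosp_active:
            mult = np.maximum(np.polyval(odds_c, fc_seg), 1.0)
            odds = p / (1.0 - p) * mult
            p = odds / (1.0 + odds)
        p = np.clip(p * season_mult[t:seg_end], 0.0, 1.0)
        hits = u_serious[t:seg_end] < p
        idx = int(np.argmax(hits)) if hits.any() else -1

        if idx < 0:
            baseline[t:seg_end] = b_seg
            b_prev = b_seg[-1]
            t = seg_end
            continue

        te = t + idx
        baseline[t:te + 1] = b_seg[:idx + 1]
        b_prev = b_seg[idx]
        p_hosp, p_er, p_ster = (float(v) for v in
                                rf.partition_probabilities(fc_seg[idx]))
        u = u_type[te] * (p_hosp + p_er + p_ster)
        if u < p_hosp:
            counts["hospitalization"] += 1
            hosp_until = max(hosp_until, te + 1 + cfg.risk.hosp_window_days)
            sare_until = max(sare_until, te + 1 + cfg.decline.sare_window_days)
        elif u < p_hosp + p_er:
            counts["ER"] += 1
            sare_until = max(sare_until, te + 1 + cfg.decline.sare_window_days)
        else:
            counts["steroid_burst"] += 1
        t = te + 1

    f = noise + baseline - dec / 100.0
    fc = np.clip(f, lo, hi)
    p_sym = np.clip(np.polyval(np.asarray(cfg.risk.symptom_cubic, dtype=float), fc), 0.0, 1.0)
    symptom_days = int((u_symptom < p_sym).sum())

    tier = child.medication_tier
    k = 1
    while round(k * 365.25) <= n:
        start = round((k - 1) * 365.25)
        stop = round(k * 365.25)
        tier = annual_review(tier, float(f[start:stop].mean()), cfg.medication)
        k += 1

    years = n / cfg.decline.days_per_year
    sares = counts["hospitalization"] + counts["ER"]
    return ChildResult(
        n_days=n,
        years_followed=years,
        symptom_days=symptom_days,
        serious_events=sum(counts.values()),
        hospitalizations=counts["hospitalization"],
        er_visits=counts["ER"],
        steroid_bursts=counts["steroid_burst"],
        sares=sares,
        end_fev1=float(f[-min(365, n):].mean()),
        mean_fev1=float(f.mean()),
        tier_start=child.medication_tier,
        tier_end=tier,
        worsened=tier > child.medication_tier,
        dec_no2_pp=float(dec_no2.mean()),
        dec_pm25_pp=float(dec_pm.mean()),
        dec_mold_pp=float(dec_mold.mean()),
        dec_blag1_pp=float(dec_b1.mean()),
        dec_blag2_pp=float(dec_b2.mean()),
        mean_eff_no2=float(env.eff_no2[:n].mean()),
        mean_eff_pm25=float(env.eff_pm25[:n].mean()),
        damp_day_fraction=float(env.damp[:n].mean()),
    )


def _maybe_roll(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing rolling mean (window >= 2) for the 5-day-average option."""
    if window <= 1:
        return x
    s = pd.Series(x).rolling(window, min_periods=1).mean()
    return s.to_numpy()


@dataclass
class CohortResult:
    """Aggregated results of one scenario run."""

    config: ScenarioConfig
    children: pd.DataFrame  # one row per child: profile + outcomes
    summary_table: pd.DataFrame  # Table-4-shaped per-FEV1-category rates
    exposure: dict  # population exposure summaries (household-days)
    overall: dict  # headline cohort statistics


def run_cohort(cfg: ScenarioConfig) -> CohortResult:
    """Simulate the full cohort and aggregate per-FEV1-category summaries."""
    cfg.validate()
    horizon_days = round(cfg.years * 365.25)
    ss = np.random.SeedSequence(cfg.seed)
    weather_ss, cohort_ss = ss.spawn(2)
    weather = generate_weather(np.random.default_rng(weather_ss), horizon_days, cfg.climate)
    rf = RiskFunctions(cfg.risk)

    rows = []
    profile_rows = []
    no2_s1 = no2_s2 = 0.0
    pm_s1 = pm_s2 = pm_s3 = 0.0
    damp_end = 0
    blag1_med: dict[int, list] = {1: [], 2: [], 3: []}
    blag2_med: dict[int, list] = {1: [], 2: [], 3: []}
    n_days_total = 0

    child_seeds = cohort_ss.spawn(cfg.n_children)
    for i in range(cfg.n_children):
        rng = np.random.default_rng(child_seeds[i])
        household = sample_household(rng, cfg.population)
        child = sample_child(rng, household, cfg.population, cfg.medication)
        env = simulate_household_environment(rng, household, weather, cfg)
        res = run_child(rng, child, weather, cfg, rf, env=env)

        no2_s1 += float(env.no2.sum())
        no2_s2 += float((env.no2 ** 2).sum())
        pm_s1 += float(env.pm25.sum())
        pm_s2 += float((env.pm25 ** 2).sum())
        pm_s3 += float((env.pm25 ** 3).sum())
        damp_end += int(env.damp[-1])
        blag1_med[household.allergen_category].append(float(np.median(env.blag1)))
        blag2_med[household.allergen_category].append(float(np.median(env.blag2)))
        n_days_total += horizon_days

        rows.append(asdict(res) | {"child_id": i, "fev1_category": res.fev1_category})
        profile_rows.append(child)
        if (i + 1) % 1000 == 0:
            logger.info("simulated %d/%d children", i + 1, cfg.n_children)

    children = cohort_frame(profile_rows).merge(pd.DataFrame(rows), on="child_id")
    summary_table = _summary_table(children)
    exposure = _exposure_summary(no2_s1, no2_s2, pm_s1, pm_s2, pm_s3, n_days_total,
                                 damp_end, cfg.n_children, blag1_med, blag2_med)
    overall = _overall_summary(children)
    return CohortResult(cfg, children, summary_table, exposure, overall)


def _per_year(children: pd.DataFrame, col: str) -> pd.Series:
    return children[col] / children["years_followed"]


def _summary_table(children: pd.DataFrame) -> pd.DataFrame:
    """Per-FEV1-category (end of run) mean (SD) annual outcome rates."""
    rates = pd.DataFrame({c: _per_year(children, c) for c in OUTCOME_COLUMNS})
    rates["fev1_category"] = children["fev1_category"]
    rows = []
    for cat in FEV1_CATEGORIES + ("all",):
        sub = rates if cat == "all" else rates[rates["fev1_category"] == cat]
        row: dict = {"fev1_category": cat, "n_children": len(sub)}
        for c in OUTCOME_COLUMNS:
            row[f"{c}_per_year"] = sub[c].mean() if len(sub) else np.nan
            row[f"{c}_per_year_sd"] = sub[c].std(ddof=1) if len(sub) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _exposure_summary(no2_s1, no2_s2, pm_s1, pm_s2, pm_s3, n_days, damp_end,
                      n_homes, blag1_med, blag2_med) -> dict:
    no2_mean = no2_s1 / n_days
    no2_var = max(no2_s2 / n_days - no2_mean ** 2, 0.0)
    pm_mean = pm_s1 / n_days
    pm_var = max(pm_s2 / n_days - pm_mean ** 2, 0.0)
    m3 = pm_s3 / n_days - 3 * pm_mean * pm_s2 / n_days + 2 * pm_mean ** 3
    return {
        "no2_mean_ppb": no2_mean,
        "no2_sd_ppb": float(np.sqrt(no2_var)),
        "pm25_mean_ugm3": pm_mean,
        "pm25_sd_ugm3": float(np.sqrt(pm_var)),
        "pm25_skewness": float(m3 / pm_var ** 1.5) if pm_var > 0 else np.nan,
        "damp_fraction_end": damp_end / n_homes,
        "blag1_median_by_category": {k: float(np.median(v)) if v else np.nan
                                     for k, v in blag1_med.items()},
        "blag2_median_by_category": {k: float(np.median(v)) if v else np.nan
                                     for k, v in blag2_med.items()},
    }


def _overall_summary(children: pd.DataFrame) -> dict:
    cats = children["fev1_category"].value_counts(normalize=True)
    return {
        "n_children": len(children),
        "symptom_day_fraction": float(children["symptom_days"].sum()
                                      / children["n_days"].sum()),
        "serious_events_per_child_year": float(_per_year(children, "serious_events").mean()),
        "hospitalizations_per_child_year": float(_per_year(children, "hospitalizations").mean()),
        "er_visits_per_child_year": float(_per_year(children, "er_visits").mean()),
        "steroid_bursts_per_child_year": float(_per_year(children, "steroid_bursts").mean()),
        "mean_end_fev1_pct": float(children["end_fev1"].mean() * 100.0),
        "sd_end_fev1_pct": float(children["end_fev1"].std(ddof=1) * 100.0),
        "fraction_worsened_tier": float(children["worsened"].mean()),
        "fraction_compliant": float(children["compliant"].mean()),
        "fev1_category_fractions": {c: float(cats.get(c, 0.0)) for c in FEV1_CATEGORIES},
        "mean_decrement_pp": {
            "no2": float(children["dec_no2_pp"].mean()),
            "pm25": float(children["dec_pm25_pp"].mean()),
            "mold": float(children["dec_mold_pp"].mean()),
            "blag1": float(children["dec_blag1_pp"].mean()),
            "blag2": float(children["dec_blag2_pp"].mean()),
        },
    }


def compare_scenarios(baseline_cfg: ScenarioConfig, intervention_cfg: ScenarioConfig,
                      paired: bool = True) -> dict:
    """Run two scenarios and report marginal changes in exposures and outcomes.

    With ``paired=True`` (the default) both scenarios must share cohort size,
    horizon and seed, so they reuse common random numbers and the deltas are
    low-variance child-by-child contrasts.
    """
    if paired and (baseline_cfg.n_children != intervention_cfg.n_children
                   or baseline_cfg.seed != intervention_cfg.seed
                   or baseline_cfg.years != intervention_cfg.years):
        raise ValueError("paired comparison requires matching cohort size, years and seed")
    base = run_cohort(baseline_cfg)
    interv = run_cohort(intervention_cfg)

    def _delta(b: float, v: float) -> dict:
        return {"baseline": b, "intervention": v, "change": v - b,
                "pct_change": (v - b) / b * 100.0 if b else np.nan}

    exposures = {k: _delta(base.exposure[k], interv.exposure[k])
                 for k in ("no2_mean_ppb", "pm25_mean_ugm3", "damp_fraction_end")}
    exposures["blag1_median_by_category"] = {
        "baseline": base.exposure["blag1_median_by_category"],
        "intervention": interv.exposure["blag1_median_by_category"],
    }
    outcome_keys = ("symptom_day_fraction", "serious_events_per_child_year",
                    "er_visits_per_child_year", "hospitalizations_per_child_year",
                    "steroid_bursts_per_child_year", "mean_end_fev1_pct",
                    "fraction_worsened_tier")
    outcomes = {k: _delta(base.overall[k], interv.overall[k]) for k in outcome_keys}
    return {"exposures": exposures, "outcomes": outcomes,
            "baseline": base, "intervention": interv}


def calibrate_rebaseline(cfg: ScenarioConfig) -> float:
    """Recompute the no-exposure rebaselining offset by paired simulation.

    Runs the scenario with and without exposure effects (all response
    coefficients zeroed) under common random numbers and returns the mean
    decrease in daily FEV1% attributable to the environment (as a fraction,
    e.g. 0.198).  With all betas already zero the offset is 0.
    """
    no_exposure = cfg.with_overrides({
        "response.beta_no2": 0.0,
        "response.beta_pm25": 0.0,
        "response.use_blag1": False,
        "response.use_blag2": False,
        "response.damp_effect": 0.0,
    })
    exposed = run_cohort(cfg)
    clean = run_cohort(no_exposure)
    return float(clean.children["mean_fev1"].mean() - exposed.children["mean_fev1"].mean())


def write_outputs(result: CohortResult, out_dir: str | Path) -> dict:
    """Write cohort CSVs and a run manifest; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "children": out / "children.csv",
        "summary": out / "summary.csv",
        "overall": out / "overall.json",
        "manifest": out / "manifest.json",
    }
    result.children.to_csv(paths["children"], index=False)
    result.summary_table.to_csv(paths["summary"], index=False)
    with open(paths["overall"], "w") as fh:
        json.dump({"overall": result.overall, "exposure": result.exposure}, fh, indent=2)
    manifest = {
        "seed": result.config.seed,
        "n_children": result.config.n_children,
        "years": result.config.years,
        "version": _version,
        "config_hash": config_hash(result.config),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
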