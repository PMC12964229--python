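"""Three-state partitioned-survival engine on weekly cycles.

State occupancy is read directly off the overall-survival and progression-
free-survival curves: PFS(t) from the PFS curve, PD(t) = OS(t) - PFS(t)
(clamped at zero), dead(t) = 1 - OS(t).  Cycles are one week long with
trapezoidal half-cycle correction; month-to-week conversion uses 30.4375
days/month and 365.25/7 weeks/year.  Costs accrue in six categories
(acquisition, administration, monitoring, adverse events, subsequent
treatment, end of life) and QALYs per component (PFS, PD, adverse-event
disutility, time-to-death disutility); everything is discounted at cycle
midpoints except one-off model-initiation items (adverse-event cost and
disutility, the molecular test), which occur at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig, Settings, Strategy
from .survival import SurvivalFunction, from_coefficients, survival_function

__all__ = [
    "Trace", "StrategyResult", "build_trace", "discount_factors",
    "ara_population_utility", "drug_cost_per_administration",
    "weekly_regimen_cost", "accrue_costs", "accrue_qalys",
    "run_strategy", "run_all", "strategy_survival_functions",
]

COST_CATEGORIES = ("acquisition", "administration", "monitoring",
                   "adverse_events", "subsequent", "end_of_life")


@dataclass
class Trace:
    """Per-cycle state occupancy of the partitioned-survival cohort."""

    weeks: np.ndarray       # cycle boundaries, 0..K
    pfs: np.ndarray         # occupancy at boundaries
    pd: np.ndarray
    dead: np.ndarray
    pfs_mid: np.ndarray     # half-cycle-corrected occupancy, length K
    pd_mid: np.ndarray
    new_deaths: np.ndarray  # per-cycle increment of the dead state
    clamp_fraction: float   # share of boundaries where PFS > OS was clamped

    @property
    def n_cycles(self) -> int:
        return int(self.weeks.size - 1)

    def to_frame(self, settings: Settings | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "week": self.weeks, "pfs": self.pfs, "pd": self.pd,
            "dead": self.dead,
        })
        df["new_deaths"] = np.concatenate([[0.0], self.new_deaths])
        if settings is not None:
            df["discount"] = np.concatenate(
                [[1.0], discount_factors(settings, self.weeks[:-1] + 0.5)])
        return df


def build_trace(os_fn: SurvivalFunction, pfs_fn: SurvivalFunction,
                settings: Settings) -> Trace:
    """Evaluate both curves on the weekly cycle grid and partition the cohort.

    Cycle boundaries sit at k weeks for k = 0..K with
    K = floor(horizon_years * 365.25 / 7); survival functions are evaluated
    in months (weeks * 7 / 30.4375).
    """
    horizon_years = settings.horizon_years.value
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    K = int(np.floor(horizon_years * settings.days_per_year / settings.cycle_days))
    weeks = np.arange(K + 1, dtype=float)
    months = weeks * settings.cycle_days / settings.days_per_month
    os_ = np.asarray(os_fn(months), dtype=float)
    pfs_raw = np.asarray(pfs_fn(months), dtype=float)
    clamped = pfs_raw > os_ + 1e-12
    pfs = np.minimum(pfs_raw, os_)
    pd_ = np.maximum(os_ - pfs, 0.0)
    dead = 1.0 - os_
    new_deaths = np.maximum(np.diff(dead), 0.0)
    return Trace(
        weeks=weeks, pfs=pfs, pd=pd_, dead=dead,
        pfs_mid=0.5 * (pfs[:-1] + pfs[1:]),
        pd_mid=0.5 * (pd_[:-1] + pd_[1:]),
        new_deaths=new_deaths,
        clamp_fraction=float(np.mean(clamped)),
    )


def discount_factors(settings: Settings, t_weeks) -> np.ndarray:
    """(1 + r)^(-t) with t in years, for flows at the given week positions."""
    rate = settings.discount_rate.value
    t_years = np.asarray(t_weeks, dtype=float) * settings.cycle_days / settings.days_per_year
    return (1.0 + rate) ** (-t_years)


def _mid_discount(settings: Settings, trace: Trace) -> np.ndarray:
    return discount_factors(settings, trace.weeks[:-1] + 0.5)


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------


def ara_population_utility(age, male_proportion: float):
    """General-population EQ-5D utility by age and proportion male
    (Ara-Brazier regression): 0.9508566 + 0.0212126*male - 0.0002587*age
    - 0.0000332*age^2."""
    age = np.asarray(age, dtype=float)
    if np.any((age < 16) | (age > 100)):
        raise ValueError("age outside the supported 16-100 range")
    u = (0.9508566 + 0.0212126 * male_proportion
         - 0.0002587 * age - 0.0000332 * age ** 2)
    return float(u) if u.ndim == 0 else u


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------


def drug_cost_per_administration(component, config: ModelConfig) -> float:
    """Dollar cost of one administration (or one day, for daily dosing) of a
    regimen component: rule-evaluated dose / unit size * unit cost * RDI.
    Fractional per-mg pricing, no vial rounding."""
    settings = config.settings
    if component.dose_rule == "fixed":
        dose = component.dose_mg
    elif component.dose_rule == "per-m2":
        dose = component.dose_mg * settings.body_surface_area.value
    elif component.dose_rule == "per-kg":
        dose = component.dose_mg * settings.weight_kg.value
    else:  # pragma: no cover - schema enforces the literal
        raise ValueError(component.dose_rule)
    drug = config.drugs[component.drug]
    rdi = 1.0
    if settings.apply_rdi and component.rdi is not None:
        rdi = config.rdi[component.rdi].value
    return dose / drug.unit_mg * drug.cost.value * rdi * component.fraction


def _per_week(component, amount: float) -> float:
    if component.schedule == "per-day":
        return 7.0 * amount
    return amount / 2.0  # per-2-week


def weekly_regimen_cost(strategy: Strategy, config: ModelConfig) -> tuple[float, float]:
    """(acquisition, administration) dollars per week of on-treatment time."""
    acq = 0.0
    adm = 0.0
    for comp in strategy.components:
        acq += _per_week(comp, drug_cost_per_administration(comp, config))
        events = sum(n * config.admin_costs[ev].value
                     for ev, n in comp.admin_events.items())
        adm += _per_week(comp, events * comp.fraction)
    return acq, adm


def accrue_costs(trace: Trace, strategy: Strategy, config: ModelConfig) -> dict:
    """Discounted cost totals by category for one strategy.

    Treatment (acquisition, administration, monitoring) runs to progression,
    i.e. accrues on PFS occupancy; subsequent-treatment costs accrue on PD
    occupancy; adverse-event management is a one-off at model initiation;
    end-of-life cost attaches to new deaths.
    """
    settings = config.settings
    disc = _mid_discount(settings, trace)
    pfs_weeks = float(np.sum(trace.pfs_mid * disc))
    pd_weeks = float(np.sum(trace.pd_mid * disc))
    deaths = float(np.sum(trace.new_deaths * disc))

    acq_wk, adm_wk = weekly_regimen_cost(strategy, config)
    mon = config.monitoring_costs
    mon_wk = (mon["scan"].value / settings.scan_interval_weeks
              + mon["consultation"].value / settings.consultation_interval_weeks)

    ae_once = sum(strategy.ae_incidence[name].value * config.ae_catalog[name].cost.value
                  for name in strategy.ae_incidence)

    costs = {
        "acquisition": acq_wk * pfs_weeks,
        "administration": adm_wk * pfs_weeks,
        "monitoring": mon_wk * pfs_weeks + mon["braf_test"].value,
        "adverse_events": ae_once,
        "subsequent": config.subsequent_cost_per_week.value * pd_weeks,
        "end_of_life": (config.end_of_life_cost.value
                        * settings.end_of_life_multiplier * deaths),
    }
    costs["total"] = sum(costs.values())
    return costs


# ---------------------------------------------------------------------------
# QALYs
# ---------------------------------------------------------------------------


def accrue_qalys(trace: Trace, strategy: Strategy, config: ModelConfig) -> dict:
    """Discounted life-year and QALY totals by component.

    In the default ``constant`` utility mode the state utilities are applied
    directly each cycle (equivalent to re-deriving the population-norm
    multiplier every cycle); in ``aging-multiplier`` mode the baseline
    multiplier u_state / norm(age_0) is fixed and multiplied by the
    age-updated population norm so utilities decline as the cohort ages.
    """
    settings = config.settings
    disc = _mid_discount(settings, trace)
    cycle_years = settings.cycle_days / settings.days_per_year
    t_mid_years = (trace.weeks[:-1] + 0.5) * cycle_years

    u_pfs = config.utilities["pfs"].value
    u_pd = config.utilities["pd"].value
    if settings.utility_mode == "aging-multiplier":
        norm0 = ara_population_utility(settings.baseline_age,
                                       settings.male_proportion)
        ages = np.minimum(settings.baseline_age + t_mid_years, 100.0)
        norm_t = ara_population_utility(ages, settings.male_proportion)
        upfs_t = (u_pfs / norm0) * norm_t
        upd_t = (u_pd / norm0) * norm_t
    else:
        upfs_t = u_pfs
        upd_t = u_pd

    ly_pfs = float(np.sum(trace.pfs_mid * disc)) * cycle_years
    ly_pd = float(np.sum(trace.pd_mid * disc)) * cycle_years
    q_pfs = float(np.sum(trace.pfs_mid * upfs_t * disc)) * cycle_years
    q_pd = float(np.sum(trace.pd_mid * upd_t * disc)) * cycle_years

    ae_dis = 0.0
    death_dis = 0.0
    if settings.include_ae_effects:
        weeks_per_year = settings.days_per_year / settings.cycle_days
        ae_dis = -sum(
            strategy.ae_incidence[name].value
            * config.ae_catalog[name].disutility.value
            * config.ae_catalog[name].duration_weeks / weeks_per_year
            for name in strategy.ae_incidence)
    if settings.include_death_disutility:
        per_death = sum(
            dd.decrement.value * (dd.window_days[1] - dd.window_days[0])
            / settings.days_per_year
            for dd in config.death_disutilities)
        per_death *= settings.death_disutility_scale
        death_dis = -per_death * float(np.sum(trace.new_deaths * disc))

    return {
        "ly_pfs": ly_pfs, "ly_pd": ly_pd, "ly_total": ly_pfs + ly_pd,
        "qaly_pfs": q_pfs, "qaly_pd": q_pd,
        "qaly_ae_disutility": ae_dis, "qaly_death_disutility": death_dis,
        "qaly_total": q_pfs + q_pd + ae_dis + death_dis,
    }


# ---------------------------------------------------------------------------
# strategy orchestration
# ---------------------------------------------------------------------------


@dataclass
class StrategyResult:
    """Discounted totals for one strategy."""

    name: str
    costs: dict
    outcomes: dict
    clamp_fraction: float = 0.0
    warnings: list = field(default_factory=list)

    @property
    def total_cost(self) -> float:
        return self.costs["total"]

    @property
    def total_qalys(self) -> float:
        return self.outcomes["qaly_total"]

    @property
    def total_lys(self) -> float:
        return self.outcomes["ly_total"]

    def to_series(self) -> pd.Series:
        out = {f"cost_{k}": v for k, v in self.costs.items()}
        out.update(self.outcomes)
        return pd.Series(out, name=self.name)


def strategy_survival_functions(strategy: Strategy) -> dict[str, SurvivalFunction]:
    """OS/PFS survival functions from a strategy's coefficient blocks."""
    out = {}
    for endpoint, block in strategy.survival.items():
        fit = from_coefficients(block.family, block.coefs, block.coef_names)
        out[endpoint] = survival_function(fit)
    return out


def run_strategy(name: str, config: ModelConfig,
                 survival_fns: dict[str, SurvivalFunction] | None = None
                 ) -> StrategyResult:
    """Build the trace and accrue costs and QALYs for one named strategy.

    ``survival_fns`` (keys ``os``/``pfs``) overrides the config's coefficient
    blocks, which is how alternative extrapolations (splines, model averages)
    are run through the same engine.
    """
    if name not in config.strategies:
        raise KeyError(f"unknown strategy '{name}'; have {list(config.strategies)}")
    strategy = config.strategies[name]
    fns = survival_fns or strategy_survival_functions(strategy)
    trace = build_trace(fns["os"], fns["pfs"], config.settings)
    warnings = []
    if trace.clamp_fraction > 0.20:
        warnings.append(
            f"PFS exceeded OS on {trace.clamp_fraction:.1%} of cycle "
            "boundaries (clamped); check curve compatibility")
    costs = accrue_costs(trace, strategy, config)
    outcomes = accrue_qalys(trace, strategy, config)
    return StrategyResult(name=name, costs=costs, outcomes=outcomes,
                          clamp_fraction=trace.clamp_fraction,
                          warnings=warnings)


def run_all(config: ModelConfig,
            survival_fns: dict[str, dict[str, SurvivalFunction]] | None = None
            ) -> dict[str, StrategyResult]:
    """Run every configured strategy; returns name -> StrategyResult."""
    return {
        name: run_strategy(
            name, config,
            survival_fns.get(name) if survival_fns else None)
        for name in config.strategies
    }


def results_table(results: dict[str, StrategyResult]) -> pd.DataFrame:
    """Three-strategy results block (rows = quantities, columns = strategies)."""
    return pd.DataFrame({name: r.to_series() for name, r in results.items()})
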