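"""Dynamic-cohort budget impact of adopting a biologic sequence over SoC.

Payer perspective: direct medical costs only (the non-medical food/transport
component of the cost-utility analysis is excluded).  Streams are
undiscounted, per budget-impact convention.

Per-patient annual cost streams come from the cohort engine run under the
budget-impact reading of the stop rule — every biologic stops at the end of
model year ``stop_years`` (``stop_clock="model_start"``) — with each drug's
annual relapse probability overridden by ``relapse_rate_y45``, so years 4–5
biologic spend is driven entirely by retreatment of relapsers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .model_core import COST_CATEGORIES, run_cohort
from .parameters import ParameterSet, Strategy

__all__ = [
    "PopulationInputs",
    "BIAResult",
    "per_patient_annual_costs",
    "eligible_patients",
    "scenario_budget",
    "budget_impact_table",
]

_PAYER_EXCLUDED = ("nonmedical",)


@dataclass
class PopulationInputs:
    """Eligible-population dynamics for the budget-impact model."""

    base_population: float = 31_600_000.0
    prevalence: float = 0.003
    annual_incidence: float = 0.0002
    prop_systemic_treated: float = 0.3
    annual_death_rate: float = 0.01
    uptake_rate: float = 0.05
    relapse_rate_y45: float = 0.91
    horizon_years: int = 5
    incident_half_year: bool = True

    def validate(self) -> list[str]:
        errs = []
        if self.base_population <= 0:
            errs.append("base_population must be > 0")
        for fld in ("prevalence", "annual_incidence", "prop_systemic_treated",
                    "annual_death_rate", "uptake_rate", "relapse_rate_y45"):
            v = getattr(self, fld)
            if not (0.0 <= v <= 1.0):
                errs.append(f"{fld} must be in [0,1], got {v}")
        if self.horizon_years < 1:
            errs.append("horizon_years must be >= 1")
        return errs

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in (
            "base_population", "prevalence", "annual_incidence",
            "prop_systemic_treated", "annual_death_rate", "uptake_rate",
            "relapse_rate_y45", "horizon_years", "incident_half_year")}

    @staticmethod
    def from_dict(d: Mapping[str, Any]) -> "PopulationInputs":
        return PopulationInputs(**dict(d))


@dataclass
class BIAResult:
    """Year-by-year treated counts and budgets (THB, undiscounted)."""

    years: list[int]
    patients_total: list[float]
    patients_on_sequence: list[float]
    budget_soc: list[float]
    budget_sequence: list[float]
    impact: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years,
            "patients_total": self.patients_total,
            "patients_on_sequence": self.patients_on_sequence,
            "budget_soc_thb": self.budget_soc,
            "budget_sequence_thb": self.budget_sequence,
            "impact_thb": self.impact,
        })


def _bia_parameter_set(ps: ParameterSet, pop: PopulationInputs,
                       years: int) -> ParameterSet:
    out = ps.copy()
    out.settings.stop_clock = "model_start"
    out.settings.horizon_age = out.settings.start_age + years
    for drug in out.drugs.values():
        drug.annual_relapse_prob = pop.relapse_rate_y45
    return out


def per_patient_annual_costs(ps: ParameterSet, pop: PopulationInputs,
                             strategy: Strategy, payer: bool = True) -> pd.DataFrame:
    """Undiscounted per-patient cost by year on treatment and cost category.

    Index = year on treatment (1..horizon); columns = cost categories (the
    non-medical category dropped under the payer perspective) plus ``total``.
    """
    years = pop.horizon_years
    ps_b = _bia_parameter_set(ps, pop, years)
    trace = run_cohort(strategy, ps_b)
    cpy = trace.cycles_per_year
    cats = [c for c in COST_CATEGORIES if not (payer and c in _PAYER_EXCLUDED)]
    rows = {}
    for y in range(years):
        sl = slice(y * cpy, (y + 1) * cpy)
        rows[y + 1] = {c: float(trace.cost_by_category[c][sl].sum()) for c in cats}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "year_on_treatment"
    df["total"] = df.sum(axis=1)
    return df


def eligible_patients(year: int, pop: PopulationInputs) -> tuple[float, float]:
    """(systemically-treated stock, biologic-treated count) for a model year.

    Year-1 stock is prevalent patients on systemic therapy; later years decay
    by the annual death rate and gain incident systemically-treated patients.
    The uptake fraction of the stock receives the biologic sequence.
    """
    if not (1 <= year <= pop.horizon_years):
        raise ValueError(f"year must be in 1..{pop.horizon_years}, got {year}")
    errs = pop.validate()
    if errs:
        raise ValueError("; ".join(errs))
    stock = pop.base_population * pop.prevalence * pop.prop_systemic_treated
    for _ in range(year - 1):
        stock = (stock * (1.0 - pop.annual_death_rate)
                 + pop.base_population * pop.annual_incidence
                 * pop.prop_systemic_treated)
    return stock, stock * pop.uptake_rate


def _cohort_plan(pop: PopulationInputs) -> list[dict]:
    """Per calendar year: stock, sequence-treated target, and the surviving
    size of each annual starter cohort (new starters fill the uptake target)."""
    plan = []
    starters: list[float] = []   # starters[j] = new entrants in calendar year j+1
    d = pop.annual_death_rate
    for year in range(1, pop.horizon_years + 1):
        stock, target = eligible_patients(year, pop)
        surviving = [n * (1.0 - d) ** (year - (j + 1)) for j, n in enumerate(starters)]
        new = max(0.0, target - sum(surviving))
        starters.append(new)
        plan.append({"year": year, "stock": stock, "target": target,
                     "cohorts": surviving + [new]})
    return plan


def scenario_budget(year: int, pop: PopulationInputs, ps: ParameterSet,
                    strategy: Strategy | None) -> float:
    """Total payer budget (THB) for one calendar year under one scenario.

    ``strategy=None`` is the all-SoC scenario.  Under the sequence scenario
    the uptake fraction of the stock follows the sequence (new starters after
    year 1 accrue half a year of sequence cost and half of SoC cost when
    ``incident_half_year`` is set); the remainder stays on SoC.
    """
    soc_stream = per_patient_annual_costs(ps, pop, Strategy("SoC"), payer=True)
    soc_annual = float(soc_stream["total"].iloc[0])
    stock, _ = eligible_patients(year, pop)
    if strategy is None:
        return stock * soc_annual

    seq_stream = per_patient_annual_costs(ps, pop, strategy, payer=True)
    plan = _cohort_plan(pop)[year - 1]
    total = 0.0
    on_seq = 0.0
    for j, size in enumerate(plan["cohorts"]):
        year_on_tx = year - (j + 1) + 1
        seq_cost = float(seq_stream["total"].iloc[year_on_tx - 1])
        if year_on_tx == 1 and (j + 1) > 1 and pop.incident_half_year:
            total += size * 0.5 * (seq_cost + soc_annual)
        else:
            total += size * seq_cost
        on_seq += size
    total += (stock - on_seq) * soc_annual
    return total


def budget_impact_table(pop: PopulationInputs, ps: ParameterSet,
                        strategy: Strategy) -> BIAResult:
    """Five-year budget impact: sequence scenario minus all-SoC scenario."""
    errs = pop.validate()
    if errs:
        raise ValueError("; ".join(errs))
    years = list(range(1, pop.horizon_years + 1))
    totals, on_seq, b_soc, b_seq, impact = [], [], [], [], []
    for y in years:
        stock, treated = eligible_patients(y, pop)
        soc_budget = scenario_budget(y, pop, ps, None)
        seq_budget = scenario_budget(y, pop, ps, strategy)
        totals.append(stock)
        on_seq.append(treated)
        b_soc.append(soc_budget)
        b_seq.append(seq_budget)
        impact.append(seq_budget - soc_budget)
    return BIAResult(years=years, patients_total=totals, patients_on_sequence=on_seq,
                     budget_soc=b_soc, budget_sequence=b_seq, impact=impact)
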