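"""Dosing-schedule and resource-use costing (all amounts in 2021 THB).

Dose cost uses whole dispensing units: ``ceil(dose_mg / mg_per_unit) ×
price_per_unit`` — no vial sharing.  Maintenance doses run on a periodic grid
starting one interval after the last induction dose, so e.g. a drug loaded
weekly over weeks 0–4 with a q4w maintenance interval resumes at week 8.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .parameters import (
    SCREENING_TESTS, CostSet, DrugProfile, EconSettings, ParameterSet, SoCProfile,
)

__all__ = [
    "dose_events_in_window",
    "doses_in_window",
    "units_for_dose",
    "drug_cost_in_window",
    "drug_cost_per_cycle",
    "line_drug_cost_array",
    "maintenance_cost_per_cycle_mean",
    "screening_cost",
    "monitoring_cost_per_year",
    "soc_drug_cost_per_cycle",
    "thb_to_usd",
]


def dose_events_in_window(drug: DrugProfile, week_start: float,
                          week_end: float) -> list[tuple[float, float]]:
    """All (week, dose_mg) administrations with week in [week_start, week_end)."""
    if week_end < week_start:
        raise ValueError("week_end must be >= week_start")
    events = [(float(e.week_offset), e.dose_mg) for e in drug.induction_schedule
              if week_start <= e.week_offset < week_end]
    last = drug.last_induction_week
    interval = drug.maintenance_interval_weeks
    # first maintenance dose one interval after the last induction dose
    i = max(1, math.ceil((week_start - last) / interval))
    wk = last + i * interval
    while wk < week_end:
        events.append((float(wk), drug.maintenance_dose_mg))
        wk += interval
    events.sort()
    return events


def doses_in_window(drug: DrugProfile, week_start: float,
                    week_end: float) -> tuple[int, float]:
    """Dose count and total mg administered in [week_start, week_end)."""
    ev = dose_events_in_window(drug, week_start, week_end)
    return len(ev), sum(mg for _, mg in ev)


def units_for_dose(dose_mg: float, mg_per_unit: float) -> int:
    if mg_per_unit <= 0:
        raise ValueError("mg_per_unit must be > 0")
    return math.ceil(dose_mg / mg_per_unit)


def drug_cost_in_window(drug: DrugProfile, week_start: float, week_end: float) -> float:
    """THB cost of all doses falling in [week_start, week_end)."""
    return sum(units_for_dose(mg, drug.mg_per_unit) * drug.price_per_unit
               for _, mg in dose_events_in_window(drug, week_start, week_end))


def maintenance_cost_per_cycle_mean(drug: DrugProfile, settings: EconSettings) -> float:
    """Steady-state mean drug cost per cycle during maintenance dosing."""
    units = units_for_dose(drug.maintenance_dose_mg, drug.mg_per_unit)
    return units * drug.price_per_unit * (settings.weeks_per_cycle
                                          / drug.maintenance_interval_weeks)


def drug_cost_per_cycle(drug: DrugProfile, phase: str, ps: ParameterSet) -> float:
    """Mean per-cycle drug cost in the given phase (induction | maintenance)."""
    s = ps.settings
    if phase == "maintenance":
        return maintenance_cost_per_cycle_mean(drug, s)
    if phase == "induction":
        weeks = s.assessment_cycles * s.weeks_per_cycle
        return drug_cost_in_window(drug, 0.0, weeks) / s.assessment_cycles
    raise ValueError(f"unknown phase {phase!r}")


def line_drug_cost_array(drug: DrugProfile, n_cycles: int,
                         settings: EconSettings) -> np.ndarray:
    """Exact THB drug cost per cycle, indexed by cycle since line start.

    Covers both induction and continuing maintenance dosing on one grid, so
    the same array serves the induction and maintenance states of a line.
    """
    wpc = settings.weeks_per_cycle
    horizon_weeks = n_cycles * wpc
    events = dose_events_in_window(drug, 0.0, horizon_weeks)
    out = np.zeros(n_cycles)
    for wk, mg in events:
        c = int(wk // wpc)
        if 0 <= c < n_cycles:
            out[c] += units_for_dose(mg, drug.mg_per_unit) * drug.price_per_unit
    return out


def screening_cost(ps: ParameterSet) -> float:
    """One-time pre-biologic screening panel cost (11 tests)."""
    labs = ps.costs.lab_costs
    missing = [t for t in SCREENING_TESTS if t not in labs]
    if missing:
        raise KeyError(f"missing screening unit costs: {missing}")
    return sum(labs[t] for t in SCREENING_TESTS)


def monitoring_cost_per_year(state_kind: str, ps: ParameterSet) -> float:
    """Annual lab-monitoring cost for a maintenance-biologic or SoC patient.

    Biologic maintenance: bi-yearly CBC/AST/ALT plus a yearly IGRA.  SoC:
    CBC/AST/ALT/BUN/Cr at the configured 3–6-month frequency (default
    quarterly), quarterly lipid profile, and quarterly uric acid + magnesium
    for the ciclosporin fraction of the mix.
    """
    labs = ps.costs.lab_costs
    if state_kind == "MAINT":
        return 2.0 * (labs["CBC"] + labs["AST"] + labs["ALT"]) + labs["IGRA"]
    if state_kind == "SOC":
        f = ps.soc.soc_lab_frequency_per_year
        base = f * (labs["CBC"] + labs["AST"] + labs["ALT"] + labs["BUN"] + labs["Cr"])
        lipid = 4.0 * labs["lipid_profile"]
        csa = (1.0 - ps.soc.mix_mtx_fraction) * 4.0 * (labs["uric_acid"]
                                                       + labs["magnesium"])
        return base + lipid + csa
    raise ValueError(f"monitoring is defined for MAINT or SOC, not {state_kind!r}")


def soc_drug_cost_per_cycle(soc: SoCProfile, settings: EconSettings,
                            variant: str | None = None) -> float:
    """Mix-blended MTX/ciclosporin drug cost per model cycle."""
    variant = variant or soc.mtx_variant
    mtx_price = {"tablet": soc.mtx_price_tablet,
                 "injection": soc.mtx_price_injection}[variant]
    days = settings.cycle_length_days
    mtx_mg_per_cycle = soc.mtx_weekly_dose_mg * (days / 7.0)
    csa_mg_per_cycle = soc.csa_dose_mg_per_kg_day * soc.patient_weight_kg * days
    return (soc.mix_mtx_fraction * mtx_mg_per_cycle * mtx_price
            + (1.0 - soc.mix_mtx_fraction) * csa_mg_per_cycle * soc.csa_price)


def thb_to_usd(amount_thb: float, rate: float = 0.0313) -> float:
    """Convert THB to USD at the configured 2021 average rate (0.0313 $/THB)."""
    if rate <= 0:
        raise ValueError("exchange rate must be > 0")
    return amount_thb * rate
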