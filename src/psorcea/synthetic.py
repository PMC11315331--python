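"""Synthetic parameter generation.

The real cost-utility and budget-impact input tables live in supplementary
material that is not distributed with this package, so every analysis here is
exercised on internally consistent synthetic inputs that reproduce the
*statistical structure* of the study's inputs: response probabilities ordered
PASI75 >= PASI90 >= PASI100 with means in a plausible trial range, annual
drop-out 5–25%, annual relapse 30–95%, ordered utilities, biologic unit
prices 1–3 orders of magnitude above conventional-therapy drug prices (so
biologic cost dominates), and a monotone-increasing life table for ages
40–100.  Generation is bit-reproducible from a seed; generated sets always
carry the provenance tag ``"synthetic"``.

Dosing schedules are *not* synthetic: they are the published label regimens
of secukinumab, ixekizumab, brodalumab and guselkumab.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .budget_impact import PopulationInputs
from .model_core import StrategyResult
from .parameters import (
    AE_TYPES, LAB_TESTS, CostSet, DistributionSpec, DoseEvent,
    DrugProfile, EconSettings, LifeTable, ParameterSet, SoCProfile, UtilitySet,
    set_param, validate_parameter_set,
)

__all__ = [
    "SyntheticSpec",
    "generate_parameter_set",
    "generate_population_inputs",
    "table1_fixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic input bundle: seed, realism level, overrides."""

    seed: int
    level: str = "plausible"        # "plausible" | "toy"
    overrides: dict[str, Any] = field(default_factory=dict)


def _dose_schedules() -> dict[str, dict]:
    """Label induction schedules and maintenance intervals (mg, weeks)."""
    return {
        # 300 mg at weeks 0-4 then every 4 weeks
        "secukinumab": {
            "induction": [(0, 300), (1, 300), (2, 300), (3, 300), (4, 300)],
            "interval": 4, "maint_mg": 300, "mg_per_unit": 150,
        },
        # 160 mg at week 0, 80 mg q2w to week 12, then every 4 weeks
        "ixekizumab": {
            "induction": [(0, 160), (2, 80), (4, 80), (6, 80), (8, 80),
                          (10, 80), (12, 80)],
            "interval": 4, "maint_mg": 80, "mg_per_unit": 80,
        },
        # 210 mg at weeks 0, 1, 2 then every 2 weeks
        "brodalumab": {
            "induction": [(0, 210), (1, 210), (2, 210)],
            "interval": 2, "maint_mg": 210, "mg_per_unit": 210,
        },
        # 100 mg every 8 weeks, no extra loading
        "guselkumab": {
            "induction": [(0, 100)],
            "interval": 8, "maint_mg": 100, "mg_per_unit": 100,
        },
    }


def _toy_parameter_set() -> ParameterSet:
    """Hand-checkable deterministic inputs: probabilities in {0, 0.5, 1},
    prices in {0, 100}, no mortality, flat unit lab costs."""
    drugs = {}
    for name, sched in _dose_schedules().items():
        drugs[name] = DrugProfile(
            name=name,
            induction_schedule=[DoseEvent(w, mg) for w, mg in sched["induction"]],
            maintenance_interval_weeks=sched["interval"],
            maintenance_dose_mg=sched["maint_mg"],
            price_per_unit=100.0,
            mg_per_unit=sched["mg_per_unit"],
            response_prob={"PASI75": 0.5, "PASI90": 0.5, "PASI100": 0.5},
            annual_dropout_prob=0.0,
            annual_relapse_prob=0.5,
            p_serious_infection_once=0.0,
            p_malignancy_annual=0.0,
        )
    return ParameterSet(
        drugs=drugs,
        soc=SoCProfile(mtx_price_tablet=0.0, mtx_price_injection=0.0, csa_price=0.0,
                       response_prob_soc=0.5, p_cirrhosis_annual=0.0),
        utilities=UtilitySet(u_baseline=0.5, u_pasi75=1.0, u_pasi90=1.0,
                             u_pasi100=1.0, du_infection=0.0, du_malignancy=0.0,
                             du_cirrhosis=0.0),
        costs=CostSet(lab_costs={t: 0.0 for t in LAB_TESTS},
                      visit_cost_direct_medical=0.0, nonmedical_cost_per_visit=0.0,
                      visits_per_year=0.0, topical_cost_per_cycle=0.0,
                      ae_management_costs={t: 0.0 for t in AE_TYPES}),
        life_table=LifeTable(annual_death_prob={a: 0.0 for a in range(40, 101)},
                             rr_psoriasis=1.0),
        settings=EconSettings(discount_rate_annual=0.0),
        psa_specs=[],
        provenance="synthetic",
    )


def generate_parameter_set(spec: SyntheticSpec) -> ParameterSet:
    """Emit a complete ParameterSet; always passes validation."""
    if spec.level == "toy":
        ps = _toy_parameter_set()
    elif spec.level == "plausible":
        ps = _plausible_parameter_set(np.random.default_rng(spec.seed))
    else:
        raise ValueError(f"unknown realism level {spec.level!r}")
    for path, value in spec.overrides.items():
        set_param(ps, path, value)
    violations = validate_parameter_set(ps)
    if violations:  # pragma: no cover - generator contract
        raise AssertionError(f"synthetic generator emitted invalid set: {violations}")
    return ps


def _plausible_parameter_set(rng: np.random.Generator) -> ParameterSet:
    drugs = {}
    for name, sched in _dose_schedules().items():
        # ordered response means: PASI75 in [0.6, 0.9], then step-downs
        p75 = rng.uniform(0.60, 0.90)
        p90 = p75 * rng.uniform(0.70, 0.95)
        p100 = p90 * rng.uniform(0.40, 0.80)
        price = rng.uniform(10_000, 40_000)  # THB per pen/vial
        drugs[name] = DrugProfile(
            name=name,
            induction_schedule=[DoseEvent(w, mg) for w, mg in sched["induction"]],
            maintenance_interval_weeks=sched["interval"],
            maintenance_dose_mg=sched["maint_mg"],
            price_per_unit=float(round(price, 2)),
            mg_per_unit=sched["mg_per_unit"],
            response_prob={"PASI75": float(round(p75, 4)),
                           "PASI90": float(round(p90, 4)),
                           "PASI100": float(round(p100, 4))},
            annual_dropout_prob=float(round(rng.uniform(0.05, 0.25), 4)),
            annual_relapse_prob=float(round(rng.uniform(0.30, 0.95), 4)),
            p_serious_infection_once=float(round(rng.uniform(0.005, 0.03), 4)),
            p_malignancy_annual=float(round(rng.uniform(0.001, 0.01), 4)),
        )

    # SoC drug prices per mg: 1-3 orders of magnitude below biologic unit prices
    soc = SoCProfile(
        mtx_price_tablet=float(round(rng.uniform(1.0, 5.0), 3)),
        mtx_price_injection=float(round(rng.uniform(5.0, 15.0), 3)),
        csa_price=float(round(rng.uniform(3.0, 12.0), 3)),
        response_prob_soc=float(round(rng.uniform(0.2, 0.45), 4)),
        p_cirrhosis_annual=float(round(rng.uniform(0.002, 0.02), 4)),
    )

    u_base = rng.uniform(0.55, 0.72)
    u75 = u_base + rng.uniform(0.08, 0.18)
    u90 = u75 + rng.uniform(0.0, 0.05)
    u100 = min(1.0, u90 + rng.uniform(0.0, 0.04))
    utilities = UtilitySet(
        u_baseline=float(round(u_base, 4)), u_pasi75=float(round(u75, 4)),
        u_pasi90=float(round(u90, 4)), u_pasi100=float(round(u100, 4)),
        du_infection=float(round(rng.uniform(0.005, 0.03), 4)),
        du_malignancy=float(round(rng.uniform(0.05, 0.15), 4)),
        du_cirrhosis=float(round(rng.uniform(0.05, 0.15), 4)),
    )
    # alternative utility source for scenario analysis: same ordering, shifted
    shift = rng.uniform(0.0, 0.03)
    alt = UtilitySet(
        u_baseline=utilities.u_baseline,
        u_pasi75=float(round(min(1.0, utilities.u_pasi75 + shift), 4)),
        u_pasi90=float(round(min(1.0, utilities.u_pasi90 + shift), 4)),
        u_pasi100=float(round(min(1.0, utilities.u_pasi100 + shift), 4)),
        du_infection=utilities.du_infection,
        du_malignancy=utilities.du_malignancy,
        du_cirrhosis=utilities.du_cirrhosis,
    )

    costs = CostSet(
        lab_costs={t: float(round(rng.uniform(50, 600), 2)) for t in LAB_TESTS},
        visit_cost_direct_medical=float(round(rng.uniform(300, 900), 2)),
        nonmedical_cost_per_visit=float(round(rng.uniform(200, 600), 2)),
        visits_per_year=float(rng.integers(4, 9)),
        topical_cost_per_cycle=float(round(rng.uniform(50, 300), 2)),
        ae_management_costs={
            "serious_infection": float(round(rng.uniform(20_000, 80_000), 2)),
            "malignancy": float(round(rng.uniform(100_000, 400_000), 2)),
            "cirrhosis": float(round(rng.uniform(50_000, 200_000), 2)),
        },
    )

    # Gompertz-like monotone life table for ages 40-100
    ages = np.arange(40, 101)
    q = 1e-3 * np.exp(0.085 * (ages - 40)) * rng.uniform(0.8, 1.2)
    q = np.minimum(0.6, q)
    life_table = LifeTable(
        annual_death_prob={int(a): float(round(v, 6)) for a, v in zip(ages, q)},
        rr_psoriasis=float(round(rng.uniform(1.0, 1.6), 3)),
    )

    specs: list[DistributionSpec] = []
    for name in drugs:
        specs.append(DistributionSpec(f"drugs.{name}.response_prob.PASI75", "beta"))
        specs.append(DistributionSpec(f"drugs.{name}.annual_dropout_prob", "beta"))
        specs.append(DistributionSpec(f"drugs.{name}.annual_relapse_prob", "beta"))
        specs.append(DistributionSpec(f"drugs.{name}.price_per_unit", "gamma"))
    for fld in ("u_baseline", "u_pasi75", "u_pasi90", "u_pasi100"):
        specs.append(DistributionSpec(f"utilities.{fld}", "beta",
                                      {"se": 0.03}))
    specs.append(DistributionSpec("soc.response_prob_soc", "beta"))
    specs.append(DistributionSpec("costs.visit_cost_direct_medical", "gamma"))
    specs.append(DistributionSpec("life_table.rr_psoriasis", "lognormal",
                                  {"se": 0.1}))

    return ParameterSet(drugs=drugs, soc=soc, utilities=utilities, costs=costs,
                        life_table=life_table, settings=EconSettings(),
                        psa_specs=specs, alt_utilities=alt, provenance="synthetic")


def generate_population_inputs(spec: SyntheticSpec) -> PopulationInputs:
    """Budget-impact population inputs; uptake and years-4/5 relapse keep their
    defaults (5% and 91%) unless overridden."""
    rng = np.random.default_rng(spec.seed)
    if spec.level == "toy":
        pop = PopulationInputs(base_population=1_000_000.0, prevalence=0.003,
                               annual_incidence=0.0001, prop_systemic_treated=0.5,
                               annual_death_rate=0.02)
    else:
        pop = PopulationInputs(
            prevalence=float(round(rng.uniform(0.001, 0.01), 6)),
            annual_incidence=float(round(rng.uniform(0.00005, 0.0005), 6)),
            prop_systemic_treated=float(round(rng.uniform(0.2, 0.6), 4)),
            annual_death_rate=float(round(rng.uniform(0.005, 0.02), 5)),
        )
    for key, value in spec.overrides.items():
        setattr(pop, key, value)
    errs = pop.validate()
    if errs:  # pragma: no cover - generator contract
        raise AssertionError(f"synthetic population inputs invalid: {errs}")
    return pop


def table1_fixture() -> list[StrategyResult]:
    """The published base-case totals (cost THB, life-years, QALYs) as
    StrategyResults, for exercising the decision analysis independently of
    the cohort engine.  Carries provenance ``"paper:Table1"``."""
    rows = [
        ("SoC", 783_388.0, 20.589, 13.489),
        ("Sequence1", 2_646_675.0, 20.589, 16.484),
        ("Sequence2", 3_808_175.0, 20.589, 16.649),
        ("Sequence3", 4_552_700.0, 20.589, 16.318),
    ]
    return [StrategyResult(strategy_name=name, total_cost_thb=cost, total_ly=ly,
                           total_qaly=qaly, undiscounted_cost_thb=cost,
                           undiscounted_ly=ly, undiscounted_qaly=qaly,
                           provenance="paper:Table1")
            for name, cost, ly, qaly in rows]
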