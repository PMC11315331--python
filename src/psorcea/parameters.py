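"""Model input data model: drugs, SoC, utilities, costs, life table, settings.

A :class:`ParameterSet` bundles every input the cohort engine, the
cost-effectiveness analyses and the budget-impact model consume.  It can be
serialised to / loaded from a single YAML document; loading rejects unknown
keys and re-validates, so a config file is always either fully usable or
diagnosed with a list of violations naming parameter path and rule.

Monetary values are stored in 2021 THB.  Raw-year costs may be declared with
``costs.cpi_factor_to_2021`` != 1, in which case they are inflated at load.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "PASI_LEVELS",
    "SCREENING_TESTS",
    "LAB_TESTS",
    "AE_TYPES",
    "SchemaError",
    "Violation",
    "DoseEvent",
    "DrugProfile",
    "SoCProfile",
    "UtilitySet",
    "CostSet",
    "LifeTable",
    "EconSettings",
    "DistributionSpec",
    "TreatmentLine",
    "Strategy",
    "ParameterSet",
    "load_parameter_set",
    "save_parameter_set",
    "validate_parameter_set",
    "get_param",
    "set_param",
    "default_strategies",
]

#: Treatment-response definitions (75 / 90 / 100 % PASI reduction).
PASI_LEVELS = ("PASI75", "PASI90", "PASI100")

#: One-time pre-biologic screening panel (11 tests).
SCREENING_TESTS = (
    "CBC", "FBS", "lipid_profile", "BUN", "Cr", "LFT",
    "IGRA", "CXR", "HBsAg", "anti_HBs", "anti_HBc",
)

#: Every lab test a CostSet must price (screening + monitoring panels).
LAB_TESTS = SCREENING_TESTS + ("AST", "ALT", "uric_acid", "magnesium")

#: Adverse-event types the model accrues costs/disutilities for.
AE_TYPES = ("serious_infection", "malignancy", "cirrhosis")


class SchemaError(ValueError):
    """Raised when a configuration document cannot be interpreted."""


@dataclass(frozen=True)
class Violation:
    """A single invariant breach found by :func:`validate_parameter_set`."""

    path: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: [{self.rule}] {self.message}"


# ---------------------------------------------------------------------------
# schema helpers
# ---------------------------------------------------------------------------

def _check_mapping(d: Any, path: str) -> Mapping[str, Any]:
    if not isinstance(d, Mapping):
        raise SchemaError(f"{path}: expected a mapping, got {type(d).__name__}")
    return d

def _check_keys(d: Mapping[str, Any], allowed: Iterable[str], path: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)!r}")

def _get(d: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in d:
        raise SchemaError(f"{path}.{key}: missing required key")
    return d[key]

def _num(v: Any, path: str) -> float:
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise SchemaError(f"{path}: expected a number, got {v!r}")
    return float(v)

def _opt_num(d: Mapping[str, Any], key: str, default: float, path: str) -> float:
    return _num(d[key], f"{path}.{key}") if key in d else float(default)

def _str(v: Any, path: str) -> str:
    if not isinstance(v, str):
        raise SchemaError(f"{path}: expected a string, got {v!r}")
    return v


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseEvent:
    """A single scheduled administration, ``week_offset`` weeks after line start."""

    week_offset: int
    dose_mg: float

    @staticmethod
    def from_dict(d: Mapping[str, Any], path: str) -> "DoseEvent":
        d = _check_mapping(d, path)
        _check_keys(d, ("week_offset", "dose_mg"), path)
        return DoseEvent(
            week_offset=int(_num(_get(d, "week_offset", path), f"{path}.week_offset")),
            dose_mg=_num(_get(d, "dose_mg", path), f"{path}.dose_mg"),
        )

    def to_dict(self) -> dict:
        return {"week_offset": self.week_offset, "dose_mg": self.dose_mg}


@dataclass
class DrugProfile:
    """A biologic: dosing schedule, price, efficacy and safety inputs.

    ``induction_schedule`` lists fixed loading/induction doses; from the last
    induction dose onward, ``maintenance_dose_mg`` is given every
    ``maintenance_interval_weeks``.  Response probabilities are the chance of
    reaching each PASI level at the response assessment.  Drop-out and relapse
    are annual probabilities (converted per cycle by the engine); serious
    infection is a one-time risk at treatment start and malignancy an annual
    risk applying after the first year on the biologic.
    """

    name: str
    induction_schedule: list[DoseEvent]
    maintenance_interval_weeks: int
    maintenance_dose_mg: float
    price_per_unit: float
    mg_per_unit: float
    response_prob: dict[str, float]
    annual_dropout_prob: float
    annual_relapse_prob: float
    p_serious_infection_once: float
    p_malignancy_annual: float

    _FIELDS = (
        "induction_schedule", "maintenance_interval_weeks", "maintenance_dose_mg",
        "price_per_unit", "mg_per_unit", "response_prob", "annual_dropout_prob",
        "annual_relapse_prob", "p_serious_infection_once", "p_malignancy_annual",
    )

    @staticmethod
    def from_dict(name: str, d: Mapping[str, Any], path: str) -> "DrugProfile":
        d = _check_mapping(d, path)
        _check_keys(d, DrugProfile._FIELDS, path)
        sched_raw = _get(d, "induction_schedule", path)
        if not isinstance(sched_raw, Sequence) or isinstance(sched_raw, str):
            raise SchemaError(f"{path}.induction_schedule: expected a list")
        sched = [DoseEvent.from_dict(e, f"{path}.induction_schedule[{i}]")
                 for i, e in enumerate(sched_raw)]
        rp_raw = _check_mapping(_get(d, "response_prob", path), f"{path}.response_prob")
        _check_keys(rp_raw, PASI_LEVELS, f"{path}.response_prob")
        rp = {lvl: _num(_get(rp_raw, lvl, f"{path}.response_prob"),
                        f"{path}.response_prob.{lvl}") for lvl in PASI_LEVELS}
        return DrugProfile(
            name=name,
            induction_schedule=sched,
            maintenance_interval_weeks=int(_num(_get(d, "maintenance_interval_weeks", path),
                                                f"{path}.maintenance_interval_weeks")),
            maintenance_dose_mg=_num(_get(d, "maintenance_dose_mg", path),
                                     f"{path}.maintenance_dose_mg"),
            price_per_unit=_num(_get(d, "price_per_unit", path), f"{path}.price_per_unit"),
            mg_per_unit=_num(_get(d, "mg_per_unit", path), f"{path}.mg_per_unit"),
            response_prob=rp,
            annual_dropout_prob=_num(_get(d, "annual_dropout_prob", path),
                                     f"{path}.annual_dropout_prob"),
            annual_relapse_prob=_num(_get(d, "annual_relapse_prob", path),
                                     f"{path}.annual_relapse_prob"),
            p_serious_infection_once=_num(_get(d, "p_serious_infection_once", path),
                                          f"{path}.p_serious_infection_once"),
            p_malignancy_annual=_num(_get(d, "p_malignancy_annual", path),
                                     f"{path}.p_malignancy_annual"),
        )

    def to_dict(self) -> dict:
        return {
            "induction_schedule": [e.to_dict() for e in self.induction_schedule],
            "maintenance_interval_weeks": self.maintenance_interval_weeks,
            "maintenance_dose_mg": self.maintenance_dose_mg,
            "price_per_unit": self.price_per_unit,
            "mg_per_unit": self.mg_per_unit,
            "response_prob": dict(self.response_prob),
            "annual_dropout_prob": self.annual_dropout_prob,
            "annual_relapse_prob": self.annual_relapse_prob,
            "p_serious_infection_once": self.p_serious_infection_once,
            "p_malignancy_annual": self.p_malignancy_annual,
        }

    @property
    def last_induction_week(self) -> int:
        if not self.induction_schedule:
            return 0
        return max(e.week_offset for e in self.induction_schedule)


@dataclass
class SoCProfile:
    """Conventional systemic therapy: an 85:15 MTX/ciclosporin mix by default.

    MTX 25 mg/week (tablet or injection price variant), ciclosporin
    5 mg/kg/day at an assumed 60 kg body weight.  ``response_prob_soc`` is
    carried as a model input for sensitivity analyses; the SoC health state
    itself is absorbing (no response branching).  Cirrhosis is an annual
    adverse-event risk for the MTX fraction.
    """

    mtx_price_tablet: float
    mtx_price_injection: float
    csa_price: float
    response_prob_soc: float
    p_cirrhosis_annual: float
    mtx_weekly_dose_mg: float = 25.0
    csa_dose_mg_per_kg_day: float = 5.0
    patient_weight_kg: float = 60.0
    mix_mtx_fraction: float = 0.85
    mtx_variant: str = "tablet"
    soc_lab_frequency_per_year: float = 4.0

    _FIELDS = (
        "mtx_price_tablet", "mtx_price_injection", "csa_price", "response_prob_soc",
        "p_cirrhosis_annual", "mtx_weekly_dose_mg", "csa_dose_mg_per_kg_day",
        "patient_weight_kg", "mix_mtx_fraction", "mtx_variant",
        "soc_lab_frequency_per_year",
    )

    @staticmethod
    def from_dict(d: Mapping[str, Any], path: str) -> "SoCProfile":
        d = _check_mapping(d, path)
        _check_keys(d, SoCProfile._FIELDS, path)
        return SoCProfile(
            mtx_price_tablet=_num(_get(d, "mtx_price_tablet", path), f"{path}.mtx_price_tablet"),
            mtx_price_injection=_num(_get(d, "mtx_price_injection", path),
                                     f"{path}.mtx_price_injection"),
            csa_price=_num(_get(d, "csa_price", path), f"{path}.csa_price"),
            response_prob_soc=_num(_get(d, "response_prob_soc", path),
                                   f"{path}.response_prob_soc"),
            p_cirrhosis_annual=_num(_get(d, "p_cirrhosis_annual", path),
                                    f"{path}.p_cirrhosis_annual"),
            mtx_weekly_dose_mg=_opt_num(d, "mtx_weekly_dose_mg", 25.0, path),
            csa_dose_mg_per_kg_day=_opt_num(d, "csa_dose_mg_per_kg_day", 5.0, path),
            patient_weight_kg=_opt_num(d, "patient_weight_kg", 60.0, path),
            mix_mtx_fraction=_opt_num(d, "mix_mtx_fraction", 0.85, path),
            mtx_variant=_str(d.get("mtx_variant", "tablet"), f"{path}.mtx_variant"),
            soc_lab_frequency_per_year=_opt_num(d, "soc_lab_frequency_per_year", 4.0, path),
        )

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self._FIELDS}


@dataclass
class UtilitySet:
    """Health-state utilities (0 = death, 1 = full health) and AE decrements.

    ``u_baseline`` applies to uncontrolled disease (SoC state and induction);
    responders accrue the utility of their response level.  ``du_*`` are
    one-time QALY decrements per adverse event.
    """

    u_baseline: float
    u_pasi75: float
    u_pasi90: float
    u_pasi100: float
    du_infection: float
    du_malignancy: float
    du_cirrhosis: float

    _FIELDS = ("u_baseline", "u_pasi75", "u_pasi90", "u_pasi100",
               "du_infection", "du_malignancy", "du_cirrhosis")

    def responder_utility(self, level: str) -> float:
        return {"PASI75": self.u_pasi75, "PASI90": self.u_pasi90,
                "PASI100": self.u_pasi100}[level]

    @staticmethod
    def from_dict(d: Mapping[str, Any], path: str) -> "UtilitySet":
        d = _check_mapping(d, path)
        _check_keys(d, UtilitySet._FIELDS, path)
        return UtilitySet(**{f: _num(_get(d, f, path), f"{path}.{f}")
                             for f in UtilitySet._FIELDS})

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self._FIELDS}


@dataclass
class CostSet:
    """Unit costs (2021 THB): labs, visits, topicals, AE management, FX rate."""

    lab_costs: dict[str, float]
    visit_cost_direct_medical: float
    nonmedical_cost_per_visit: float
    visits_per_year: float
    topical_cost_per_cycle: float
    ae_management_costs: dict[str, float]
    cpi_factor_to_2021: float = 1.0
    exchange_rate_usd_per_thb: float = 0.0313

    _FIELDS = ("lab_costs", "visit_cost_direct_medical", "nonmedical_cost_per_visit",
               "visits_per_year", "topical_cost_per_cycle", "ae_management_costs",
               "cpi_factor_to_2021", "exchange_rate_usd_per_thb")

    @staticmethod
    def from_dict(d: Mapping[str, Any], path: str) -> "CostSet":
        d = _check_mapping(d, path)
        _check_keys(d, CostSet._FIELDS, path)
        labs_raw = _check_mapping(_get(d, "lab_costs", path), f"{path}.lab_costs")
        _check_keys(labs_raw, LAB_TESTS, f"{path}.lab_costs")
        labs = {t: _num(_get(labs_raw, t, f"{path}.lab_costs"), f"{path}.lab_costs.{t}")
                for t in LAB_TESTS}
        ae_raw = _check_mapping(_get(d, "ae_management_costs", path),
                                f"{path}.ae_management_costs")
        _check_keys(ae_raw, AE_TYPES, f"{path}.ae_management_costs")
        ae = {t: _num(_get(ae_raw, t, f"{path}.ae_management_costs"),
                      f"{path}.ae_management_costs.{t}") for t in AE_TYPES}
        return CostSet(
            lab_costs=labs,
            visit_cost_direct_medical=_num(_get(d, "visit_cost_direct_medical", path),
                                           f"{path}.visit_cost_direct_medical"),
            nonmedical_cost_per_visit=_num(_get(d, "nonmedical_cost_per_visit", path),
                                           f"{path}.nonmedical_cost_per_visit"),
            visits_per_year=_num(_get(d, "visits_per_year", path), f"{path}.visits_per_year"),
            topical_cost_per_cycle=_num(_get(d, "topical_cost_per_cycle", path),
                                        f"{path}.topical_cost_per_cycle"),
            ae_management_costs=ae,
            cpi_factor_to_2021=_opt_num(d, "cpi_factor_to_2021", 1.0, path),
            exchange_rate_usd_per_thb=_opt_num(d, "exchange_rate_usd_per_thb", 0.0313, path),
        )

    def to_dict(self) -> dict:
        return {
            "lab_costs": dict(self.lab_costs),
            "visit_cost_direct_medical": self.visit_cost_direct_medical,
            "nonmedical_cost_per_visit": self.nonmedical_cost_per_visit,
            "visits_per_year": self.visits_per_year,
            "topical_cost_per_cycle": self.topical_cost_per_cycle,
            "ae_management_costs": dict(self.ae_management_costs),
            "cpi_factor_to_2021": self.cpi_factor_to_2021,
            "exchange_rate_usd_per_thb": self.exchange_rate_usd_per_thb,
        }


@dataclass
class LifeTable:
    """Age-specific annual death probabilities plus a disease relative risk."""

    annual_death_prob: dict[int, float]
    rr_psoriasis: float

    _FIELDS = ("annual_death_prob", "rr_psoriasis")

    def annual_q(self, age: int) -> float:
        if age not in self.annual_death_prob:
            raise KeyError(f"life table does not cover age {age}")
        return self.annual_death_prob[age]

    @staticmethod
    def from_dict(d: Mapping[str, Any], path: str) -> "LifeTable":
        d = _check_mapping(d, path)
        _check_keys(d, LifeTable._FIELDS, path)
        q_raw = _check_mapping(_get(d, "annual_death_prob", path),
                               f"{path}.annual_death_prob")
        q = {}
        for k, v in q_raw.items():
            try:
                age = int(k)
            except (TypeError, ValueError):
                raise SchemaError(f"{path}.annual_death_prob: non-integer age {k!r}")
            q[age] = _num(v, f"{path}.annual_death_prob.{k}")
        return LifeTable(annual_death_prob=q,
                         rr_psoriasis=_num(_get(d, "rr_psoriasis", path),
                                           f"{path}.rr_psoriasis"))

    def to_dict(self) -> dict:
        return {"annual_death_prob": {int(a): q for a, q in
                                      sorted(self.annual_death_prob.items())},
                "rr_psoriasis": self.rr_psoriasis}


@dataclass
class EconSettings:
    """Economic and structural run settings.

    cycle_length_days=14 gives 26 cycles per 364-day model year — the least
    common grid for q2w/q4w/q8w dosing and the 6-month response assessment
    (13 cycles).  ``stop_clock`` selects whether the 3-year biologic stop runs
    per biologic from its maintenance start ("per_line", default) or from
    model start ("model_start").
    """

    discount_rate_annual: float = 0.03
    cycle_length_days: float = 14.0
    start_age: int = 40
    horizon_age: int = 100
    wtp_thb_per_qaly: float = 160000.0
    response_definition: str = "PASI75"
    assessment_months: float = 6.0
    stop_years: float = 3.0
    stop_clock: str = "per_line"
    half_cycle_correction: bool = False

    _FIELDS = ("discount_rate_annual", "cycle_length_days", "start_age", "horizon_age",
               "wtp_thb_per_qaly", "response_definition", "assessment_months",
               "stop_years", "stop_clock", "half_cycle_correction")

    @property
    def cycles_per_year(self) -> int:
        return max(1, int(round(364.0 / self.cycle_length_days)))

    @property
    def weeks_per_cycle(self) -> float:
        return self.cycle_length_days / 7.0

    @property
    def n_cycles(self) -> int:
        return (self.horizon_age - self.start_age) * self.cycles_per_year

    @property
    def assessment_cycles(self) -> int:
        return max(1, int(round(self.assessment_months / 12.0 * self.cycles_per_year)))

    @staticmethod
    def from_dict(d: Mapping[str, Any], path: str) -> "EconSettings":
        d = _check_mapping(d, path)
        _check_keys(d, EconSettings._FIELDS, path)
        hc = d.get("half_cycle_correction", False)
        if not isinstance(hc, bool):
            raise SchemaError(f"{path}.half_cycle_correction: expected a boolean")
        return EconSettings(
            discount_rate_annual=_opt_num(d, "discount_rate_annual", 0.03, path),
            cycle_length_days=_opt_num(d, "cycle_length_days", 14.0, path),
            start_age=int(_opt_num(d, "start_age", 40, path)),
            horizon_age=int(_opt_num(d, "horizon_age", 100, path)),
            wtp_thb_per_qaly=_opt_num(d, "wtp_thb_per_qaly", 160000.0, path),
            response_definition=_str(d.get("response_definition", "PASI75"),
                                     f"{path}.response_definition"),
            assessment_months=_opt_num(d, "assessment_months", 6.0, path),
            stop_years=_opt_num(d, "stop_years", 3.0, path),
            stop_clock=_str(d.get("stop_clock", "per_line"), f"{path}.stop_clock"),
            half_cycle_correction=hc,
        )

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self._FIELDS}


@dataclass
class DistributionSpec:
    """Uncertainty assignment for one scalar parameter (by dotted path).

    ``family`` is one of beta | gamma | lognormal | point.  ``params`` may
    carry explicit family parameters (``alpha``/``beta``, ``shape``/``scale``,
    ``mu``/``sigma``), a standard error ``se`` for a method-of-moments fit
    around the base value, and/or a 95% CI ``ci: [low, high]`` used by the
    one-way sensitivity analysis.
    """

    path: str
    family: str
    params: dict[str, Any] = field(default_factory=dict)

    FAMILIES = ("beta", "gamma", "lognormal", "point")

    @staticmethod
    def from_dict(d: Mapping[str, Any], path: str) -> "DistributionSpec":
        d = _check_mapping(d, path)
        _check_keys(d, ("path", "family", "params"), path)
        params = d.get("params", {}) or {}
        params = dict(_check_mapping(params, f"{path}.params"))
        return DistributionSpec(path=_str(_get(d, "path", path), f"{path}.path"),
                                family=_str(_get(d, "family", path), f"{path}.family"),
                                params=params)

    def to_dict(self) -> dict:
        return {"path": self.path, "family": self.family, "params": dict(self.params)}


@dataclass(frozen=True)
class TreatmentLine:
    """One treatment line: one drug, or two alternatives with a split."""

    drugs: tuple[str, ...]
    split: tuple[float, ...]

    @staticmethod
    def of(*drugs: str, split: Sequence[float] | None = None) -> "TreatmentLine":
        if split is None:
            split = [1.0 / len(drugs)] * len(drugs)
        return TreatmentLine(drugs=tuple(drugs), split=tuple(split))


@dataclass(frozen=True)
class Strategy:
    """An ordered sequence of biologic lines; empty ``lines`` is pure SoC."""

    name: str
    lines: tuple[TreatmentLine, ...] = ()

    @property
    def is_soc(self) -> bool:
        return len(self.lines) == 0


@dataclass
class ParameterSet:
    """The complete, validated model input bundle."""

    drugs: dict[str, DrugProfile]
    soc: SoCProfile
    utilities: UtilitySet
    costs: CostSet
    life_table: LifeTable
    settings: EconSettings
    psa_specs: list[DistributionSpec] = field(default_factory=list)
    alt_utilities: UtilitySet | None = None
    provenance: str = "synthetic"

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        d = {
            "provenance": self.provenance,
            "drugs": {name: drug.to_dict() for name, drug in self.drugs.items()},
            "soc": self.soc.to_dict(),
            "utilities": self.utilities.to_dict(),
            "costs": self.costs.to_dict(),
            "life_table": self.life_table.to_dict(),
            "settings": self.settings.to_dict(),
            "psa_specs": [s.to_dict() for s in self.psa_specs],
        }
        if self.alt_utilities is not None:
            d["alt_utilities"] = self.alt_utilities.to_dict()
        return d

    @staticmethod
    def from_dict(d: Mapping[str, Any]) -> "ParameterSet":
        d = _check_mapping(d, "$")
        _check_keys(d, ("provenance", "drugs", "soc", "utilities", "alt_utilities",
                        "costs", "life_table", "settings", "psa_specs"), "$")
        drugs_raw = _check_mapping(_get(d, "drugs", "$"), "drugs")
        drugs = {name: DrugProfile.from_dict(name, dd, f"drugs.{name}")
                 for name, dd in drugs_raw.items()}
        specs_raw = d.get("psa_specs", []) or []
        if not isinstance(specs_raw, Sequence) or isinstance(specs_raw, str):
            raise SchemaError("psa_specs: expected a list")
        alt = d.get("alt_utilities")
        return ParameterSet(
            drugs=drugs,
            soc=SoCProfile.from_dict(_get(d, "soc", "$"), "soc"),
            utilities=UtilitySet.from_dict(_get(d, "utilities", "$"), "utilities"),
            costs=CostSet.from_dict(_get(d, "costs", "$"), "costs"),
            life_table=LifeTable.from_dict(_get(d, "life_table", "$"), "life_table"),
            settings=EconSettings.from_dict(_get(d, "settings", "$"), "settings"),
            psa_specs=[DistributionSpec.from_dict(s, f"psa_specs[{i}]")
                       for i, s in enumerate(specs_raw)],
            alt_utilities=None if alt is None else
                UtilitySet.from_dict(alt, "alt_utilities"),
            provenance=_str(d.get("provenance", "synthetic"), "provenance"),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _apply_cpi(ps: ParameterSet) -> None:
    """Inflate raw-year monetary inputs to 2021 THB in place."""
    f = ps.costs.cpi_factor_to_2021
    if f == 1.0:
        return
    for drug in ps.drugs.values():
        drug.price_per_unit *= f
    ps.soc.mtx_price_tablet *= f
    ps.soc.mtx_price_injection *= f
    ps.soc.csa_price *= f
    ps.costs.lab_costs = {k: v * f for k, v in ps.costs.lab_costs.items()}
    ps.costs.visit_cost_direct_medical *= f
    ps.costs.nonmedical_cost_per_visit *= f
    ps.costs.topical_cost_per_cycle *= f
    ps.costs.ae_management_costs = {k: v * f
                                    for k, v in ps.costs.ae_management_costs.items()}
    ps.costs.cpi_factor_to_2021 = 1.0


def load_parameter_set(path: str, inflate: bool = True) -> ParameterSet:
    """Read a YAML config; reject unknown keys; raise on validation failure."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ps = ParameterSet.from_dict(raw)
    if inflate:
        _apply_cpi(ps)
    violations = validate_parameter_set(ps)
    if violations:
        msgs = "\n  ".join(str(v) for v in violations)
        raise SchemaError(f"invalid parameter set ({len(violations)} violation(s)):\n  {msgs}")
    return ps


def save_parameter_set(ps: ParameterSet, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ps.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _prob(v: float, path: str, out: list[Violation]) -> None:
    if not (0.0 <= v <= 1.0):
        out.append(Violation(path, "probability bounds", f"probability out of [0,1]: {v}"))

def _nonneg(v: float, path: str, rule: str, out: list[Violation]) -> None:
    if v < 0:
        out.append(Violation(path, rule, f"must be >= 0, got {v}"))


def validate_parameter_set(ps: ParameterSet) -> list[Violation]:
    """Check every type invariant; violations are data, not exceptions."""
    out: list[Violation] = []

    for name, drug in ps.drugs.items():
        p = f"drugs.{name}"
        offsets = [e.week_offset for e in drug.induction_schedule]
        if len(set(offsets)) != len(offsets):
            out.append(Violation(f"{p}.induction_schedule", "unique week offsets",
                                 "duplicate week_offset in schedule"))
        for i, e in enumerate(drug.induction_schedule):
            if e.dose_mg <= 0:
                out.append(Violation(f"{p}.induction_schedule[{i}].dose_mg",
                                     "positive dose", f"dose_mg must be > 0, got {e.dose_mg}"))
            if e.week_offset < 0:
                out.append(Violation(f"{p}.induction_schedule[{i}].week_offset",
                                     "nonnegative offset", "week_offset must be >= 0"))
        if drug.maintenance_interval_weeks <= 0:
            out.append(Violation(f"{p}.maintenance_interval_weeks", "positive interval",
                                 "must be > 0"))
        if drug.maintenance_dose_mg <= 0:
            out.append(Violation(f"{p}.maintenance_dose_mg", "positive dose", "must be > 0"))
        if drug.mg_per_unit <= 0:
            out.append(Violation(f"{p}.mg_per_unit", "positive unit size", "must be > 0"))
        _nonneg(drug.price_per_unit, f"{p}.price_per_unit", "nonnegative price", out)
        for lvl in PASI_LEVELS:
            _prob(drug.response_prob[lvl], f"{p}.response_prob.{lvl}", out)
        rp = drug.response_prob
        if not (rp["PASI75"] >= rp["PASI90"] >= rp["PASI100"]):
            out.append(Violation(f"{p}.response_prob", "response monotonicity",
                                 "requires PASI75 >= PASI90 >= PASI100"))
        for fld in ("annual_dropout_prob", "annual_relapse_prob",
                    "p_serious_infection_once", "p_malignancy_annual"):
            _prob(getattr(drug, fld), f"{p}.{fld}", out)

    soc = ps.soc
    if not (0.0 <= soc.mix_mtx_fraction <= 1.0):
        out.append(Violation("soc.mix_mtx_fraction", "mix bounds", "must be in [0,1]"))
    for fld in ("mtx_weekly_dose_mg", "csa_dose_mg_per_kg_day", "patient_weight_kg"):
        if getattr(soc, fld) <= 0:
            out.append(Violation(f"soc.{fld}", "positive dose", "must be > 0"))
    for fld in ("mtx_price_tablet", "mtx_price_injection", "csa_price"):
        _nonneg(getattr(soc, fld), f"soc.{fld}", "nonnegative price", out)
    _prob(soc.response_prob_soc, "soc.response_prob_soc", out)
    _prob(soc.p_cirrhosis_annual, "soc.p_cirrhosis_annual", out)
    if soc.mtx_variant not in ("tablet", "injection"):
        out.append(Violation("soc.mtx_variant", "variant vocabulary",
                             f"must be tablet|injection, got {soc.mtx_variant!r}"))
    if soc.soc_lab_frequency_per_year <= 0:
        out.append(Violation("soc.soc_lab_frequency_per_year", "positive frequency",
                             "must be > 0"))

    u = ps.utilities
    for us, upath in ((u, "utilities"),) + (
            ((ps.alt_utilities, "alt_utilities"),) if ps.alt_utilities else ()):
        if not (0.0 <= us.u_baseline <= us.u_pasi75 <= us.u_pasi90 <= us.u_pasi100 <= 1.0):
            out.append(Violation(upath, "utility ordering",
                                 "requires 0 <= u_baseline <= u_pasi75 <= u_pasi90"
                                 " <= u_pasi100 <= 1"))
        for fld in ("du_infection", "du_malignancy", "du_cirrhosis"):
            _nonneg(getattr(us, fld), f"{upath}.{fld}", "nonnegative decrement", out)

    c = ps.costs
    for t, v in c.lab_costs.items():
        _nonneg(v, f"costs.lab_costs.{t}", "nonnegative cost", out)
    for t, v in c.ae_management_costs.items():
        _nonneg(v, f"costs.ae_management_costs.{t}", "nonnegative cost", out)
    for fld in ("visit_cost_direct_medical", "nonmedical_cost_per_visit",
                "visits_per_year", "topical_cost_per_cycle"):
        _nonneg(getattr(c, fld), f"costs.{fld}", "nonnegative cost", out)
    if c.exchange_rate_usd_per_thb <= 0:
        out.append(Violation("costs.exchange_rate_usd_per_thb", "positive rate",
                             "must be > 0"))
    if c.cpi_factor_to_2021 <= 0:
        out.append(Violation("costs.cpi_factor_to_2021", "positive factor", "must be > 0"))

    lt = ps.life_table
    if lt.rr_psoriasis < 0:
        out.append(Violation("life_table.rr_psoriasis", "nonnegative RR", "must be >= 0"))
    for age, q in lt.annual_death_prob.items():
        _prob(q, f"life_table.annual_death_prob.{age}", out)
    s = ps.settings
    missing = [a for a in range(s.start_age, s.horizon_age)
               if a not in lt.annual_death_prob]
    if missing:
        out.append(Violation("life_table.annual_death_prob", "life table coverage",
                             f"missing ages {missing[:5]}{'...' if len(missing) > 5 else ''}"
                             f" for horizon [{s.start_age}, {s.horizon_age})"))

    if s.discount_rate_annual < 0:
        out.append(Violation("settings.discount_rate_annual", "nonnegative rate",
                             "must be >= 0"))
    if not s.start_age < s.horizon_age:
        out.append(Violation("settings.horizon_age", "horizon ordering",
                             "requires start_age < horizon_age"))
    if s.assessment_months <= 0:
        out.append(Violation("settings.assessment_months", "positive assessment",
                             "must be > 0"))
    if s.cycle_length_days <= 0:
        out.append(Violation("settings.cycle_length_days", "positive cycle", "must be > 0"))
    if s.stop_years <= 0:
        out.append(Violation("settings.stop_years", "positive stop", "must be > 0"))
    if s.response_definition not in PASI_LEVELS:
        out.append(Violation("settings.response_definition", "response vocabulary",
                             f"must be one of {PASI_LEVELS}"))
    if s.stop_clock not in ("per_line", "model_start"):
        out.append(Violation("settings.stop_clock", "clock vocabulary",
                             "must be per_line|model_start"))
    if s.wtp_thb_per_qaly < 0:
        out.append(Violation("settings.wtp_thb_per_qaly", "nonnegative WTP", "must be >= 0"))

    for i, spec in enumerate(ps.psa_specs):
        p = f"psa_specs[{i}]"
        if spec.family not in DistributionSpec.FAMILIES:
            out.append(Violation(f"{p}.family", "family vocabulary",
                                 f"must be one of {DistributionSpec.FAMILIES}"))
        try:
            get_param(ps, spec.path)
        except (KeyError, AttributeError):
            out.append(Violation(f"{p}.path", "path resolution",
                                 f"parameter path {spec.path!r} does not resolve"))
        pr = spec.params
        if "alpha" in pr or "beta" in pr:
            if pr.get("alpha", 1.0) <= 0 or pr.get("beta", 1.0) <= 0:
                out.append(Violation(f"{p}.params", "beta parameters",
                                     "alpha and beta must be > 0"))
        if pr.get("se", 1.0) is not None and pr.get("se", 1.0) <= 0:
            out.append(Violation(f"{p}.params.se", "positive SE", "must be > 0"))
        ci = pr.get("ci")
        if ci is not None and (len(ci) != 2 or ci[0] > ci[1]):
            out.append(Violation(f"{p}.params.ci", "CI ordering",
                                 "ci must be [low, high] with low <= high"))
    return out


# ---------------------------------------------------------------------------
# dotted-path access
# ---------------------------------------------------------------------------

def _walk(obj: Any, tokens: list[str]):
    """Yield (container, key) pairs resolving a dotted path step by step."""
    for tok in tokens:
        if isinstance(obj, Mapping):
            if tok not in obj:
                raise KeyError(f"no key {tok!r} in mapping")
            yield obj, tok
            obj = obj[tok]
        elif dataclasses.is_dataclass(obj):
            if not hasattr(obj, tok):
                raise AttributeError(f"{type(obj).__name__} has no field {tok!r}")
            yield obj, tok
            obj = getattr(obj, tok)
        else:
            raise AttributeError(f"cannot descend into {type(obj).__name__} with {tok!r}")


def get_param(ps: ParameterSet, path: str) -> Any:
    """Fetch a scalar by dotted path, e.g. ``drugs.secukinumab.response_prob.PASI75``."""
    obj = ps
    for container, key in _walk(ps, path.split(".")):
        obj = container[key] if isinstance(container, Mapping) else getattr(container, key)
    return obj


def set_param(ps: ParameterSet, path: str, value: Any) -> None:
    """Assign a scalar by dotted path (in place)."""
    pairs = list(_walk(ps, path.split(".")))
    container, key = pairs[-1]
    if isinstance(container, Mapping):
        container[key] = value
    else:
        setattr(container, key, value)


# ---------------------------------------------------------------------------
# canonical strategies
# ---------------------------------------------------------------------------

def default_strategies(ps: ParameterSet) -> list[Strategy]:
    """The four compared strategies: SoC and the three biologic sequences.

    Sequence 1: secukinumab → (ixekizumab | brodalumab) → guselkumab.
    Sequence 2: ixekizumab → (secukinumab | brodalumab) → guselkumab.
    Sequence 3: brodalumab → (ixekizumab | secukinumab) → guselkumab.
    Second-line alternatives split 50:50.
    """
    need = {"secukinumab", "ixekizumab", "brodalumab", "guselkumab"}
    missing = need - set(ps.drugs)
    if missing:
        raise SchemaError(f"parameter set lacks drugs {sorted(missing)} needed for the "
                          "canonical sequences")
    mk = TreatmentLine.of
    return [
        Strategy("SoC"),
        Strategy("Sequence1", (mk("secukinumab"), mk("ixekizumab", "brodalumab"),
                               mk("guselkumab"))),
        Strategy("Sequence2", (mk("ixekizumab"), mk("secukinumab", "brodalumab"),
                               mk("guselkumab"))),
        Strategy("Sequence3", (mk("brodalumab"), mk("ixekizumab", "secukinumab"),
                               mk("guselkumab"))),
    ]
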