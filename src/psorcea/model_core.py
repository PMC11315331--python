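"""Discrete-cycle cohort engine for sequential biologic therapy.

The model is a hybrid: a decision-tree induction cascade (each treatment line
is assessed for response after a fixed induction period; failures move to the
next line, exhausted sequences fall back to conventional systemic therapy)
feeding a Markov maintenance phase.  Maintenance on a biologic can end by
drop-out (to SoC), by the planned stop after ``stop_years`` of continuity (to
a topical-only off-treatment state), or by death.  Off-treatment patients
relapse at a drug-specific annual rate and are retreated with their last
biologic for life.

States, per treatment arm (a line may hold two alternative drugs):

* ``IND`` — induction dosing, response not yet assessed (baseline utility);
* ``MAINT`` — maintenance therapy after response (responder utility);
* ``OFF`` — planned stop, topical treatment only (responder utility until
  relapse);
* ``RETX`` — retreatment after relapse, continued lifelong (no further
  planned stop, no drop-out);

plus the absorbing ``SOC`` and ``DEAD`` states.  Mortality is identical in
every alive state (biologics are assumed not to prolong life): the
age-specific annual death probability times a psoriasis relative risk, capped
at 1, converted to a per-cycle probability.

Accrual convention: the cohort distribution is recorded at cycle boundaries;
cycle-``t`` costs, QALYs and life-years are weighted by the end-of-cycle
(post-transition) occupancy, so a constant per-cycle death probability ``q``
yields the geometric life expectancy ``(1-q)/q`` cycles in the limit.  An
optional half-cycle correction averages start- and end-of-cycle occupancy.

Adverse events (serious infection at biologic start, malignancy after the
first year on a biologic, cirrhosis for the MTX fraction of SoC) are accrued
as expected event counts with attached costs, not as explicit states.
Infection and malignancy additionally carry one-time QALY decrements;
cirrhosis is costed only, so the MTX:ciclosporin mix affects costs alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import costing
from .parameters import (
    DrugProfile, EconSettings, ParameterSet, Strategy, UtilitySet,
)

__all__ = [
    "EVENT_TYPES",
    "COST_CATEGORIES",
    "Arm",
    "CohortTrace",
    "StrategyResult",
    "annual_prob_to_cycle_prob",
    "mortality_prob",
    "induction_cascade",
    "run_cohort",
    "pathway_oracle",
    "accrue_outcomes",
    "run_strategy",
]

EVENT_TYPES = ("serious_infection", "malignancy", "cirrhosis", "relapse", "dropout")

COST_CATEGORIES = ("drug_line1", "drug_line2", "drug_line3", "labs_screening",
                   "labs_monitoring", "soc_drug", "soc_labs", "visit", "nonmedical",
                   "topical", "ae")


def annual_prob_to_cycle_prob(p_annual: float, cycles_per_year: int) -> float:
    """Convert an annual probability to the equivalent per-cycle probability.

    Uses the constant-rate identity ``1 - (1 - p)**(1/cycles_per_year)``.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"p_annual must be in [0,1], got {p_annual}")
    if cycles_per_year < 1:
        raise ValueError("cycles_per_year must be >= 1")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def mortality_prob(age: int, lt, cycles_per_year: int) -> float:
    """Per-cycle death probability at integer ``age``: annual q × RR, capped at 1."""
    q_annual = min(1.0, lt.annual_q(age) * lt.rr_psoriasis)
    return annual_prob_to_cycle_prob(q_annual, cycles_per_year)


# ---------------------------------------------------------------------------
# state-space construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Arm:
    """One drug within one treatment line, with its share of line entrants."""

    index: int           # arm index within the strategy
    line: int            # 0-based line index
    drug: DrugProfile
    entry_split: float   # fraction of the line's entrants starting this drug
    label: str           # e.g. "1", "2a", "2b", "3"


def _build_arms(strategy: Strategy, ps: ParameterSet) -> list[Arm]:
    arms: list[Arm] = []
    for li, line in enumerate(strategy.lines):
        if abs(sum(line.split) - 1.0) > 1e-9:
            raise ValueError(f"line {li + 1} split fractions must sum to 1")
        multi = len(line.drugs) > 1
        for ai, (name, frac) in enumerate(zip(line.drugs, line.split)):
            if name not in ps.drugs:
                raise KeyError(f"strategy {strategy.name!r} references unknown drug "
                               f"{name!r}")
            suffix = chr(ord("a") + ai) if multi else ""
            arms.append(Arm(index=len(arms), line=li, drug=ps.drugs[name],
                            entry_split=frac, label=f"{li + 1}{suffix}"))
    return arms


def _state_names(arms: list[Arm]) -> list[str]:
    names = []
    for arm in arms:
        names += [f"IND{arm.label}", f"MAINT{arm.label}", f"OFF{arm.label}",
                  f"RETX{arm.label}"]
    return names + ["SOC", "DEAD"]


def _stop_cycle(arm: Arm, settings: EconSettings) -> int:
    """Absolute cycle at which this arm's maintenance phase ends."""
    a = settings.assessment_cycles
    m = (arm.line + 1) * a
    stop_cycles = int(round(settings.stop_years * settings.cycles_per_year))
    if settings.stop_clock == "model_start":
        return max(m, stop_cycles)
    return m + stop_cycles


# ---------------------------------------------------------------------------
# decision-tree front end
# ---------------------------------------------------------------------------

def induction_cascade(strategy: Strategy, ps: ParameterSet) -> pd.DataFrame:
    """Cohort fractions (ignoring death) routed to each maintenance line or SoC.

    Fractions are products of line response/failure probabilities; a two-drug
    line blends its response probability by the line split.
    """
    level = ps.settings.response_definition
    rows = []
    reach = 1.0
    for li, line in enumerate(strategy.lines):
        for name in line.drugs:
            if name not in ps.drugs:
                raise KeyError(f"strategy {strategy.name!r} references unknown drug "
                               f"{name!r}")
        p_line = sum(frac * ps.drugs[name].response_prob[level]
                     for name, frac in zip(line.drugs, line.split))
        rows.append({"destination": f"MAINT_{li + 1}",
                     "assessment_cycle": (li + 1) * ps.settings.assessment_cycles,
                     "fraction": reach * p_line})
        reach *= (1.0 - p_line)
    rows.append({"destination": "SOC",
                 "assessment_cycle": len(strategy.lines) * ps.settings.assessment_cycles,
                 "fraction": reach})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trace container
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle state occupancy with event and cost/QALY/LY accrual streams.

    ``occupancy[t]`` is the cohort distribution at the start of cycle ``t``
    (row ``n_cycles`` is the terminal distribution).  Event counts and
    accruals are indexed by cycle 0..n_cycles-1 and are undiscounted.
    """

    strategy_name: str
    state_names: list[str]
    occupancy: np.ndarray                      # (n_cycles+1, n_states)
    events: dict[str, np.ndarray]              # each (n_cycles,)
    cost_by_category: dict[str, np.ndarray]    # each (n_cycles,)
    cycle_qaly: np.ndarray                     # (n_cycles,)
    cycle_ly: np.ndarray                       # (n_cycles,)
    cycles_per_year: int

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cycle_cost(self) -> np.ndarray:
        return sum(self.cost_by_category.values())

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle: occupancy, events, per-category costs, accruals."""
        n = self.n_cycles
        data: dict[str, np.ndarray] = {"cycle": np.arange(n)}
        for j, s in enumerate(self.state_names):
            data[f"occ_{s}"] = self.occupancy[:n, j]
        for ev in EVENT_TYPES:
            data[f"event_{ev}"] = self.events[ev]
        for cat in COST_CATEGORIES:
            data[f"cost_{cat}"] = self.cost_by_category[cat]
        data["cycle_cost"] = self.cycle_cost
        data["cycle_qaly"] = self.cycle_qaly
        data["cycle_ly"] = self.cycle_ly
        return pd.DataFrame(data)


@dataclass
class StrategyResult:
    """Discounted and undiscounted totals for one strategy run."""

    strategy_name: str
    total_cost_thb: float
    total_ly: float
    total_qaly: float
    undiscounted_cost_thb: float = 0.0
    undiscounted_ly: float = 0.0
    undiscounted_qaly: float = 0.0
    cost_breakdown: dict[str, float] = field(default_factory=dict)
    cost_breakdown_undiscounted: dict[str, float] = field(default_factory=dict)
    provenance: str = "model"


# ---------------------------------------------------------------------------
# cohort propagation
# ---------------------------------------------------------------------------

def _alive_matrices(arms: list[Arm], strategy: Strategy, ps: ParameterSet,
                    n_states: int):
    """Base alive-conditional transition matrix plus boundary-cycle overrides.

    Returns (M0, {boundary_cycle: matrix}) where a boundary matrix applies to
    the transition *entering* that cycle.
    """
    s = ps.settings
    cpy = s.cycles_per_year
    a = s.assessment_cycles
    level = s.response_definition
    soc_ix, dead_ix = n_states - 2, n_states - 1

    def idx(arm: Arm, kind: str) -> int:
        return arm.index * 4 + {"IND": 0, "MAINT": 1, "OFF": 2, "RETX": 3}[kind]

    m0 = np.zeros((n_states, n_states))
    m0[soc_ix, soc_ix] = 1.0
    m0[dead_ix, dead_ix] = 1.0
    for arm in arms:
        d = annual_prob_to_cycle_prob(arm.drug.annual_dropout_prob, cpy)
        r = annual_prob_to_cycle_prob(arm.drug.annual_relapse_prob, cpy)
        m0[idx(arm, "IND"), idx(arm, "IND")] = 1.0
        m0[idx(arm, "MAINT"), soc_ix] = d
        m0[idx(arm, "MAINT"), idx(arm, "MAINT")] = 1.0 - d
        m0[idx(arm, "OFF"), idx(arm, "RETX")] = r
        m0[idx(arm, "OFF"), idx(arm, "OFF")] = 1.0 - r
        m0[idx(arm, "RETX"), idx(arm, "RETX")] = 1.0

    n_lines = len(strategy.lines)
    boundaries: dict[int, np.ndarray] = {}

    def mat_for(b: int) -> np.ndarray:
        if b not in boundaries:
            boundaries[b] = m0.copy()
        return boundaries[b]

    for arm in arms:
        b = (arm.line + 1) * a  # assessment boundary of this arm's line
        mat = mat_for(b)
        row = idx(arm, "IND")
        mat[row, :] = 0.0
        p = arm.drug.response_prob[level]
        dest = idx(arm, "MAINT") if b < _stop_cycle(arm, s) else idx(arm, "OFF")
        mat[row, dest] += p
        if arm.line + 1 < n_lines:
            for nxt in arms:
                if nxt.line == arm.line + 1:
                    mat[row, idx(nxt, "IND")] += (1.0 - p) * nxt.entry_split
        else:
            mat[row, soc_ix] += 1.0 - p

    for arm in arms:
        b = _stop_cycle(arm, s)
        mat = mat_for(b)
        row = idx(arm, "MAINT")
        mat[row, :] = 0.0
        mat[row, idx(arm, "OFF")] = 1.0

    return m0, boundaries


def run_cohort(strategy: Strategy, ps: ParameterSet,
               n_cycles: int | None = None) -> CohortTrace:
    """Propagate the cohort over the full horizon and accrue all streams."""
    s = ps.settings
    cpy = s.cycles_per_year
    n = s.n_cycles if n_cycles is None else int(n_cycles)
    arms = _build_arms(strategy, ps)
    names = _state_names(arms)
    n_states = len(names)
    soc_ix, dead_ix = n_states - 2, n_states - 1

    def idx(arm: Arm, kind: str) -> int:
        return arm.index * 4 + {"IND": 0, "MAINT": 1, "OFF": 2, "RETX": 3}[kind]

    m0, boundaries = _alive_matrices(arms, strategy, ps, n_states)

    q_cycle = np.array([mortality_prob(s.start_age + t // cpy, ps.life_table, cpy)
                        for t in range(n)])

    occ = np.zeros((n + 1, n_states))
    if strategy.is_soc:
        occ[0, soc_ix] = 1.0
    else:
        for arm in arms:
            if arm.line == 0:
                occ[0, idx(arm, "IND")] = arm.entry_split

    for t in range(n):
        mat = boundaries.get(t + 1, m0)
        a_next = occ[t] @ mat
        if not np.all(np.isfinite(a_next)):
            raise FloatingPointError(f"non-finite occupancy at cycle {t + 1}")
        q = q_cycle[t]
        dead = a_next[dead_ix]
        occ[t + 1] = a_next * (1.0 - q)
        occ[t + 1, dead_ix] = dead + q * (1.0 - dead)

    # accrual weights: end-of-cycle occupancy (optionally half-cycle corrected)
    if s.half_cycle_correction:
        w = 0.5 * (occ[:-1] + occ[1:])
    else:
        w = occ[1:]

    # --- expected event counts ----------------------------------------------
    events = {ev: np.zeros(n) for ev in EVENT_TYPES}
    surv = 1.0 - q_cycle
    for arm in arms:
        d = annual_prob_to_cycle_prob(arm.drug.annual_dropout_prob, cpy)
        r = annual_prob_to_cycle_prob(arm.drug.annual_relapse_prob, cpy)
        p_mal = annual_prob_to_cycle_prob(arm.drug.p_malignancy_annual, cpy)
        stop = _stop_cycle(arm, s)
        drop = occ[:n, idx(arm, "MAINT")] * d * surv
        if 0 <= stop - 1 < n:
            drop[stop - 1] = 0.0  # the stop transition pre-empts drop-out
        events["dropout"] += drop
        events["relapse"] += occ[:n, idx(arm, "OFF")] * r * surv
        line_start = arm.line * s.assessment_cycles
        if line_start < n:
            events["serious_infection"][line_start] += (
                arm.drug.p_serious_infection_once * occ[line_start, idx(arm, "IND")])
        mal_mask = (np.arange(n) >= line_start + cpy).astype(float)
        events["malignancy"] += p_mal * mal_mask * (
            occ[:n, idx(arm, "MAINT")] + occ[:n, idx(arm, "RETX")])
    p_cirr = annual_prob_to_cycle_prob(ps.soc.p_cirrhosis_annual, cpy)
    events["cirrhosis"] = p_cirr * occ[:n, soc_ix] * ps.soc.mix_mtx_fraction

    # --- per-category costs --------------------------------------------------
    costs = {cat: np.zeros(n) for cat in COST_CATEGORIES}
    alive_w = 1.0 - w[:, dead_ix]

    for arm in arms:
        line_start = arm.line * s.assessment_cycles
        if line_start >= n:
            continue
        cat = f"drug_line{arm.line + 1}"
        rel = costing.line_drug_cost_array(arm.drug, n - line_start, s)
        arr = np.zeros(n)
        arr[line_start:] = rel
        costs[cat] += arr * (w[:, idx(arm, "IND")] + w[:, idx(arm, "MAINT")])
        costs[cat] += (costing.maintenance_cost_per_cycle_mean(arm.drug, s)
                       * w[:, idx(arm, "RETX")])
        costs["labs_screening"][line_start] += (
            costing.screening_cost(ps) * occ[line_start, idx(arm, "IND")])

    mon_maint = costing.monitoring_cost_per_year("MAINT", ps) / cpy
    maint_retx = np.zeros(n)
    for arm in arms:
        maint_retx += w[:, idx(arm, "MAINT")] + w[:, idx(arm, "RETX")]
    costs["labs_monitoring"] = mon_maint * maint_retx
    costs["soc_drug"] = costing.soc_drug_cost_per_cycle(ps.soc, s) * w[:, soc_ix]
    costs["soc_labs"] = (costing.monitoring_cost_per_year("SOC", ps) / cpy
                         * w[:, soc_ix])
    visits_per_cycle = ps.costs.visits_per_year / cpy
    costs["visit"] = ps.costs.visit_cost_direct_medical * visits_per_cycle * alive_w
    costs["nonmedical"] = ps.costs.nonmedical_cost_per_visit * visits_per_cycle * alive_w
    costs["topical"] = ps.costs.topical_cost_per_cycle * alive_w
    ae_cost = ps.costs.ae_management_costs
    costs["ae"] = (ae_cost["serious_infection"] * events["serious_infection"]
                   + ae_cost["malignancy"] * events["malignancy"]
                   + ae_cost["cirrhosis"] * events["cirrhosis"])

    # --- QALY / LY ------------------------------------------------------------
    # cirrhosis is accrued as a management cost only: the SoC mix must not
    # perturb QALYs (the mix scenarios vary costs alone)
    u = _state_utilities(arms, ps.utilities, s.response_definition, n_states)
    du = ps.utilities
    cycle_qaly = (w @ u) / cpy - (du.du_infection * events["serious_infection"]
                                  + du.du_malignancy * events["malignancy"])
    cycle_ly = alive_w / cpy

    return CohortTrace(strategy_name=strategy.name, state_names=names, occupancy=occ,
                       events=events, cost_by_category=costs, cycle_qaly=cycle_qaly,
                       cycle_ly=cycle_ly, cycles_per_year=cpy)


def _state_utilities(arms: list[Arm], u: UtilitySet, level: str,
                     n_states: int) -> np.ndarray:
    """Utility weight per state: baseline in induction and SoC, responder
    utility (at the active response definition) in MAINT/OFF/RETX, 0 if dead."""
    u_resp = u.responder_utility(level)
    vec = np.zeros(n_states)
    for arm in arms:
        base = arm.index * 4
        vec[base + 0] = u.u_baseline          # IND
        vec[base + 1] = u_resp                # MAINT
        vec[base + 2] = u_resp                # OFF (response retained until relapse)
        vec[base + 3] = u_resp                # RETX
    vec[n_states - 2] = u.u_baseline          # SOC
    return vec


# ---------------------------------------------------------------------------
# outcome aggregation
# ---------------------------------------------------------------------------

def accrue_outcomes(trace: CohortTrace, ps: ParameterSet) -> StrategyResult:
    """Discount and total the trace streams (annual discounting, year 0 at par)."""
    n = trace.n_cycles
    cpy = trace.cycles_per_year
    r = ps.settings.discount_rate_annual
    years = np.arange(n) // cpy
    dfac = (1.0 + r) ** (-years.astype(float))

    breakdown_u = {cat: float(arr.sum()) for cat, arr in trace.cost_by_category.items()}
    breakdown_d = {cat: float((arr * dfac).sum())
                   for cat, arr in trace.cost_by_category.items()}
    return StrategyResult(
        strategy_name=trace.strategy_name,
        total_cost_thb=sum(breakdown_d.values()),
        total_ly=float((trace.cycle_ly * dfac).sum()),
        total_qaly=float((trace.cycle_qaly * dfac).sum()),
        undiscounted_cost_thb=sum(breakdown_u.values()),
        undiscounted_ly=float(trace.cycle_ly.sum()),
        undiscounted_qaly=float(trace.cycle_qaly.sum()),
        cost_breakdown=breakdown_d,
        cost_breakdown_undiscounted=breakdown_u,
    )


def run_strategy(strategy: Strategy, ps: ParameterSet) -> StrategyResult:
    """Convenience: propagate the cohort and aggregate outcomes."""
    return accrue_outcomes(run_cohort(strategy, ps), ps)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive pathway enumeration
# ---------------------------------------------------------------------------

def pathway_oracle(strategy: Strategy, ps: ParameterSet, n_cycles: int) -> np.ndarray:
    """Exact occupancy by brute-force enumeration of every state path.

    Written independently of the matrix engine (plain per-state transition
    rules, depth-first path enumeration); tractable only for short horizons,
    hence the hard ``n_cycles <= 12`` limit.  Returns an array of shape
    ``(n_cycles + 1, n_states)`` comparable with ``run_cohort(...).occupancy``.
    """
    if n_cycles > 12:
        raise ValueError("pathway_oracle is limited to n_cycles <= 12")
    s = ps.settings
    cpy = s.cycles_per_year
    a = s.assessment_cycles
    level = s.response_definition
    arms = _build_arms(strategy, ps)
    names = _state_names(arms)
    pos = {nm: j for j, nm in enumerate(names)}
    n_lines = len(strategy.lines)

    # per-cycle death probability, recomputed from first principles
    qc = []
    for t in range(n_cycles):
        age = s.start_age + t // cpy
        q_annual = min(1.0, ps.life_table.annual_q(age) * ps.life_table.rr_psoriasis)
        qc.append(1.0 - (1.0 - q_annual) ** (1.0 / cpy))

    by_line: dict[int, list[Arm]] = {}
    for arm in arms:
        by_line.setdefault(arm.line, []).append(arm)

    def successors(state: str, t: int) -> list[tuple[str, float]]:
        """Alive-conditional transitions out of ``state`` entering cycle t+1."""
        if state == "DEAD":
            return [("DEAD", 1.0)]
        if state == "SOC":
            return [("SOC", 1.0)]
        kind = state.rstrip("ab0123456789")
        label = state[len(kind):]
        arm = next(x for x in arms if x.label == label)
        if kind == "IND":
            if t + 1 == (arm.line + 1) * a:
                p = arm.drug.response_prob[level]
                dest = ("MAINT" if (arm.line + 1) * a < _stop_cycle(arm, s)
                        else "OFF")
                out = [(f"{dest}{arm.label}", p)]
                if arm.line + 1 < n_lines:
                    for nxt in by_line[arm.line + 1]:
                        out.append((f"IND{nxt.label}", (1.0 - p) * nxt.entry_split))
                else:
                    out.append(("SOC", 1.0 - p))
                return out
            return [(state, 1.0)]
        if kind == "MAINT":
            if t + 1 == _stop_cycle(arm, s):
                return [(f"OFF{arm.label}", 1.0)]
            d = 1.0 - (1.0 - arm.drug.annual_dropout_prob) ** (1.0 / cpy)
            return [("SOC", d), (state, 1.0 - d)]
        if kind == "OFF":
            r = 1.0 - (1.0 - arm.drug.annual_relapse_prob) ** (1.0 / cpy)
            return [(f"RETX{arm.label}", r), (state, 1.0 - r)]
        if kind == "RETX":
            return [(state, 1.0)]
        raise AssertionError(state)

    occ = np.zeros((n_cycles + 1, len(names)))

    def recurse(state: str, t: int, prob: float) -> None:
        occ[t, pos[state]] += prob
        if t == n_cycles or prob == 0.0:
            return
        if state == "DEAD":
            occ[t + 1:, pos["DEAD"]] += prob
            return
        q = qc[t]
        if q > 0.0:
            occ[t + 1:, pos["DEAD"]] += prob * q
        for nxt, p in successors(state, t):
            if p > 0.0:
                recurse(nxt, t + 1, prob * (1.0 - q) * p)

    if strategy.is_soc:
        recurse("SOC", 0, 1.0)
    else:
        for arm in by_line[0]:
            if arm.entry_split > 0.0:
                recurse(f"IND{arm.label}", 0, arm.entry_split)
    return occ
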