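"""Cohort engine: rate conversions, cascade arithmetic, propagation, accrual."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psorcea.model_core import (
    accrue_outcomes, annual_prob_to_cycle_prob, induction_cascade, mortality_prob,
    pathway_oracle, run_cohort, run_strategy,
)
from psorcea.parameters import LifeTable, Strategy, TreatmentLine, default_strategies

from conftest import random_small_instance, toy_ps


# --- rate conversion --------------------------------------------------------

@pytest.mark.parametrize("p, cpy, expected", [
    (0.0, 26, 0.0),
    (1.0, 26, 1.0),
    (0.2, 26, 1.0 - 0.8 ** (1.0 / 26)),   # 0.008546...
])
def test_annual_to_cycle_prob_closed_form(p, cpy, expected):
    assert annual_prob_to_cycle_prob(p, cpy) == pytest.approx(expected, abs=1e-12)
    assert annual_prob_to_cycle_prob(0.2, 26) == pytest.approx(0.008546, abs=1e-6)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(p=st.floats(0.0, 1.0), cpy=st.integers(1, 52))
def test_annual_to_cycle_prob_round_trips(p, cpy):
    pc = annual_prob_to_cycle_prob(p, cpy)
    assert 0.0 <= pc <= 1.0
    assert 1.0 - (1.0 - pc) ** cpy == pytest.approx(p, abs=1e-12)


def test_annual_to_cycle_prob_domain_errors():
    with pytest.raises(ValueError):
        annual_prob_to_cycle_prob(-0.1, 26)
    with pytest.raises(ValueError):
        annual_prob_to_cycle_prob(1.1, 26)


@pytest.mark.parametrize("rr, q, cpy, expected", [
    (1.0, 0.0, 26, 0.0),
    (2.0, 0.6, 1, 1.0),                              # capped at annual 1.0
    (1.5, 0.01, 26, 1.0 - 0.985 ** (1.0 / 26)),      # ~5.814e-4
])
def test_mortality_prob(rr, q, cpy, expected):
    lt = LifeTable(annual_death_prob={50: q}, rr_psoriasis=rr)
    assert mortality_prob(50, lt, cpy) == pytest.approx(expected, abs=1e-12)


def test_mortality_prob_coverage_error():
    lt = LifeTable(annual_death_prob={50: 0.1}, rr_psoriasis=1.0)
    with pytest.raises(KeyError):
        mortality_prob(51, lt, 26)


# --- decision-tree cascade --------------------------------------------------

def _set_response(ps, name, p):
    ps.drugs[name].response_prob = {"PASI75": p, "PASI90": p, "PASI100": p}


def test_cascade_universal_response_goes_to_first_maintenance():
    ps = toy_ps()
    for name in ps.drugs:
        _set_response(ps, name, 1.0)
    strat = default_strategies(ps)[1]
    df = induction_cascade(strat, ps).set_index("destination")["fraction"]
    assert df["MAINT_1"] == pytest.approx(1.0)
    assert df["SOC"] == pytest.approx(0.0)


def test_cascade_universal_failure_reaches_soc_after_line3():
    ps = toy_ps()
    for name in ps.drugs:
        _set_response(ps, name, 0.0)
    strat = default_strategies(ps)[1]
    df = induction_cascade(strat, ps)
    soc = df[df.destination == "SOC"].iloc[0]
    assert soc.fraction == pytest.approx(1.0)
    assert soc.assessment_cycle == 3 * ps.settings.assessment_cycles


def test_cascade_hand_product():
    ps = toy_ps()
    _set_response(ps, "secukinumab", 0.6)
    _set_response(ps, "ixekizumab", 0.5)
    _set_response(ps, "brodalumab", 0.5)
    _set_response(ps, "guselkumab", 0.4)
    strat = default_strategies(ps)[1]
    df = induction_cascade(strat, ps).set_index("destination")["fraction"]
    assert df["MAINT_1"] == pytest.approx(0.6)
    assert df["MAINT_2"] == pytest.approx(0.4 * 0.5)
    assert df["MAINT_3"] == pytest.approx(0.4 * 0.5 * 0.4)
    assert df["SOC"] == pytest.approx(0.4 * 0.5 * 0.6)
    assert df.sum() == pytest.approx(1.0)


def test_cascade_unknown_drug_is_config_error():
    ps = toy_ps()
    strat = Strategy("bad", (TreatmentLine.of("adalimumab"),))
    with pytest.raises(KeyError, match="adalimumab"):
        induction_cascade(strat, ps)


# --- cohort propagation -----------------------------------------------------

def test_ideal_responder_holds_maintenance_until_stop_then_off():
    ps = toy_ps()
    _set_response(ps, "secukinumab", 1.0)
    ps.drugs["secukinumab"].annual_relapse_prob = 0.0
    strat = Strategy("mono", (TreatmentLine.of("secukinumab"),))
    trace = run_cohort(strat, ps)
    a = ps.settings.assessment_cycles                 # 13
    stop = a + 3 * ps.settings.cycles_per_year        # 91
    maint = trace.state_names.index("MAINT1")
    off = trace.state_names.index("OFF1")
    assert np.allclose(trace.occupancy[a:stop, maint], 1.0)
    assert np.allclose(trace.occupancy[stop:, off], 1.0)


def test_certain_death_first_cycle_absorbs_cohort():
    ps = toy_ps()
    ps.life_table.annual_death_prob = {age: 1.0 for age in range(40, 101)}
    strat = Strategy("SoC")
    trace = run_cohort(strat, ps, n_cycles=10)
    dead = trace.state_names.index("DEAD")
    assert np.allclose(trace.occupancy[1:, dead], 1.0)
    assert accrue_outcomes(trace, ps).total_ly == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(40))
def test_engine_matches_pathway_enumeration(seed):
    strat, ps, n = random_small_instance(seed)
    engine = run_cohort(strat, ps, n_cycles=n).occupancy
    oracle = pathway_oracle(strat, ps, n)
    assert np.abs(engine - oracle).max() < 1e-12


def test_occupancy_rows_conserve_mass(ps_plausible, strategies):
    for strat in strategies:
        occ = run_cohort(strat, ps_plausible).occupancy
        assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-9
        assert occ.min() >= -1e-15 and occ.max() <= 1.0 + 1e-12
        dead = occ[:, -1]
        assert np.all(np.diff(dead) >= -1e-15)        # DEAD non-decreasing


def test_oracle_refuses_long_horizons(ps_plausible):
    with pytest.raises(ValueError):
        pathway_oracle(Strategy("SoC"), ps_plausible, 13)


def test_life_years_equal_across_strategies(ps_plausible, strategies):
    results = [run_strategy(s, ps_plausible) for s in strategies]
    lys = [r.total_ly for r in results]
    ulys = [r.undiscounted_ly for r in results]
    assert max(lys) - min(lys) < 1e-9
    assert max(ulys) - min(ulys) < 1e-9


def test_geometric_life_expectancy_limit():
    # constant annual death probability q, annual cycles, long horizon:
    # expected surviving person-years -> (1-q)/q
    q = 0.05
    ps = toy_ps()
    ps.settings.cycle_length_days = 364.0
    ps.settings.start_age = 40
    ps.settings.horizon_age = 940
    ps.life_table.annual_death_prob = {a: q for a in range(40, 941)}
    res = run_strategy(Strategy("SoC"), ps)
    assert res.undiscounted_ly == pytest.approx((1 - q) / q, rel=1e-3)


def test_zero_discount_equates_totals(ps_plausible, strategies):
    ps = ps_plausible.copy()
    ps.settings.discount_rate_annual = 0.0
    for strat in strategies[:2]:
        res = run_strategy(strat, ps)
        assert res.total_cost_thb == pytest.approx(res.undiscounted_cost_thb)
        assert res.total_qaly == pytest.approx(res.undiscounted_qaly)
        assert res.total_ly == pytest.approx(res.undiscounted_ly)


def test_two_year_constant_utility_discounting_closed_form():
    # one absorbing alive state at utility 0.8 for exactly two years at 3%:
    # QALY = 0.8 * (1 + 1/1.03), year 0 undiscounted
    ps = toy_ps()
    ps.utilities.u_baseline = 0.8
    ps.settings.discount_rate_annual = 0.03
    ps.settings.horizon_age = 42
    res = run_strategy(Strategy("SoC"), ps)
    assert res.total_qaly == pytest.approx(0.8 * (1 + 1 / 1.03), abs=1e-4)
    assert res.total_ly == pytest.approx(1 + 1 / 1.03, abs=1e-4)


def test_discounted_totals_never_exceed_undiscounted(ps_plausible, strategies):
    for strat in strategies:
        res = run_strategy(strat, ps_plausible)
        assert res.total_cost_thb <= res.undiscounted_cost_thb
        assert res.total_qaly <= res.undiscounted_qaly
        assert res.total_ly <= res.undiscounted_ly


def test_qaly_monotone_in_responder_utility(ps_plausible, strategies):
    base = run_strategy(strategies[1], ps_plausible).total_qaly
    for fld in ("u_pasi75", "u_pasi90", "u_pasi100"):
        ps = ps_plausible.copy()
        bump = min(0.02, 1.0 - getattr(ps.utilities, fld))
        setattr(ps.utilities, fld, getattr(ps.utilities, fld) + bump)
        assert run_strategy(strategies[1], ps).total_qaly >= base - 1e-12


def test_discounting_monotone_in_rate(ps_plausible, strategies):
    prev_cost, prev_qaly = np.inf, np.inf
    for r in (0.0, 0.03, 0.06):
        ps = ps_plausible.copy()
        ps.settings.discount_rate_annual = r
        res = run_strategy(strategies[1], ps)
        assert res.total_cost_thb <= prev_cost + 1e-9
        assert res.total_qaly <= prev_qaly + 1e-9
        prev_cost, prev_qaly = res.total_cost_thb, res.total_qaly


def test_trace_export_shape(ps_plausible, strategies):
    trace = run_cohort(strategies[1], ps_plausible)
    df = trace.to_frame()
    assert len(df) == trace.n_cycles
    assert df.columns[0] == "cycle"
    for col in ("event_relapse", "cost_drug_line1", "cycle_cost", "cycle_qaly",
                "cycle_ly"):
        assert col in df.columns
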