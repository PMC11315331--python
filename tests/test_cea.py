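"""Decision analysis: incremental tables, dominance, DSA, PSA, CEAC, scenarios."""

import numpy as np
import pytest

from psorcea.cea import (
    apply_scenario, ceac, fully_incremental, incremental_vs_reference,
    one_way_ranges, run_psa, run_scenarios, tornado,
)
from psorcea.model_core import StrategyResult, run_strategy
from psorcea.parameters import DistributionSpec, default_strategies

from conftest import toy_ps


def _res(name, cost, qaly):
    return StrategyResult(strategy_name=name, total_cost_thb=cost, total_ly=0.0,
                          total_qaly=qaly)


# --- incremental vs reference ----------------------------------------------

def test_identical_strategy_has_zero_deltas():
    rows = incremental_vs_reference([_res("A", 100.0, 1.0), _res("B", 100.0, 1.0)],
                                    "A")
    b = rows[1]
    assert (b.delta_cost_thb, b.delta_qaly) == (0.0, 0.0)
    assert b.status == "reference-equivalent"
    assert b.icer_thb_per_qaly is None


def test_cheaper_and_better_is_dominant_with_negative_ratio():
    rows = incremental_vs_reference([_res("ref", 100.0, 1.0),
                                     _res("new", 90.0, 1.1)], "ref")
    new = rows[1]
    assert new.status == "dominant"
    assert new.icer_thb_per_qaly == pytest.approx(-10.0 / 0.1)


def test_zero_qaly_delta_gives_undefined_icer_not_infinity():
    rows = incremental_vs_reference([_res("ref", 100.0, 1.0),
                                     _res("x", 150.0, 1.0)], "ref")
    assert rows[1].icer_thb_per_qaly is None


def test_missing_reference_raises():
    with pytest.raises(KeyError):
        incremental_vs_reference([_res("A", 1.0, 1.0)], "Z")


# --- fully incremental ------------------------------------------------------

def test_single_strategy_is_its_own_frontier():
    rows = fully_incremental([_res("only", 10.0, 1.0)])
    assert rows[0].status == "reference"
    assert rows[0].icer_thb_per_qaly is None


def test_hand_built_frontier_and_extended_dominance():
    base = [_res("zero", 0.0, 0.0), _res("mid", 10.0, 1.0),
            _res("top", 100.0, 1.01)]
    rows = {r.strategy: r for r in fully_incremental(base)}
    assert rows["mid"].status == "on_frontier"
    assert rows["mid"].icer_thb_per_qaly == pytest.approx(10.0)
    assert rows["top"].icer_thb_per_qaly == pytest.approx(9000.0)
    # a point above the zero->mid segment's extension is extended-dominated
    rows2 = {r.strategy: r
             for r in fully_incremental(base + [_res("weak", 5.0, 0.1)])}
    assert rows2["weak"].status == "extended_dominated"
    assert rows2["mid"].icer_thb_per_qaly == pytest.approx(10.0)


def test_strict_dominance_flagged():
    rows = {r.strategy: r for r in fully_incremental(
        [_res("cheap", 10.0, 2.0), _res("bad", 20.0, 1.0)])}
    assert rows["bad"].status == "dominated"


def test_frontier_icers_strictly_increase(ps_plausible, strategies):
    results = [run_strategy(s, ps_plausible) for s in strategies]
    icers = [r.icer_thb_per_qaly for r in fully_incremental(results)
             if r.status == "on_frontier"]
    assert all(a < b for a, b in zip(icers, icers[1:]))


def test_removing_dominated_strategy_preserves_frontier():
    base = [_res("a", 0.0, 0.0), _res("b", 10.0, 1.0), _res("bad", 12.0, 0.5),
            _res("c", 30.0, 2.0)]
    with_bad = fully_incremental(base)
    without = fully_incremental([r for r in base if r.strategy_name != "bad"])
    keep = [(r.strategy, r.status, r.icer_thb_per_qaly)
            for r in with_bad if r.strategy != "bad"]
    assert keep == [(r.strategy, r.status, r.icer_thb_per_qaly) for r in without]


# --- one-way ranges / tornado ----------------------------------------------

def test_one_way_ranges_pm20_and_clamping_and_ci():
    ps = toy_ps()
    ps.utilities.u_baseline = 0.5
    ps.utilities.u_pasi75 = 0.95
    ps.psa_specs = [
        DistributionSpec("utilities.u_baseline", "beta"),
        DistributionSpec("utilities.u_pasi75", "beta"),
        DistributionSpec("soc.response_prob_soc", "beta",
                         {"ci": [0.3, 0.7]}),
    ]
    ranges = dict((p, (lo, hi)) for p, lo, hi in one_way_ranges(ps))
    assert ranges["utilities.u_baseline"] == (pytest.approx(0.4), pytest.approx(0.6))
    assert ranges["utilities.u_pasi75"] == (pytest.approx(0.76), pytest.approx(1.0))
    assert ranges["soc.response_prob_soc"] == (0.3, 0.7)


def test_tornado_ranks_influential_utility_first(ps_plausible):
    ps = ps_plausible.copy()
    # responder utility moves the ICER; the uniform visit cost cancels in the
    # cost difference (equal life-years), so its span is ~0
    ps.psa_specs = [
        DistributionSpec("costs.visit_cost_direct_medical", "gamma"),
        DistributionSpec("utilities.u_pasi75", "beta"),
    ]
    strats = default_strategies(ps)
    entries = tornado((strats[1], strats[0]), ps)
    assert entries[0].parameter == "utilities.u_pasi75"
    assert entries[0].span > 0
    assert entries[-1].parameter == "costs.visit_cost_direct_medical"
    assert entries[-1].span == pytest.approx(0.0, abs=1e-6 * entries[0].base_icer)


# --- PSA / CEAC -------------------------------------------------------------

def _short_horizon(ps):
    out = ps.copy()
    out.settings.horizon_age = 50
    return out


def test_point_mass_psa_reproduces_base_case(ps_plausible):
    ps = _short_horizon(ps_plausible)
    for spec in ps.psa_specs:
        spec.family = "point"
    strats = default_strategies(ps)
    samples = run_psa(strats, ps, n=3, seed=11)
    base_cost = [run_strategy(s, ps).total_cost_thb for s in strats]
    base_qaly = [run_strategy(s, ps).total_qaly for s in strats]
    assert np.allclose(samples.costs, np.array(base_cost)[None, :])
    assert np.allclose(samples.qalys, np.array(base_qaly)[None, :])
    summ = samples.summary("SoC")
    cri = summ["strategies"]["Sequence1"]["icer_cri_95"]
    assert cri[0] == pytest.approx(cri[1])             # zero-width interval


def test_same_seed_reproduces_sample_set(ps_plausible):
    ps = _short_horizon(ps_plausible)
    strats = default_strategies(ps)
    a = run_psa(strats, ps, n=8, seed=42)
    b = run_psa(strats, ps, n=8, seed=42)
    assert np.array_equal(a.costs, b.costs)
    assert np.array_equal(a.qalys, b.qalys)
    assert a.draws.equals(b.draws)
    c = run_psa(strats, ps, n=8, seed=43)
    assert not np.array_equal(a.costs, c.costs)


def test_beta_spec_moments(ps_plausible):
    # a beta(2,2) spec on one response probability: sample mean near 0.5
    ps = _short_horizon(ps_plausible)
    ps.psa_specs = [DistributionSpec("drugs.secukinumab.response_prob.PASI75",
                                     "beta", {"alpha": 2.0, "beta": 2.0})]
    strats = [default_strategies(ps)[0]]               # SoC only: cheap runs
    samples = run_psa(strats, ps, n=2000, seed=3)
    draws = samples.draws.iloc[:, 0].to_numpy()
    se = np.sqrt(0.05 / 2000)                          # var of beta(2,2) = 1/20
    assert abs(draws.mean() - 0.5) < 3 * se
    assert draws.min() >= 0.0 and draws.max() <= 1.0


def test_invalid_distribution_rejected_before_sampling(ps_plausible):
    ps = _short_horizon(ps_plausible)
    ps.psa_specs = [DistributionSpec("utilities.u_pasi75", "beta",
                                     {"alpha": -1.0, "beta": 2.0})]
    with pytest.raises(ValueError):
        run_psa(default_strategies(ps), ps, n=2, seed=0)


def test_ceac_limits_and_normalisation(ps_plausible):
    ps = _short_horizon(ps_plausible)
    strats = default_strategies(ps)
    samples = run_psa(strats, ps, n=25, seed=9)
    grid = np.array([0.0, 1e5, 1e6, 1e12])
    curve = ceac(samples, grid)
    probs = curve.probabilities.to_numpy()
    assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-9
    assert probs.min() >= 0.0 and probs.max() <= 1.0
    # lambda = 0: NMB = -cost, winner is the per-iteration cheapest
    cheapest = samples.costs.argmin(axis=1)
    expect0 = np.bincount(cheapest, minlength=4) / samples.n
    assert np.allclose(probs[0], expect0)
    # lambda huge: winner is the per-iteration highest-QALY strategy
    best_q = samples.qalys.argmax(axis=1)
    expect_inf = np.bincount(best_q, minlength=4) / samples.n
    assert np.allclose(probs[-1], expect_inf)


def test_degenerate_psa_gives_step_function_ceac(ps_plausible):
    ps = _short_horizon(ps_plausible)
    for spec in ps.psa_specs:
        spec.family = "point"
    strats = default_strategies(ps)
    samples = run_psa(strats, ps, n=2, seed=1)
    curve = ceac(samples, np.linspace(0.0, 2e6, 11))
    assert set(np.unique(curve.probabilities.to_numpy())) <= {0.0, 1.0}


# --- scenarios --------------------------------------------------------------

def test_scenario_zero_is_base_case(ps_plausible):
    ps2 = apply_scenario(ps_plausible, 0)
    assert ps2.to_dict() == ps_plausible.to_dict()


def test_unknown_scenario_rejected(ps_plausible):
    with pytest.raises(KeyError):
        apply_scenario(ps_plausible, 99)


def test_mix_scenarios_change_costs_only(ps_plausible, strategies):
    base = {s.name: run_strategy(s, ps_plausible) for s in strategies}
    for sid in (4, 5, 6, 7):
        ps_s = apply_scenario(ps_plausible, sid)
        assert ps_s.soc.mix_mtx_fraction == {4: 0.8, 5: 0.7, 6: 1.0, 7: 0.0}[sid]
        for s in strategies:
            res = run_strategy(s, ps_s)
            assert res.total_qaly == pytest.approx(base[s.name].total_qaly,
                                                   abs=1e-9)
            assert res.total_ly == pytest.approx(base[s.name].total_ly, abs=1e-9)


def test_ciclosporin_only_scenario_raises_soc_cost_when_csa_pricier(ps_plausible,
                                                                    strategies):
    base = run_strategy(strategies[0], ps_plausible).total_cost_thb
    ps7 = apply_scenario(ps_plausible, 7)
    # synthetic CsA daily cost far exceeds MTX weekly cost
    assert run_strategy(strategies[0], ps7).total_cost_thb > base


def test_response_definition_scenarios_switch_level(ps_plausible):
    assert apply_scenario(ps_plausible, 2).settings.response_definition == "PASI90"
    assert apply_scenario(ps_plausible, 3).settings.response_definition == "PASI100"


def test_scenario_table_shape(ps_plausible, strategies):
    ps = ps_plausible.copy()
    ps.settings.horizon_age = 50                     # keep the sweep fast
    df = run_scenarios(ps, default_strategies(ps), scenario_ids=(0, 1, 8))
    assert len(df) == 3 * 4
    assert set(df.scenario) == {0, 1, 8}
    soc_rows = df[df.strategy == "SoC"]
    assert soc_rows.icer_thb_per_qaly.isna().all()
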