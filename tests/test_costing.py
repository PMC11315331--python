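"""Dose-schedule enumeration, lab/visit/SoC costing, currency conversion."""

import numpy as np
import pytest

from psorcea.costing import (
    doses_in_window, drug_cost_in_window, drug_cost_per_cycle,
    line_drug_cost_array, monitoring_cost_per_year, screening_cost,
    soc_drug_cost_per_cycle, thb_to_usd,
)
from psorcea.model_core import run_cohort, run_strategy
from psorcea.parameters import EconSettings

from conftest import toy_ps


# --- dose schedules ---------------------------------------------------------

def test_secukinumab_schedule_first_25_weeks():
    ps = toy_ps()
    # weeks 0,1,2,3,4 loading then q4w resuming at week 8: 8,12,16,20,24
    assert doses_in_window(ps.drugs["secukinumab"], 0, 25) == (10, 3000.0)


def test_ixekizumab_schedule_first_25_weeks():
    ps = toy_ps()
    # 160 mg wk 0; 80 mg wks 2..12 q2w; then q4w at 16,20,24 -> 880 mg
    assert doses_in_window(ps.drugs["ixekizumab"], 0, 25) == (10, 880.0)


def test_guselkumab_q8w_no_loading():
    ps = toy_ps()
    assert doses_in_window(ps.drugs["guselkumab"], 0, 25) == (4, 400.0)


def test_empty_window_has_no_doses():
    ps = toy_ps()
    assert doses_in_window(ps.drugs["secukinumab"], 5, 5) == (0, 0.0)


def test_maintenance_q4w_mean_cycle_cost_is_half_unit_price():
    ps = toy_ps()
    ixe = ps.drugs["ixekizumab"]          # 80 mg dose, 80 mg/unit, q4w
    assert drug_cost_per_cycle(ixe, "maintenance", ps) == pytest.approx(
        ixe.price_per_unit / 2.0)
    # exact grid alternates one unit / zero units per 2-week cycle
    arr = line_drug_cost_array(ixe, 26, ps.settings)
    maint = arr[8:]                       # past week 16 the q4w grid is regular
    assert set(np.round(maint, 6)) == {0.0, ixe.price_per_unit}


def test_zero_price_zero_cost():
    ps = toy_ps()
    ps.drugs["secukinumab"].price_per_unit = 0.0
    assert drug_cost_in_window(ps.drugs["secukinumab"], 0, 100) == 0.0


def test_ceil_to_unit_no_vial_sharing():
    ps = toy_ps()
    seku = ps.drugs["secukinumab"]        # 300 mg dose, 150 mg/unit -> 2 units
    assert drug_cost_in_window(seku, 0, 1) == pytest.approx(
        2 * seku.price_per_unit)


# --- labs / visits / SoC ----------------------------------------------------

def test_screening_panel_is_eleven_tests():
    ps = toy_ps()
    ps.costs.lab_costs = {t: 100.0 for t in ps.costs.lab_costs}
    assert screening_cost(ps) == pytest.approx(1100.0)


def test_screening_zero_costs():
    assert screening_cost(toy_ps()) == 0.0


def test_monitoring_biologic_maintenance_schedule():
    ps = toy_ps()
    ps.costs.lab_costs = {t: 1.0 for t in ps.costs.lab_costs}
    assert monitoring_cost_per_year("MAINT", ps) == pytest.approx(7.0)


def test_monitoring_soc_schedule_with_mix():
    ps = toy_ps()
    ps.costs.lab_costs = {t: 1.0 for t in ps.costs.lab_costs}
    ps.soc.soc_lab_frequency_per_year = 4.0
    ps.soc.mix_mtx_fraction = 0.85
    # 4x5 basic panel + 4 lipid + 0.15 * 4 * (uric + mg)
    assert monitoring_cost_per_year("SOC", ps) == pytest.approx(25.2)


def test_monitoring_zero_costs():
    assert monitoring_cost_per_year("SOC", toy_ps()) == 0.0


def test_soc_drug_cost_blend():
    ps = toy_ps()
    ps.soc.mtx_price_tablet = 1.0
    ps.soc.csa_price = 1.0
    ps.soc.mix_mtx_fraction = 0.85
    # 14-day cycle: MTX 50 mg, CsA 4200 mg
    assert soc_drug_cost_per_cycle(ps.soc, ps.settings) == pytest.approx(672.5)
    ps.soc.mix_mtx_fraction = 1.0
    assert soc_drug_cost_per_cycle(ps.soc, ps.settings) == pytest.approx(50.0)
    ps.soc.mix_mtx_fraction = 0.0
    assert soc_drug_cost_per_cycle(ps.soc, ps.settings) == pytest.approx(4200.0)


def test_mtx_injection_variant_uses_injection_price():
    ps = toy_ps()
    ps.soc.mtx_price_tablet = 1.0
    ps.soc.mtx_price_injection = 3.0
    ps.soc.mix_mtx_fraction = 1.0
    tablet = soc_drug_cost_per_cycle(ps.soc, ps.settings, variant="tablet")
    inj = soc_drug_cost_per_cycle(ps.soc, ps.settings, variant="injection")
    assert inj == pytest.approx(3.0 * tablet)


@pytest.mark.parametrize("thb, usd", [
    (621_373, 19_449),     # Sequence 1 ICER
    (1_332_262, 41_700),   # Sequence 3 ICER
    (1_863_287, 58_321),   # Sequence 1 incremental cost
    (160_000, 5_008),      # WTP threshold
    (0, 0),
])
def test_thb_to_usd_2021_rate(thb, usd):
    assert round(thb_to_usd(thb)) == usd


# --- whole-strategy cost properties ----------------------------------------

def test_category_breakdown_sums_to_total(ps_plausible, strategies):
    for strat in strategies:
        res = run_strategy(strat, ps_plausible)
        assert sum(res.cost_breakdown.values()) == pytest.approx(
            res.total_cost_thb, abs=1e-6)
        trace = run_cohort(strat, ps_plausible)
        assert np.allclose(sum(trace.cost_by_category.values()), trace.cycle_cost)


def test_total_cost_monotone_in_unit_price(ps_plausible, strategies):
    base = run_strategy(strategies[1], ps_plausible).total_cost_thb
    ps = ps_plausible.copy()
    ps.drugs["secukinumab"].price_per_unit *= 1.5
    assert run_strategy(strategies[1], ps).total_cost_thb > base


def test_annualized_drug_cost_stable_under_grid_refinement():
    # halving the cycle length must not shift annual drug cost by more than
    # one dose's price (doses near the year boundary may change bins)
    ps = toy_ps()
    drug = ps.drugs["secukinumab"]
    for days, cpy in ((14.0, 26), (7.0, 52)):
        s = EconSettings(cycle_length_days=days)
        assert s.cycles_per_year == cpy
    coarse = line_drug_cost_array(drug, 26, EconSettings(cycle_length_days=14.0))
    fine = line_drug_cost_array(drug, 52, EconSettings(cycle_length_days=7.0))
    dose_price = 2 * drug.price_per_unit
    assert abs(coarse.sum() - fine.sum()) <= dose_price
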