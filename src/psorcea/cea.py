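"""Decision analysis: ICERs, dominance frontier, DSA, PSA/CEAC, scenarios.

ICER convention: incremental cost divided by incremental QALYs against a
reference strategy (or the adjacent cheaper strategy on the efficiency
frontier).  An ICER is undefined when the QALY difference is zero; a strategy
that is cheaper *and* more effective than the reference is flagged dominant
(its negative ratio is reported but should not be ranked).  Reported tables
round THB/USD to integers and QALYs to three decimals; internal arithmetic is
never rounded.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import thb_to_usd
from .model_core import StrategyResult, run_strategy
from .parameters import (
    DistributionSpec, ParameterSet, Strategy, get_param, set_param,
)

__all__ = [
    "IncrementalRow",
    "PSASampleSet",
    "CEACCurve",
    "TornadoEntry",
    "incremental_vs_reference",
    "fully_incremental",
    "one_way_ranges",
    "tornado",
    "run_psa",
    "ceac",
    "default_wtp_grid",
    "SCENARIO_IDS",
    "apply_scenario",
    "run_scenarios",
    "rows_to_frame",
]


@dataclass
class IncrementalRow:
    strategy: str
    cost_thb: float
    qaly: float
    delta_cost_thb: float | None = None
    delta_cost_usd: float | None = None
    delta_qaly: float | None = None
    icer_thb_per_qaly: float | None = None
    icer_usd_per_qaly: float | None = None
    status: str = "compared"


def _icer(delta_cost: float, delta_qaly: float) -> float | None:
    return None if delta_qaly == 0.0 else delta_cost / delta_qaly


def incremental_vs_reference(results: list[StrategyResult],
                             reference: str) -> list[IncrementalRow]:
    """Pairwise incremental columns of every strategy against one reference."""
    by_name = {r.strategy_name: r for r in results}
    if reference not in by_name:
        raise KeyError(f"reference strategy {reference!r} not among results")
    ref = by_name[reference]
    rows = []
    for res in results:
        if res.strategy_name == reference:
            rows.append(IncrementalRow(res.strategy_name, res.total_cost_thb,
                                       res.total_qaly, status="reference"))
            continue
        dc = res.total_cost_thb - ref.total_cost_thb
        dq = res.total_qaly - ref.total_qaly
        icer = _icer(dc, dq)
        if dc == 0.0 and dq == 0.0:
            status = "reference-equivalent"
        elif dc < 0.0 and dq > 0.0:
            status = "dominant"
        elif dc > 0.0 and dq < 0.0:
            status = "dominated"
        else:
            status = "compared"
        rows.append(IncrementalRow(
            res.strategy_name, res.total_cost_thb, res.total_qaly,
            delta_cost_thb=dc, delta_cost_usd=thb_to_usd(dc), delta_qaly=dq,
            icer_thb_per_qaly=icer,
            icer_usd_per_qaly=None if icer is None else thb_to_usd(icer),
            status=status))
    return rows


def fully_incremental(results: list[StrategyResult]) -> list[IncrementalRow]:
    """Efficiency-frontier analysis with strict and extended dominance.

    Strategies are ordered by ascending cost (ties broken by higher QALY).
    A strategy is strictly dominated if some other strategy costs no more and
    yields no fewer QALYs (one strictly).  Extended dominance then removes
    any strategy whose ICER against the previous frontier point exceeds the
    next frontier ICER; frontier ICERs are computed between adjacent
    non-dominated strategies and are strictly increasing by construction.
    """
    if len(results) < 1:
        raise ValueError("need at least one strategy")
    ordered = sorted(results, key=lambda r: (r.total_cost_thb, -r.total_qaly))
    status = {r.strategy_name: "on_frontier" for r in ordered}
    for r in ordered:
        for other in ordered:
            if other is r:
                continue
            if (other.total_cost_thb <= r.total_cost_thb
                    and other.total_qaly >= r.total_qaly
                    and (other.total_cost_thb < r.total_cost_thb
                         or other.total_qaly > r.total_qaly)):
                status[r.strategy_name] = "dominated"
                break

    frontier = [r for r in ordered if status[r.strategy_name] == "on_frontier"]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_mid = _icer(mid.total_cost_thb - lo.total_cost_thb,
                             mid.total_qaly - lo.total_qaly)
            icer_hi = _icer(hi.total_cost_thb - mid.total_cost_thb,
                            hi.total_qaly - mid.total_qaly)
            if icer_mid is None or (icer_hi is not None and icer_mid > icer_hi):
                status[mid.strategy_name] = "extended_dominated"
                frontier.pop(i)
                changed = True
                break

    rows = []
    prev: StrategyResult | None = None
    for r in ordered:
        st = status[r.strategy_name]
        if st != "on_frontier":
            rows.append(IncrementalRow(r.strategy_name, r.total_cost_thb,
                                       r.total_qaly, status=st))
            continue
        if prev is None:
            rows.append(IncrementalRow(r.strategy_name, r.total_cost_thb,
                                       r.total_qaly, status="reference"))
        else:
            dc = r.total_cost_thb - prev.total_cost_thb
            dq = r.total_qaly - prev.total_qaly
            icer = _icer(dc, dq)
            rows.append(IncrementalRow(
                r.strategy_name, r.total_cost_thb, r.total_qaly,
                delta_cost_thb=dc, delta_cost_usd=thb_to_usd(dc), delta_qaly=dq,
                icer_thb_per_qaly=icer,
                icer_usd_per_qaly=None if icer is None else thb_to_usd(icer),
                status="on_frontier"))
        prev = r
    return rows


def rows_to_frame(rows: list[IncrementalRow], report: bool = False) -> pd.DataFrame:
    """Tabulate incremental rows; ``report=True`` mirrors published rounding
    (integer THB/USD, 3-decimal QALYs)."""
    df = pd.DataFrame([vars(r) for r in rows])
    if report:
        for col in ("cost_thb", "delta_cost_thb", "delta_cost_usd",
                    "icer_thb_per_qaly", "icer_usd_per_qaly"):
            df[col] = df[col].round(0)
        for col in ("qaly", "delta_qaly"):
            df[col] = df[col].round(3)
    return df


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------

def one_way_ranges(ps: ParameterSet) -> list[tuple[str, float, float]]:
    """Low/high bound per uncertain parameter: the 95% CI when supplied,
    otherwise ±20% of the base value; probabilities/utilities clamped to [0,1]."""
    out = []
    for spec in ps.psa_specs:
        base = float(get_param(ps, spec.path))
        ci = spec.params.get("ci")
        if ci is not None:
            lo, hi = float(ci[0]), float(ci[1])
        else:
            lo, hi = base * 0.8, base * 1.2
        if spec.family == "beta":
            lo, hi = max(0.0, lo), min(1.0, hi)
        out.append((spec.path, lo, hi))
    return out


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    span: float
    base_icer: float | None = None


def _pair_icer(intervention: Strategy, reference: Strategy,
               ps: ParameterSet) -> float | None:
    ri = run_strategy(intervention, ps)
    rr = run_strategy(reference, ps)
    return _icer(ri.total_cost_thb - rr.total_cost_thb,
                 ri.total_qaly - rr.total_qaly)


def tornado(strategy_pair: tuple[Strategy, Strategy],
            ps: ParameterSet) -> list[TornadoEntry]:
    """One-way sensitivity of the pair's ICER, sorted by descending span.

    ``strategy_pair`` is (intervention, reference).  An undefined ICER at a
    bound (zero QALY difference) leaves that endpoint as None and its side of
    the span at zero.
    """
    intervention, reference = strategy_pair
    base_icer = _pair_icer(intervention, reference, ps)
    entries = []
    for path, lo, hi in one_way_ranges(ps):
        icers = []
        for bound in (lo, hi):
            ps_b = ps.copy()
            set_param(ps_b, path, bound)
            icers.append(_pair_icer(intervention, reference, ps_b))
        icer_lo, icer_hi = icers
        finite = [x for x in icers if x is not None]
        if len(finite) == 2:
            span = abs(finite[1] - finite[0])
        elif len(finite) == 1 and base_icer is not None:
            span = abs(finite[0] - base_icer)
        else:
            span = 0.0
        entries.append(TornadoEntry(path, lo, hi, icer_lo, icer_hi, span, base_icer))
    entries.sort(key=lambda e: -e.span)
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSASampleSet:
    """Joint Monte-Carlo parameter draws with per-iteration strategy outcomes."""

    n: int
    seed: int
    strategy_names: list[str]
    costs: np.ndarray                 # (n, n_strategies)
    qalys: np.ndarray                 # (n, n_strategies)
    draws: pd.DataFrame               # (n, n_parameters)
    n_undefined_icers: dict[str, int] = field(default_factory=dict)

    def summary(self, reference: str) -> dict:
        """Mean outcomes, 95% ICER credible intervals vs the reference, and
        CE-plane quadrant fractions (NE/SE/SW/NW) per strategy."""
        ref = self.strategy_names.index(reference)
        out: dict = {"n": self.n, "seed": self.seed, "strategies": {}}
        for j, name in enumerate(self.strategy_names):
            entry = {"mean_cost_thb": float(self.costs[:, j].mean()),
                     "mean_qaly": float(self.qalys[:, j].mean())}
            if j != ref:
                dc = self.costs[:, j] - self.costs[:, ref]
                dq = self.qalys[:, j] - self.qalys[:, ref]
                defined = dq != 0.0
                self.n_undefined_icers[name] = int((~defined).sum())
                icers = dc[defined] / dq[defined]
                if icers.size:
                    entry["icer_cri_95"] = [float(np.percentile(icers, 2.5)),
                                            float(np.percentile(icers, 97.5))]
                entry["quadrants"] = {
                    "NE": float(((dc > 0) & (dq > 0)).mean()),
                    "SE": float(((dc <= 0) & (dq > 0)).mean()),
                    "SW": float(((dc <= 0) & (dq <= 0)).mean()),
                    "NW": float(((dc > 0) & (dq <= 0)).mean()),
                }
            out["strategies"][name] = entry
        return out

    def ce_plane_frame(self, reference: str) -> pd.DataFrame:
        ref = self.strategy_names.index(reference)
        recs = []
        for j, name in enumerate(self.strategy_names):
            if j == ref:
                continue
            for i in range(self.n):
                recs.append({"iteration": i, "strategy": name,
                             "delta_cost_thb": self.costs[i, j] - self.costs[i, ref],
                             "delta_qaly": self.qalys[i, j] - self.qalys[i, ref]})
        return pd.DataFrame(recs)


def _make_sampler(spec: DistributionSpec, base: float):
    """Return rng -> draw for one parameter; method-of-moments when only a
    base value (and optional SE, default 20% of the mean) is given."""
    p = spec.params
    fam = spec.family
    if fam == "point":
        return lambda rng: base
    se = float(p.get("se", 0.2 * abs(base)) or 0.2 * abs(base))
    if fam == "beta":
        if "alpha" in p and "beta" in p:
            a, b = float(p["alpha"]), float(p["beta"])
        else:
            m = min(max(base, 1e-9), 1.0 - 1e-9)
            var = min(se * se, 0.95 * m * (1.0 - m))  # MoM validity guard
            nu = m * (1.0 - m) / var - 1.0
            a, b = m * nu, (1.0 - m) * nu
        if a <= 0 or b <= 0:
            raise ValueError(f"invalid beta parameters for {spec.path}: "
                             f"alpha={a}, beta={b}")
        return lambda rng: float(rng.beta(a, b))
    if fam == "gamma":
        if "shape" in p and "scale" in p:
            k, th = float(p["shape"]), float(p["scale"])
        else:
            if base <= 0:
                return lambda rng: base  # degenerate zero-cost parameter
            k, th = (base / se) ** 2, se * se / base
        if k <= 0 or th <= 0:
            raise ValueError(f"invalid gamma parameters for {spec.path}")
        return lambda rng: float(rng.gamma(k, th))
    if fam == "lognormal":
        if "mu" in p and "sigma" in p:
            mu, sg = float(p["mu"]), float(p["sigma"])
        else:
            if base <= 0:
                raise ValueError(f"lognormal requires a positive base for {spec.path}")
            sg2 = math.log(1.0 + (se / base) ** 2)
            mu, sg = math.log(base) - sg2 / 2.0, math.sqrt(sg2)
        if sg < 0:
            raise ValueError(f"invalid lognormal sigma for {spec.path}")
        return lambda rng: float(rng.lognormal(mu, sg))
    raise ValueError(f"unknown distribution family {fam!r} for {spec.path}")


def run_psa(strategies: list[Strategy], ps: ParameterSet, n: int,
            seed: int) -> PSASampleSet:
    """Joint Monte-Carlo over all DistributionSpecs; draws are shared across
    strategies within an iteration and fully determined by ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    samplers = [(spec.path, _make_sampler(spec, float(get_param(ps, spec.path))))
                for spec in ps.psa_specs]
    rng = np.random.default_rng(seed)
    costs = np.zeros((n, len(strategies)))
    qalys = np.zeros((n, len(strategies)))
    draw_rows = np.zeros((n, len(samplers)))
    for i in range(n):
        ps_i = ps.copy()
        for k, (path, sampler) in enumerate(samplers):
            v = sampler(rng)
            draw_rows[i, k] = v
            set_param(ps_i, path, v)
        for j, strat in enumerate(strategies):
            res = run_strategy(strat, ps_i)
            costs[i, j] = res.total_cost_thb
            qalys[i, j] = res.total_qaly
    draws = pd.DataFrame(draw_rows, columns=[p for p, _ in samplers])
    return PSASampleSet(n=n, seed=seed,
                        strategy_names=[s.name for s in strategies],
                        costs=costs, qalys=qalys, draws=draws)


@dataclass
class CEACCurve:
    """Probability each strategy is cost-effective across a WTP grid."""

    wtp_grid: np.ndarray
    probabilities: pd.DataFrame   # index = WTP, columns = strategies

    def to_frame(self) -> pd.DataFrame:
        df = self.probabilities.copy()
        df.insert(0, "wtp_thb_per_qaly", self.wtp_grid)
        return df.reset_index(drop=True)


def default_wtp_grid() -> np.ndarray:
    return np.arange(0.0, 1_600_001.0, 20_000.0)


def ceac(samples: PSASampleSet, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """At each WTP, the fraction of iterations in which each strategy has the
    maximal net monetary benefit (ties split equally across the tied set)."""
    if samples.n < 1:
        raise ValueError("empty PSA sample set")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    k = len(samples.strategy_names)
    probs = np.zeros((len(grid), k))
    for gi, lam in enumerate(grid):
        nmb = lam * samples.qalys - samples.costs        # (n, k)
        best = nmb.max(axis=1, keepdims=True)
        winners = (nmb == best)
        probs[gi] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CEACCurve(wtp_grid=grid,
                     probabilities=pd.DataFrame(probs,
                                                columns=samples.strategy_names))


# ---------------------------------------------------------------------------
# scenario analyses
# ---------------------------------------------------------------------------

SCENARIO_IDS = tuple(range(0, 9))  # 0 = base case

_SCENARIO_LABELS = {
    0: "base case",
    1: "alternative health-utility source",
    2: "treatment response defined as PASI90",
    3: "treatment response defined as PASI100",
    4: "MTX:ciclosporin mix 80:20",
    5: "MTX:ciclosporin mix 70:30",
    6: "MTX only (100:0)",
    7: "ciclosporin only (0:100)",
    8: "MTX injection instead of tablet",
}


def apply_scenario(ps: ParameterSet, scenario_id: int) -> ParameterSet:
    """Return a modified copy of the parameter set for one scenario."""
    if scenario_id not in SCENARIO_IDS:
        raise KeyError(f"unknown scenario id {scenario_id}")
    out = ps.copy()
    if scenario_id == 0:
        return out
    if scenario_id == 1:
        if ps.alt_utilities is None:
            raise ValueError("scenario 1 requires alt_utilities in the config")
        out.utilities = copy.deepcopy(ps.alt_utilities)
    elif scenario_id == 2:
        out.settings.response_definition = "PASI90"
    elif scenario_id == 3:
        out.settings.response_definition = "PASI100"
    elif scenario_id in (4, 5, 6, 7):
        out.soc.mix_mtx_fraction = {4: 0.80, 5: 0.70, 6: 1.00, 7: 0.00}[scenario_id]
    elif scenario_id == 8:
        out.soc.mtx_variant = "injection"
    return out


def run_scenarios(ps: ParameterSet, strategies: list[Strategy],
                  reference: str = "SoC",
                  scenario_ids: tuple[int, ...] = SCENARIO_IDS) -> pd.DataFrame:
    """Scenario table: per scenario and strategy, cost, QALY and ICER vs SoC."""
    recs = []
    for sid in scenario_ids:
        ps_s = apply_scenario(ps, sid)
        results = [run_strategy(s, ps_s) for s in strategies]
        for row in incremental_vs_reference(results, reference):
            recs.append({
                "scenario": sid,
                "label": _SCENARIO_LABELS[sid],
                "strategy": row.strategy,
                "cost_thb": row.cost_thb,
                "qaly": row.qaly,
                "icer_thb_per_qaly": row.icer_thb_per_qaly,
                "icer_usd_per_qaly": row.icer_usd_per_qaly,
            })
    return pd.DataFrame(recs)
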