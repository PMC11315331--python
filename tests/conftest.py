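"""Shared fixtures and small-instance builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from psorcea.parameters import ParameterSet, Strategy, TreatmentLine, default_strategies
from psorcea.synthetic import SyntheticSpec, generate_parameter_set


@pytest.fixture(scope="session")
def ps_plausible() -> ParameterSet:
    """One realistic synthetic parameter set shared across tests (read-only:
    tests that mutate must work on ``ps_plausible.copy()``)."""
    return generate_parameter_set(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def strategies(ps_plausible):
    return default_strategies(ps_plausible)


def toy_ps() -> ParameterSet:
    """A fresh hand-checkable parameter set (zero mortality, flat prices)."""
    return generate_parameter_set(SyntheticSpec(seed=0, level="toy"))


def random_small_instance(seed: int):
    """A randomized annual-cycle instance small enough for path enumeration.

    Returns (strategy, parameter_set, n_cycles) with n_cycles <= 12, random
    response/drop-out/relapse probabilities, random assessment and stop
    timing, constant mortality, and a random 0-3 line sequence.
    """
    rng = np.random.default_rng(seed)
    ps = toy_ps()
    ps.settings.cycle_length_days = 364.0      # 1 cycle per model year
    ps.settings.start_age = 40
    n_cycles = int(rng.integers(4, 13))
    ps.settings.horizon_age = 40 + n_cycles
    ps.settings.assessment_months = float(rng.integers(1, 4)) * 12.0
    ps.settings.stop_years = float(rng.integers(1, 6))
    ps.settings.stop_clock = str(rng.choice(["per_line", "model_start"]))
    for drug in ps.drugs.values():
        p = float(rng.choice([0.0, 0.25, 0.5, 0.75, 1.0]))
        drug.response_prob = {"PASI75": p, "PASI90": p, "PASI100": p}
        drug.annual_dropout_prob = float(rng.uniform(0.0, 0.5))
        drug.annual_relapse_prob = float(rng.uniform(0.0, 0.9))
    q = float(rng.uniform(0.0, 0.3))
    ps.life_table.annual_death_prob = {a: q for a in range(40, 40 + n_cycles + 1)}

    n_lines = int(rng.integers(0, 4))
    names = ["secukinumab", "ixekizumab", "brodalumab", "guselkumab"]
    lines = []
    for li in range(n_lines):
        if li == 1 and rng.random() < 0.5:
            w = float(rng.uniform(0.2, 0.8))
            lines.append(TreatmentLine.of(names[li], names[3], split=[w, 1.0 - w]))
        else:
            lines.append(TreatmentLine.of(names[li]))
    return Strategy(f"rand{seed}", tuple(lines)), ps, n_cycles
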