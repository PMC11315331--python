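# psorcea

Cost-utility and budget-impact modelling of **sequential IL-17 inhibitor
therapy for moderate-to-severe plaque psoriasis**, for health-economics
analysts working in resource-limited settings (costs in Thai baht, Thai
willingness-to-pay threshold).

The package asks: for patients failing conventional systemic therapy, is a
sequence of biologics — a first IL-17 inhibitor, a second IL-17 inhibitor on
failure, then an IL-23 inhibitor rescue — worth its cost compared with
staying on methotrexate/ciclosporin (standard of care, SoC)?

## Model

A hybrid **decision tree + Markov cohort model**.  The decision tree
resolves response per treatment line: each line is assessed at 6 months
(PASI 75 response by default); responders enter maintenance, failures switch
to the next line, and patients failing all three lines fall back to SoC.
The Markov model (14-day cycles, lifetime horizon to age 100) then tracks
maintenance, drop-out to SoC, the planned 3-year treatment stop, relapse
from the off-treatment state, lifelong retreatment, and death (age-specific
mortality × a psoriasis relative risk; identical in every alive state).

The decision metric is the incremental cost-effectiveness ratio

```
ICER = (C_seq − C_SoC) / (E_seq − E_SoC)      [THB per QALY]
```

with both costs `C` and QALYs `E` discounted at 3%/year, judged against a
willingness-to-pay λ = 160,000 THB/QALY, plus a fully incremental analysis
(strict and extended dominance on the efficiency frontier), one-way
sensitivity analysis (±20% or 95% CI), probabilistic sensitivity analysis
(joint beta/gamma/log-normal draws; cost-effectiveness acceptability curves
from net monetary benefit λE − C), eight scenario analyses, and a 5-year
dynamic-cohort budget impact model under a payer perspective.

The study's numeric inputs live in unpublished supplementary tables, so a
**synthetic generator** produces structurally faithful, validated input sets
from a seed; the published base-case totals are available as a fixture for
the decision-analysis layer.  See `docs/methods.md` for assumptions,
conventions and limitations.

## Worked example

Feed the published base-case totals through the incremental analysis:

```python
from psorcea.cea import incremental_vs_reference, fully_incremental, rows_to_frame
from psorcea.synthetic import table1_fixture

print(rows_to_frame(incremental_vs_reference(table1_fixture(), "SoC"), report=True))
print(rows_to_frame(fully_incremental(table1_fixture()), report=True))
```

```
 strategy  cost_thb   qaly  delta_cost_thb  delta_cost_usd  delta_qaly  icer_thb_per_qaly
      SoC  783388.0 13.489             NaN             NaN         NaN                NaN
Sequence1 2646675.0 16.484       1863287.0         58321.0       2.995           622133.0
Sequence2 3808175.0 16.649       3024787.0         94676.0       3.160           957211.0
Sequence3 4552700.0 16.318       3769312.0        117979.0       2.829          1332383.0

 strategy  cost_thb   qaly  icer_thb_per_qaly      status
      SoC  783388.0 13.489                NaN   reference
Sequence1 2646675.0 16.484           622133.0 on_frontier
Sequence2 3808175.0 16.649          7039394.0 on_frontier
Sequence3 4552700.0 16.318                NaN   dominated
```

Reading: every sequence gains ~3 QALYs over SoC but at ~1.9–3.8 million THB
extra cost, so no sequence is cost-effective at 160,000 THB/QALY.
Sequence 1 (secukinumab first) has the lowest ICER; Sequence 3 is strictly
dominated (costlier and less effective than Sequence 2), and the frontier
runs SoC → Sequence 1 → Sequence 2.  Frontier ICERs here are recomputed from
the rounded published totals and therefore differ slightly from ratios
computed on unrounded internals (see the rounding-sensitivity note in
`docs/methods.md`).

End-to-end on synthetic inputs:

```bash
psorcea gen-config --seed 1 --out config.yaml     # or use examples/config_synthetic_seed1.yaml
psorcea run-all --config config.yaml --out results/ --n 1000 --seed 1
```

writes `base_case.csv`, `frontier.csv`, `tornado.csv`, `ce_plane.csv`,
`ceac.csv`, `scenarios.csv`, `budget_impact.csv` and a `manifest.json`
recording the config hash and seeds.

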