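# fracture-cea

Cost-effectiveness modelling of osteoporotic fracture risk assessment for
adults with intellectual disabilities (ID), from a UK NHS perspective.

People with ID fracture more often than the general population, yet their
fracture risk is rarely assessed and the standard risk scores fit them
poorly. This package compares three assessment strategies for adults aged
40 and over:

* **S1 — current practice**: a small, NICE-eligibility-driven fraction of
  the population (base 3%) receives a QFracture risk score; those testing
  positive get a DXA (bone mineral density) scan;
* **S2 — ID-specific risk score**: everyone receives an IDFracture score,
  positives get a DXA;
* **S3 — direct DXA**: everyone gets a DXA scan outright.

DXA is treated as perfectly accurate. Confirmed osteoporosis (T-score
≤ −2.5) is treated with a bisphosphonate plus vitamin D and calcium;
osteopenia (−2.5 < T ≤ −1) with vitamin D and calcium alone; normal BMD is
untreated. The model runs separately for major osteoporotic fracture (MOF)
and hip fracture (HF). It is written for health-economics researchers and
modellers who want a tested, reproducible implementation of this decision
problem.

## Model

A screening decision tree feeds a nine-state Markov cohort model (states:
untreated/treated osteoporosis, untreated/treated osteopenia, normal BMD,
no fracture, fracture year, post fracture, dead). A cohort of N = 1000
enters at age 40 and runs annual cycles to age 100, with no half-cycle
correction. Within a cycle death is resolved first: from an untreated bone
state the transition row is

    P(dead) = m(t),   P(fracture) = (1 − m(t))·p_fx,   P(stay) = remainder,

where m(t) is the Gompertz-type background mortality at age t and
p_fx = 1 − (1 − p10)^(1/10) annualises the 10-year fracture probability of
the person's BMD category. Treated states multiply p_fx by the treatment
relative risk (RR = 0.60 bisphosphonate, 0.90 vitamin D/calcium) and leak
(1 − adherence) of non-fracturing survivors per cycle to the matching
untreated state, permanently. The fracture year is a one-cycle tunnel with
elevated mortality and a year-1 cost; post fracture carries a chronic
annual cost, a re-fracture probability and its own mortality multiplier;
death absorbs. Costs (GBP 2021/22) and utilities (EQ-5D-style, age-specific
baseline with fracture decrements) accrue from start-of-cycle occupancy and
are discounted at r = 3.5%:

    E[cost] = Σ_k (1+r)^(−k) · c_k,   E[QALY] = Σ_k (1+r)^(−k) · u_k.

Strategies are compared by ICER = ΔC/ΔE with cost-effectiveness-plane
dominance labels, and by incremental net monetary benefit
NMB(λ) = λ·ΔE − ΔC at λ = £15 000, £20 000 and £30 000 per QALY.
Deterministic scenarios, a 1000-draw probabilistic sensitivity analysis
(beta for probabilities/utilities, gamma for costs, moment-matched) with
CEAC curves, and sex/age subgroup runs complete the analysis.

The study this model follows does not deposit its parameter tables, so the
package ships a **synthetic** reference parameter set (see
`docs/methods.md`): the pipeline, invariants and arithmetic are faithful,
while the absolute cost/QALY levels characterise the synthetic world.

## Worked example

```python
from fracture_cea import reference_bundle, evaluate_bundle

bundle = reference_bundle("mof")
outcomes, comparisons = evaluate_bundle(bundle, comparator="S1")
for c in comparisons:
    print(f"{c.intervention} vs {c.comparator}: dC {c.delta_cost:+.2f}, "
          f"dE {c.delta_qaly:+.5f}, ICER {c.icer.value:,.0f} "
          f"({c.dominance.value})")
```

prints

```
S2 vs S1: dC +11.71, dE +0.00704, ICER 1,663 (trade_off_NE)
S3 vs S1: dC +34.56, dE +0.00908, ICER 3,806 (trade_off_NE)
S3 vs S2: dC +22.85, dE +0.00204, ICER 11,212 (trade_off_NE)
```

i.e. in the synthetic MOF world both proactive strategies buy extra QALYs
at far below £20 000 each — universal IDFracture screening costs £11.71
more per person and yields 0.00704 extra discounted QALYs (ICER
£1,663/QALY), and direct DXA is cost-effective relative to both.

The same analysis is packaged as numbered drivers:

```sh
python analysis/01_generate_parameters.py   # write the parameter bundles
python analysis/02_base_case.py             # base-case tables + cycle-1 check
python analysis/03_deterministic_sensitivity.py
python analysis/04_probabilistic_sensitivity.py --draws 1000 --seed 0
python analysis/05_subgroups.py
```

with outputs under `results/`, or via the CLI (`fracture-cea base-case`,
`dsa`, `psa`, `subgroups`, `generate-params`).

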