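# Methods

## The decision problem

Three strategies for detecting low bone mineral density (BMD) in adults
with intellectual disabilities, aged 40+, are compared from a UK NHS
perspective: risk-score-gated DXA under current NICE-style eligibility
(S1, base 3% of the cohort scored), universal ID-specific risk scoring
followed by DXA for positives (S2), and universal direct DXA (S3). The
outcome measures are discounted lifetime cost (GBP, 2021/22 prices) and
QALYs per person, combined as ICERs and incremental net monetary benefit.

## Screening cascade

The decision tree works on expected fractional counts. A fraction *s* of
the cohort is risk-scored; a person whose true BMD category is low
(osteoporosis or osteopenia) tests positive with the tool's sensitivity,
and a normal-BMD person with 1 − specificity. The risk tools' accuracy is
defined against the true low-BMD condition because the only downstream
consequence of a positive score is the DXA-confirmed BMD category. All
positives receive a DXA, assumed perfectly accurate, and are treated
according to the confirmed category; false positives return to the normal
state untreated (their DXA cost is still incurred). Negatives and the
unscored remain untreated in their true category. Screening happens once,
at baseline; its cost (risk scores plus DXA scans) enters undiscounted at
cycle 0.

A fraction `frac_no_fracture` (default 0.50) of **every** baseline
bone-status state — treated and untreated alike — is then moved to a
lifetime "no fracture" state that faces background mortality only. This
pool represents the share of the at-risk population that will never
sustain an osteoporotic fracture; drawing it from all states keeps it
identical across strategies, which is essential: if it were drawn only
from untreated states, the untreated population would be mechanically
lower-risk on average than the treated one (for any treatment relative
risk above 1 − frac_no_fracture), and screening would appear harmful by
construction. The cost consequence — treated persons in the pool stop
accruing treatment cost — is a known simplification.

## Markov engine

Nine states, annual cycles from the starting age (default 40) to 100, no
half-cycle correction, cohort size 1000. Competing risks within a cycle
are resolved death-first: death takes m(t), fracture applies to survivors,
so rows are stochastic without renormalisation. Specifics:

* 10-year fracture probabilities are annualised under a constant hazard,
  p = 1 − (1 − p10)^(1/10). Under the lifetime-linear risk option the
  10-year probability is extrapolated linearly to the full horizon H
  (capped at 1) and spread evenly, p = min(1, p10·H/10)/H; a constant-
  hazard annualisation of the capped value would degenerate to annual
  certainty for high-risk groups, so the linear-in-time hazard is used.
* Treated states multiply the fracture probability by the treatment
  relative risk; non-adherent survivors without a fracture (probability
  1 − adherence per cycle, default 0.20) move permanently to the matching
  untreated state and stop accruing treatment cost. Treatment is otherwise
  lifelong.
* The fracture year is a strict one-cycle tunnel (mortality multiplier
  applied to m(t), year-1 cost, utility decrement), exiting to the post-
  fracture state; post fracture is memoryless, with a single re-fracture
  probability, chronic annual cost and its own mortality multiplier.
  Re-fracture returns to the tunnel. The post-fracture state cannot
  remember pre-fracture BMD or treatment arm; this is a structural limit
  of the nine-state design.
* Mortality products that exceed 1 after multipliers (possible for hip
  fracture at ages ≳ 96) are capped at 1 with a runtime warning.
* Costs and utilities accrue from start-of-cycle occupancy (consistent
  with no half-cycle correction) and are discounted by (1 + r)^(−k),
  k = 0, 1, …; cycle 0 is undiscounted. r = 3.5% for both streams.

A vectorised individual-level microsimulation replays the identical
transition rows person by person and serves as the Monte-Carlo oracle:
cohort means must agree within sampling error (checked at 20,000
individuals in the test suite — large enough for tight standard errors,
small enough to run in seconds).

## Economics

ICER = ΔC/ΔE with the cost-effectiveness-plane quadrant attached, since a
negative ratio alone is ambiguous. Exact zeros are tie-broken
deterministically: ΔE ≥ 0 → north-east trade-off, otherwise south-west.
NMB(λ) = λ·ΔE − ΔC; a comparison counts as cost-effective only when
NMB > 0 (strict — an exact zero is not cost-effective, which makes the
CEAC at λ = ICER well defined). Comparisons are S2 vs S1, S3 vs S1 and
the S3-vs-S2 head-to-head. No efficiency frontier is computed.

## Sensitivity analyses

Deterministic scenarios change exactly one serialised parameter path (set
or multiply) and revalidate the bundle, so impossible modifications fail
loudly. The built-in grid varies adherence and each tool's sensitivity
and specificity from 20% below base to (near-)perfect (0.999 for the
ID-tool sensitivity, 1.0 elsewhere), halves and doubles each of the six
unit costs, sets the current-practice screened fraction to its 1% and 5%
bounds, and switches to a 10-year horizon or lifetime-linear risk.

The PSA (default 1000 draws) samples each probability and utility from a
beta matched to its base mean with a group coefficient of variation
(default 0.20 per group — probabilities, utilities, costs — consistent
with the deterministic grid's ±20% span), each cost from a similarly
matched gamma, and the three BMD prevalences jointly from a Dirichlet so
they keep summing to one. Parameters are sampled independently; no
correlation structure is asserted. Parameters whose base value sits on the
boundary (DXA sensitivity/specificity 1.0, universal screened fractions)
carry no uncertainty and stay fixed. Structural settings (discount rate,
ages, cohort size, horizon) are never sampled. Each draw reruns the whole
pipeline including the decision tree. CEAC(λ) is the fraction of draws
with NMB(λ) strictly positive.

## Subgroups

Screened fractions follow the NICE-derived eligibility gradient: 1%–5%
(base 3%) at ages 40–49 for either sex; 35%–50% (base: midpoint 42.5%,
configurable) for women 50–64 and men 50–74; universal from 65 (women)
and 75 (men). Each subgroup starts the cohort at the band's lower age,
runs to 100, and scales fracture and mortality parameters by two
sex-specific scalar multipliers stored in the bundle (defaults: women
1.25× fracture / 0.90× mortality, men 0.75× / 1.15×) rather than separate
full tables.

## Synthetic parameter set

The study's supplementary parameter tables are not publicly available, so
the generator produces a synthetic set chosen once as realistic for this
population; none of its values are calibrated to reproduce published
cost/QALY levels. Central values:

| group | values |
|---|---|
| BMD prevalence | osteoporosis 0.20, osteopenia 0.40, normal 0.40 |
| 10-year fracture risk (MOF) | 0.25 / 0.15 / 0.08 by category |
| 10-year fracture risk (HF) | 0.10 / 0.05 / 0.02 |
| treatment | RR 0.60 (bisphosphonate), 0.90 (vit D/Ca), adherence 0.80/yr |
| mortality | Gompertz through m(40) = 0.005, m(100) = 0.45; fracture-year ×1.8 (MOF) / ×3.0 (HF); post-fracture ×1.3 / ×1.8 |
| re-fracture | 0.06/yr (MOF), 0.04/yr (HF) |
| unit costs (GBP) | risk score 5, DXA 80, osteoporosis treatment 65/yr, osteopenia 45/yr, fracture year 1: 4500 (MOF) / 14000 (HF), post-fracture 1200 / 3500 per yr |
| utilities | baseline 0.88 at 40 declining 0.002/yr; fracture-year ×0.82 / ×0.70; post-fracture ×0.92 / ×0.80 |
| screening | S1 QFracture sens 0.65 spec 0.82 screened 0.03; S2 IDFracture 0.78/0.85 screened 1.0; S3 DXA 1.0/1.0 |

`generate_parameter_set(seed)` jitters epidemiology, costs and utilities
by up to ±10% (prevalences renormalised, mortality anchors jittered before
curve construction so the table stays monotone) to produce families of
plausible model worlds for property testing; structural configuration is
never jittered. The version-pinned reference bundles under
`src/fracture_cea/data/` hold the central values.

What the synthetic world does *not* emulate: real parameter correlations
(e.g. between fracture risk and mortality), ID-specific life tables,
time-varying post-fracture costs, treatment review after five years, or
DXA non-uptake. Passing tests therefore demonstrate correctness of the
machinery — conservation, discounting, economic identities, sampling
distributions, cohort/microsimulation agreement — not the real-world
cost-effectiveness levels, which depend on the unpublished parameters.

## Numerical choices

* Occupancy conservation asserted at 1e−9 per cycle (absolute, cohort of
  1000); transition rows at 1e−10.
* Bundle JSON serialisation round-trips floats exactly (shortest-repr);
  the CSV age-table importer reads with round-trip float precision.
* Beta moment matching requires 0 < mean < 1 and variance below
  mean(1 − mean); violations raise with the offending parameter named.
* Degenerate inputs: ΔE = 0 gives a labelled non-numeric ICER; empty
  traces, empty scenario lists, empty λ grids and non-positive
  microsimulation populations are rejected.
* The microsimulation clamps each row's cumulative probability at 1 to
  guard against round-off when inverting uniform draws.

## Known limitations

Single baseline assessment only; no bisphosphonate adverse events; no
societal costs; memoryless post-fracture state; treatment-cost truncation
for never-fracturing treated persons (see cascade section); subgroup
heterogeneity reduced to two scalar multipliers per sex.
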