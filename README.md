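# steppedcare

A decision-tree cost-utility model comparing a **collaborative stepped care
(CSC)** intervention against **care-as-usual (CAU)** for adults treated for
depression and/or anxiety in primary care, evaluated over a 1-year horizon
in 2019 Australian dollars from a health-sector perspective.

The package is aimed at health economists and mental-health service
researchers who want a tested, scriptable implementation of this class of
model: an eligible-population cohort construction, remission propagation
with area-under-the-curve person-time, DALY-based health outcomes, pathway
costing with cost offsets, incremental analysis, Monte Carlo uncertainty
analysis, and univariate/scenario sensitivity analyses — all driven by a
single declarative YAML parameter file.

## The model

**Population.** Adults (18+) who visited a GP for mental-health treatment
in the past year and have a depressive or anxiety disorder, stratified by
age band, sex, primary diagnosis and severity (mild/moderate/severe):

    n = population × P(GP mental-health visit) × prevalence × severity split

**Health outcomes.** Each stratum passes through three 4-month intervals.
Conditional remission probabilities `p_t` (arm- and disorder-specific,
from trial evidence) move people from *unremitted* to *remitted*;
remission is absorbing within the year. Person-time `LY` in each state is
accumulated by the midpoint (AUC) convention. Health gain is expressed as
healthy-equivalent life years ("DALYs averted"):

    DALYs averted = (1 − DW_unremitted) × LY_unremitted + (1 − DW_remitted) × LY_remitted

with disability weights combined multiplicatively with a background
morbidity weight: `DW_adj = 1 − (1 − DW_condition)(1 − DW_background)`.

**Costs.** The CSC pathway steps mild/moderate cases through nurse-guided
self-help (plus antidepressants when moderate), steps 4-month
non-remitters up to specialised care, sends severe cases to specialised
care directly, amortises provider training per treated person, and applies
a benzodiazepine add-on; CAU splits patients over antidepressants-only,
specialised care and no treatment. Cost offsets value the difference in
unremitted person-years between arms at the annual treatment cost per
unremitted case.

**Incremental analysis.**

    ICER = (ΔC_pathway + cost offsets) / ΔE          [A$ per DALY averted]

with dominance handling on the cost-effectiveness plane (dominant =
cheaper and more effective; dominated = the reverse) and a default
willingness-to-pay threshold of A$50 000/DALY. The probabilistic
sensitivity analysis draws every uncertain parameter from its declared
distribution (beta for probabilities/proportions, gamma for unit costs,
3000 iterations by default), and cost-effectiveness at threshold λ is
judged by net monetary benefit `λ·ΔE − ΔC ≥ 0`.

Because the supplementary data tables that would drive a real application
are not bundled, the package includes a synthetic parameter generator
(`steppedcare.synthetic`) producing complete, internally consistent
parameter sets with realistic Australian-scale magnitudes; its defaults
are documented stand-ins, not published estimates.

## Worked example

```python
from steppedcare import CostUtilityModel, SyntheticConfig

model = CostUtilityModel.from_synthetic(SyntheticConfig(seed=1))
results = model.fit()            # deterministic base case
print(results.summary())

psa = results.psa(seed=1)        # 3000-iteration Monte Carlo
print(f"95% UI: {psa.icer_summary['lower']} to {psa.icer_summary['upper']:.0f}")
print(f"P(cost-effective at A$50,000/DALY): {psa.below_threshold_prop:.1%}")
```

prints

```
Cost-utility analysis: collaborative stepped care vs care-as-usual
  target: both    currency: 2019 A$    horizon: 1 year
  eligible population: 1,421,623 persons

  CSC pathway cost:          A$    1,290,835,413
  CAU pathway cost:          A$      527,422,220
  incremental pathway cost:  A$      763,413,193
  cost offsets:              A$     -559,316,480
  net incremental cost:      A$      204,096,713

  CSC DALYs averted:                   1,192,124
  CAU DALYs averted:                   1,157,308
  incremental DALYs averted:              34,816

  ICER: 5862 A$/DALY averted   (quadrant NE)
  WTP threshold: A$ 50,000/DALY

95% UI: dominant to 30229
P(cost-effective at A$50,000/DALY): 99.6%
```

Read as: delivering stepped care to the ~1.4 M eligible adults would cost
a net A$204 M more than usual care (after A$559 M of avoided treatment
costs) and avert ~34 800 additional DALYs, i.e. A$5 862 per DALY averted —
well below the A$50 000 threshold, with a 99.6% probability of being
cost-effective under parameter uncertainty. The lower uncertainty bound is
*dominant*: in some iterations stepped care is both cheaper and more
effective.

The same pipeline is available from the shell:

```sh
steppedcare generate --seed 1 --out params.yaml
steppedcare base-case params.yaml --out run/
steppedcare psa params.yaml --iterations 3000 --seed 1 --out run/
steppedcare tornado params.yaml --top 10 --out run/
steppedcare scenario params.yaml --id SA1 --out run/
steppedcare report params.yaml --out run/
```

Each run writes CSVs plus a JSON summary and a manifest (parameter-file
digest, seed, version), so results are reproducible from the parameter
file and seed alone.

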