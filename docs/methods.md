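# Methods

This note documents the model implemented by `steppedcare`, the choices
made where the design was genuinely open, and what the synthetic defaults
do and do not represent. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model structure and assumptions

The model is a quasi-decision tree evaluated on a closed cohort over a
1-year horizon with three 4-month intervals, from a health-sector
perspective in 2019 A$. Core assumptions:

- **Two health states.** Each person is *unremitted* or *remitted*;
  remission is absorbing within the year (no relapse), there is no
  mortality and no discounting (1-year horizon). Symptom improvement
  short of remission carries no health gain — a conservative choice that
  understates benefits for partial responders.
- **Conditional interval probabilities.** The remission schedule's three
  probabilities are read as conditional per-interval remission
  probabilities among the still-unremitted. This is the only reading that
  keeps remitted counts monotone for arbitrary inputs. An alternative
  cumulative-proportion reading is available
  (`ModelParameters.remission_reading = "cumulative"`), converted via
  `c_t = (P_t − P_{t−1}) / (1 − P_{t−1})` with a monotonicity clamp.
- **Midpoint person-time.** Within an interval, people who remit
  contribute half the interval (1/6 year) to each state; people already
  remitted contribute the full interval to the remitted state. This is
  algebraically identical to the trapezoid rule on the piecewise-linear
  unremitted-count curve (verified by an independent trapezoid
  implementation and a 200 000-individual microsimulation in the test
  suite). Transition timing within an interval is a structural choice and
  is visible to the tornado analysis via the remission parameters.
- **Additive disorder streams.** Comorbid cases carry a single primary
  diagnosis, so the depression and anxiety streams are disjoint and
  additive: results for the combined target equal the sum of the two
  single-disorder runs (asserted as an invariant).
- **Background morbidity.** State weights are combined multiplicatively
  with a background weight, `DW_adj = 1 − (1 − DW_c)(1 − DW_b)` — the
  standard independent-comorbidity assumption. The remitted state carries
  a small residual weight (may be zero), constrained not to exceed the
  mildest unremitted weight for the same disorder.

## Costing conventions

- Every line item is `unit cost × quantity × coverage × persons in
  branch`, making pathway costs exactly additive across categories and
  degree-1 homogeneous in unit costs (both asserted).
- **Step-up rule.** Mild and moderate cases start in step 1 (guided
  self-help, ± antidepressants); those unremitted at 4 months enter
  step 2 and are split over its three treatment mixes by the step-2
  allocation. Severe cases enter step 2 at month 0. Step-2 item
  quantities represent one specialised-care episode, so entrants from
  step 1 (costed for months 4–8) and severe entrants carry the same
  per-person step-2 cost.
- **Training.** Provider training is amortised per treated person,
  reflecting steady-state operation with trained staff in place; a
  fixed-program mode (`training_mode = "fixed_program"`) charges it as a
  lump sum instead, for throughput-sensitivity questions.
- **Benzodiazepine add-on.** The proportion receiving the add-on lives in
  the pathway allocation; the CSC9/CAU9 item's own `coverage` multiplies
  it (generator defaults set item coverage to 1 so the allocation
  proportion is the single dial).
- **Cost offsets.** `offset = annual treatment cost per unremitted case ×
  (unremitted burden CSC − unremitted burden CAU)`. The default burden is
  unremitted *person-years* from the AUC engine, consistent with the
  outcome side; counting unremitted cases at 12 months instead is
  available (`offset_basis = "end_of_year_cases"`) because "treatment
  costs for unremitted cases" is ambiguous between the two.
- **Time and travel.** Patient time/travel items are configured per arm
  and enter only under scenario SA2; they never touch the base case.

## Uncertainty analysis

- One master seed; iteration *i* draws from the substream
  `SeedSequence(seed, spawn_key=(i,))`, so results are independent of
  execution order and bit-reproducible. Fixed-family values consume no
  random state, so a fully degenerate parameter set reproduces the base
  case draw for draw.
- Parameters are drawn jointly independently. A rank-correlation hook
  (Iman–Conover reordering over a Gaussian-copula score matrix) is
  available through `run_psa(..., correlation=[(id_a, id_b, rho)])` but
  off by default, since no correlation structure is specified by the
  evidence the model encodes.
- Severity splits and branch allocations are renormalised to sum to one
  after their independent beta draws (the usual moment-matched
  alternative to a Dirichlet). Out-of-range draws — possible only for
  mis-specified uniform families — are rejected and redrawn, with the
  rejection count reported.
- Cost-effectiveness at threshold λ is `λ·ΔE − ΔC ≥ 0` (net monetary
  benefit), which behaves coherently in all four quadrants; the CEAC is
  this probability on a λ grid (default 0 to 2×WTP in 101 points).
- **ICER uncertainty intervals.** Percentiles of iteration-wise ICERs are
  not well defined when ΔE changes sign, so draws are ordered *dominant*
  < numeric (ascending) < *dominated* and the 2.5th/97.5th positions of
  that ordering are reported: linearly interpolated where both
  neighbours are numeric, otherwise the nearest-rank label. Percentiles
  of ΔC and ΔE themselves use the inclusive linear-interpolation
  definition.
- **Quadrant tie-breaks.** Boundary draws are assigned deterministically
  and counted: ΔC = 0 with ΔE > 0 goes to SE (no extra cost, more
  effective → dominant), ΔC = 0 with ΔE < 0 to NW (no saving, less
  effective → dominated); ΔE = 0 draws go to SE when ΔC ≤ 0 and NW
  otherwise. Tie counts are reported so the proportions are
  reproducible. In the deterministic classifier, ΔE = 0
  yields *equivalent* (ΔC = 0) or *indeterminate* (ΔC ≠ 0) rather than a
  signed infinity.

## Sensitivity analyses

- The tornado perturbs each addressable point estimate by ±10%
  (distribution families untouched), holding all else fixed, and sorts by
  absolute ICER swing. Probability-type values are clipped at 1 with a
  warning. Perturbed runs that land in a dominance quadrant are excluded
  from the numeric ranking (reported with their label and a warning).
  Group sum-to-one constraints are deliberately *not* re-enforced under a
  univariate perturbation, so the perturbation stays univariate.
- SA1 forces cost offsets to zero; SA2 adds the time/travel layer to both
  arms. Both reuse the deterministic pipeline unchanged and never mutate
  the input parameter set.

## Synthetic parameter generator

The generator emulates the structure of the tabular inputs a real
application would use: age-sex cohorts with consultation, prevalence and
severity proportions; four remission schedules; disability weights; cost
items; and allocation proportions — every probability/proportion with
beta uncertainty (moment-matched so `sd = spread·√(m(1−m))`, valid for
any mean), every unit cost with gamma uncertainty (CV = `spread`,
default 0.10).

Default magnitudes are chosen once for realism at Australian scale and
are *not* estimates from any study: ~19.6 M adults over seven age bands
with a declining demographic profile and mild seeded jitter; 11% GP
mental-health consultation (higher for women); primary-diagnosis
prevalences of 0.30/0.35 (depression/anxiety) among consulters;
GBD-flavoured severity splits and disability weights; care-as-usual
4-month remission probabilities of (0.35, 0.25, 0.20) for depression and
(0.30, 0.22, 0.18) for anxiety with a +0.15 additive stepped-care
advantage per interval; plausible 2019 A$ unit costs (e.g. A$70 × 5
nurse sessions for guided self-help, A$2 640/year treatment cost per
unremitted case, A$20/person amortised training). These defaults place
the base-case ICER in the low-thousands A$/DALY with a mostly-NE,
partly-SE cost-effectiveness plane — a realistic operating regime for
this intervention class — so all code paths (dominance labels, CEAC
shape, offset signs) are exercised.

What the generator does **not** emulate: correlation between parameters,
skewed or heavy-tailed cost distributions beyond gamma, time-varying
pathway allocations, and any real jurisdiction's demography or price
schedule. Passing tests on synthetic sets therefore demonstrate the
*mechanics* of the pipeline (arithmetic identities, conservation laws,
reproducibility, distributional calibration), not the validity of any
particular published estimate.

## Numerical conventions

- All person counts are reals (cohort expectation model, not
  microsimulation); rounding happens only in reports.
- Person-time accumulates interval-weighted counts and divides once by
  the number of intervals, so simple rational inputs (e.g. n = 100,
  p = 0.5) give exact binary results.
- Sum-to-one invariants are enforced at load time to 1e-9; cost
  additivity to 1e-6 absolute; round trips through the YAML parameter
  file preserve full float precision.
- Problem sizes used by the shipped analyses: 14 age-sex cohorts × 2
  disorders × 3 severities (84 strata per arm), 3000 PSA iterations.
  A full PSA runs in seconds on one core.

## Known limitations

- No relapse, mortality, or YLL component; health gains accrue only
  through remission within 12 months.
- CAU allocation proportions are applied at baseline and held fixed over
  the 8-month delivery window.
- The deterministic scenario analyses report point ICERs only; scenarios
  are not re-run probabilistically.
- Price-year conversion is treated as pre-processing: all costs are
  expected in 2019 A$ at load time, with `price_year` retained purely as
  documentation.
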