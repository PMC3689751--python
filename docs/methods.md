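# Methods

## Decision problem and model structure

The package evaluates three primary-care screening strategies for
moderate-to-severe obstructive sleep apnea syndrome (OSAS, apnea–hypopnea
index ≥ 15) in a hypothetical cohort of 50-year-old men whose symptoms
(snoring, obesity, hypertension) make the pre-test probability of disease
high (0.82 at baseline):

* **no screening** — nobody is referred for a sleep study;
* **GP-only** (`without_cp`) — the general practitioner refers 15% of the
  cohort to a sleep specialist on clinical suspicion;
* **pharmacist-assisted** (`with_cp`) — a community-pharmacist program
  (questionnaires, counselling, a letter to the GP) raises the referred
  fraction to 45.4% at baseline, swept over 25–65%.

A one-shot decision tree allocates the cohort at time zero.  Referred
patients undergo in-hospital polysomnography (sensitivity 0.97, specificity
1.00); confirmed cases are offered CPAP, which 10.2% refuse outright.  The
tree's output is the initial occupancy over four live Markov states —
*OSAS treated*, *OSAS untreated*, *no OSAS*, *no OSAS treated* (false
positives on CPAP, only reachable when specificity < 1) — plus a one-time
per-capita upfront cost: one GP visit (€23) for everyone, the pharmacist
program (€75) for everyone in the with-CP arm, and the diagnostic work-up
(polysomnography €837 plus two specialist visits at €50) for every referred
patient, whether or not the test is positive.  Screening is a single
episode: false negatives and the non-referred are never re-screened within
the horizon.

The Markov model runs five annual cycles.  Per cycle, treated patients quit
CPAP with probability 0.10 in the first year and 0.06 thereafter, reverting
to their true disease state (and, for OSAS patients, to the elevated
mortality) from the next cycle.  Background mortality q(age) comes from the
attached life table; untreated OSAS carries an excess cardiovascular risk
expressed as an odds ratio OR = 2.87 applied on the odds scale:
p' = OR·q/(1−q) / (1 + OR·q/(1−q)).  The odds ratio applies only to the
untreated-OSAS state; treated and disease-free patients face baseline risk.

Per-cycle rewards: treated states pay the annual CPAP cost (€1200) plus
follow-up visits (€75 in year 1, €25 after); untreated OSAS pays €1800/year
of combined direct and indirect costs; disease-free untreated patients pay
nothing.  Utilities are 0.55 (treated OSAS), 0.32 (untreated OSAS and
falsely treated), 0.435 (no OSAS).  Costs and QALYs are discounted at
3%/year with the end-of-cycle factor 1/(1+r)^k; upfront costs precede the
first cycle and are not discounted.

## Frozen conventions

Two modelling conventions are not identified by the published description
and were fixed once, by comparing the two candidate settings of each
against the published strategy table, then frozen:

* **Reward timing** (`reward_timing` in `ParameterSet`): rewards accrue on
  the state occupied at the *beginning* of each cycle.  This reproduces all
  seven published cost/QALY columns within ±0.03 QALYs and ±2% on costs;
  the end-of-cycle alternative misses the cost columns by up to 2.6%.  No
  half-cycle correction is applied.
* **Quitting-year cost**: with begin-of-cycle accrual, patients who
  discontinue CPAP during a cycle pay the treated-state cost for that cycle
  — annual granularity makes mid-year proration unidentifiable.

## Background-mortality fixture

The one model input not published is the French 2007–2009 life table.  The
package ships a geometric-hazard stand-in, q(50+k) = 0.005·1.07^k, i.e.
0.5%/year at age 50 growing 7%/year — consistent with published French male
mortality at these ages (q₅₀ ≈ 0.0049, roughly 7–8%/year growth to age 55).
It is configurable (`build_life_table`, CSV import/export) but the default
was chosen for realism and **not** tuned to the published outputs.  Over a
5-year horizon background mortality is a second-order effect; its main
visible consequence is a small systematic offset discussed under
*Known limitations*.

## Sensitivity analyses

**One-way battery.**  The scenario grid ships as package data
(`data/one_way_scenarios.json`): pre-test probability {0.79, 0.85}, PSG
specificity {0.90}, sensitivity {0.90, 1.00}, compliance (low = refusal and
both cessation rates doubled; high = perfect adherence), discount {0, 5%},
PSG cost ±20%, CPAP cost {420, 1400}, program cost {25, 125}, untreated
cost {441, 2714}.  Each row is evaluated at screening rates 25–65% against
the GP-only arm under the same perturbation.  The GP-only column of the
grid is flagged *dominated* when the with-CP strategy dominates it even at
the least favourable swept rate (25%) — the reading of the published grid
that reproduces its dominated/blank pattern.

**Program-cost threshold.**  The pharmacist program is charged once per
cohort member, so the incremental cost of with-CP versus GP-only is affine
in the program cost with unit slope; the cost-neutral program cost is found
by bisection to €0.01 over [0, 1000] (and the linearity itself is tested).
A screening rate is labelled *dominant for any program cost* when the
strategy still saves money at €125, the upper bound of the plausible
program-cost range.

**Probabilistic sensitivity analysis.**  Second-order Monte Carlo with
10,000 draws.  Assigned marginals: beta(1.15, 10.15) for initial CPAP
refusal; beta(3.7, 4.8), beta(2.4, 5.1), beta(2.4, 5.1), beta(2.01, 1.65)
for the four utilities; triangular (mode at base case) for the four
uncertain costs; uniform for the CP screening rate.  The published table
gives the uniform support as [0.25, 0.65] while the narrative says
[0.25, 0.55]; the table value is the default and `default_psa_specs(cp_rate_high=0.55)`
selects the narrative variant.  Parameters without an assigned distribution
are held at base case.  Sampling is independent across parameters (only
marginals are specified), uses one seeded NumPy generator, and draws in a
fixed documented order, so a seed reproduces the analysis bit for bit.
Each comparison is classified into five plane categories at a €40,000/QALY
willingness-to-pay threshold; ties (ΔC = 0) favour the comparator.

## Numerical choices

* Transition matrices are exact row-stochastic 5×5 arrays; traces are
  validated to conserve probability to 1e-12 and to have a non-decreasing
  dead fraction.
* ICERs are reported to 2 decimals (€/QALY); dominance cells print the
  strings `dominant`/`dominated` verbatim.
* Quadrant boundary ties are resolved toward the more favourable quadrant
  (ΔC = 0 with ΔE > 0 → quadrant IV; the origin → IV).
* Bisection tolerance for thresholds: €0.01.
* Degenerate inputs: a zero-year horizon returns the upfront cost and zero
  QALYs; a CE ratio at zero QALYs raises rather than returning infinity;
  an odds-ratio adjustment at p = 1 is rejected.

## Test design and problem sizes

The default suite runs the deterministic pipeline at full size (it is
milliseconds), the one-way battery over the full 17-row grid, trace
conservation over 1,000 random parameter scenarios, a 200,000-individual
microsimulation oracle that must agree with the cohort expectations within
three standard errors, 50,000-draw sampler-calibration checks, and the PSA
at the full 10,000 draws.  Tolerances in the acceptance layer: ±0.03 QALYs
and ±2% on costs for the strategy table, ±€10 on program-cost thresholds,
±5 percentage points on PSA plane fractions, and ±10% for the worst-case
one-way ICER — a ratio of two small differences, for which the component
tolerances propagate to far more than 10%, so 10% is the conservative
choice.

The synthetic scenario generator draws every uncertain parameter uniformly
within its plausible range.  It emulates parameter uncertainty only: it
does not emulate sampling variation in a real cohort, correlations between
parameters, or secular drift in costs — passing property tests therefore
demonstrates internal consistency of the engine, not external validity of
the base-case inputs.

## Known limitations

* With the realistic (but not identical) mortality fixture, the model's
  discounted savings per additional 10% of screening are ≈ €147 against
  ≈ €141 implied by the published table — a ~4% offset that shifts the
  program-cost thresholds to €53.20 (published €48) and €106.40 (published
  €95), and flips the sign of near-zero incremental costs in two rows of
  the one-way grid (PSG specificity 0.90; low compliance at a 65% rate).
  The corresponding acceptance checks are asserted at the published values
  and fail honestly rather than being recalibrated.
* No re-diagnosis, CPAP re-uptake after quitting, age-progression beyond
  the life-table index, or treatment-effect waning.
* Utilities come from standard-gamble elicitation in OSAS patients; the
  model inherits whatever bias that implies.
* The published CE-ratio row is internally consistent with unrounded
  QALYs; recomputing ratios from the printed 2-decimal cells reproduces
  them only to ~0.3% (rounding propagation), which the internal-consistency
  tests account for.
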