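# Methods

## Scope

The package models dose and frequency errors of antibiotics and
anticonvulsants on a neonatal ward under two computerized order-entry
strategies, and the statistics used to compare them.  Prescription and
transcription errors are in scope; administration errors (a wrong value
given despite a correct chart) are not — administration is assumed to
follow the paper-based medication administration chart (PBMAC) exactly.

## Dose checking

A knowledge-base rule carries a recommended dose (mg/kg/dose) and interval
(hours) for a band of patient space: gestational-age, postnatal-age and
optional weight intervals, an optional GFR range, and an indication (a
diagnosis code, or a wildcard shadowed by indication-specific rules).
Within one drug and indication the bands must partition patient space;
the loader rejects overlapping pairs, so at most one rule ever matches.

Checking a line computes `severity_pct = 100 × prescribed / recommended`
for the patient's current weight.  A dose outside a tolerance band
(default ±10% — the source report defines over/underdose without printing
a tolerance, so it is a per-rule parameter) is an overdose or underdose;
an interval differing from the recommended one is curtailed (shorter) or
prolonged (longer).  A line defective in both dose and interval is a
single erroneous ordered medication, labelled by its dose status and
carrying the interval defect as a flag, so each line is counted once.

GFR is estimated with the pediatric Schwartz form `k × length / Scr`
(defaults k = 0.45 term, 0.33 preterm).  The emulated system only names
estimated GFR as a criterion; the estimator is configuration, not
doctrine.

Overdose severity categories for the trend test default to
(100, 150], (150, 200), [200, ∞) percent of the recommended dose: the top
bin is closed on the left so a two-fold dose is "two-fold or greater".
The emulated study did not print its bins, so they are configurable.

## Workflow simulation

One simulated period draws `n_patients` neonates.  Gestational age is
normal around 38 completed weeks (SD 2.2, clipped to 24–42); admission
age and length of stay are lognormal around configurable medians (7 d and
9.1 d for the POE profile, 5 d and 6.7 d for NOE); weight and length
scale with gestational age.  Each hospital day is a therapy day with
probability 0.9; a therapy day carries `1 + Poisson(rate−1)` orders, each
with `1 + Poisson(rate−1)` distinct drugs from the patient's regimen
(capped by the regimen size, which lowers the realized mean — the per-mode
defaults compensate so that patients, orders, ordered medications and
patient-days land near the emulated two-month periods: 69/972/2357/601 and
89/978/2297/648).

Criteria-change events arrive as a Poisson process per patient-day
(default 0.25/day); an event jumps the weight by 12–30%, enough to push
the previously correct dose outside the checking tolerance.

Per ordered medication:

1. With `p_initial_prescription_error` the prescribed value is perturbed —
   a truncated lognormal dose multiplier on (0.2, 3.0) forced outside the
   tolerance band, or (with probability `p_interval_error`) a neighboring
   interval from the allowed set {4, 6, 8, 12, 24, 48} h.
2. Otherwise, on a criteria-change day, with `p_stale_dose_error` the line
   keeps a dosage computed under the outdated criteria.  Stale lines are
   continuations of standing orders: they never pass through order entry
   again, so the CDSS never re-evaluates them and no warning fires.  This
   is the only reading consistent with the emulated period's counts
   (warnings were fewer than prescription errors) and with its description
   of prescribers who "neglected to correct" standing orders.
3. Every freshly entered erroneous line triggers a warning at the step the
   mode dictates — order entry (POE) or countersignature (NOE).  With
   `p_compliance` the prescriber complies and the electronic order is
   corrected; in NOE a complied warning additionally requires updating the
   paper order, neglected with `p_paper_order_not_updated`, in which case
   the Kardex and PBMAC follow the stale paper value (structurally
   impossible in POE, where no paper order exists).
4. A surviving erroneous electronic order is intercepted by a nurse or
   physician before administration with `p_provider_interception`
   (observable as a correct PBMAC under an erroneous electronic order).
5. Values propagate across the documentation hops: the electronic chart
   copies the electronic order exactly; the Kardex and the PBMAC are each
   corrupted with their per-hop probabilities (a slip never reproduces the
   exact correct value, which keeps exact-equality review unambiguous).

Defaults are calibrated once from the emulated period aggregates: initial
error rates from warning volumes (312/2357 and 339/2297), compliance 0.44
and 0.68, stale-dose and per-hop rates from the per-reason error counts,
provider interception from its 12 and 11 events.

What the generator does **not** emulate: renewals of one order across
days (each line lives on its order day, so warning re-display on renewal
is not simulated), dose rounding to ampoule sizes, free-text orders,
administration errors, drug–drug interactions, and any secular trend in
prescriber behaviour within a period.  Passing tests therefore show that
the pipeline's logic is correct under the stated corruption model, not
that real chart review is error-free.

## Classification

The classifier sees only what a chart review would: the documentation
chain, the warning registrations, and the knowledge-base recommendation.
Comparisons are exact equality of recorded values — the review compares
what was written, not measurements.  Decision order: (1) electronic order
and chart both correct → warning interception if a complied warning is on
file, else no error; (2) erroneous electronic order → prescription-stage
error (a registered warning means the initial entry was wrong, no warning
means a stale standing order), intercepted by a provider if the chart is
correct, nonintercepted otherwise — this branch dominates any additional
downstream corruption; (3) correct electronic order with a wrong chart →
nonintercepted transcription error attributed to the earliest corrupted
hop (paper order, then Kardex, then PBMAC).  A complied warning whose
line was later re-corrupted downstream is classified as the resulting
transcription error, not as an interception.

Under the simulator's corruption model every injected-error signature is
distinct, so the classifier provably recovers the hidden labels; the test
suite asserts exact line-by-line agreement on seeded datasets.

## Statistics

Rates are events per exposure unit; the rate ratio is NOE over POE.  The
chi-square feeding Miettinen's test-based interval RR^(1 ± z/χ) is the
uncorrected Pearson 2×2 on (erroneous, correct) counts per period — this
choice reproduces every published interval recomputed in the regression
suite; the person-time (Poisson) variant is available via
`compare_rates(..., ci_chi2="poisson")`.  The trend statistic is the
score form of the Mantel extension (variance without the finite-population
(N−1) factor), which on a two-category table reduces exactly to the
Pearson 2×2; `corrected=True` applies Mantel's hypergeometric variance.
Mann-Whitney uses the exhaustive permutation distribution of U when the
combined sample is ≤ 10 and the tie-corrected normal approximation
otherwise; a fully tied pooled sample returns p = 1.  Tests are two-sided
at α = 0.05; no multiplicity correction is applied.  Report rounding
follows the published conventions (rates to 0.1 percent, ratios and
bounds to 2 decimals, compliance to integer percent).

Degenerate inputs signal rather than guess: a zero reference-period error
count makes the rate ratio undefined, identical rates or a zero
comparison-period count make the test-based CI undefined, and empty table
margins are rejected.

## Known limitations

* The published severity-bin counts behind the trend statistic and the
  per-patient count distributions behind the rank test were never printed,
  so those two results are validated structurally (algebraic identity and
  exact-enumeration equivalence) rather than numerically.
* One published secondary interval differs in the last printed digit from
  the recomputation (e.g. 0.57 vs 0.58 for the initial-dose reason row);
  the `repro` comparison allows one unit in the last digit on bounds.
* The simulator's medication-day totals run high relative to the emulated
  periods because simulated regimens repeat the same drugs across a day's
  orders more uniformly than real wards do.
* The shipped knowledge base is illustrative; its doses are not clinical
  recommendations.
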