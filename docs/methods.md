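# Methods

This note records the models implemented, the parameter choices that matter,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Energy expenditure

REE is treated as equivalent to BMR and estimated by four equations whose
coefficients are frozen in `nutricontrol.energy` exactly as published, so
results are reproducible with no external lookup:

| equation | inputs | formula (kcal/day) |
| --- | --- | --- |
| Harris–Benedict (original) | sex, W kg, H cm, A y | men 66.4730 + 13.7516W + 5.0033H − 6.7550A; women 655.0955 + 9.5634W + 1.8496H − 4.6756A |
| Mifflin-St Jeor | sex, W, H, A | 10W + 6.25H − 5A + 5 (men) / − 161 (women) |
| Katch-McArdle | lean mass L kg | 370 + 21.6L |
| Cunningham | lean mass L kg | 500 + 22L |

Two Harris–Benedict coefficient sets circulate (the original and a later
revision); this package uses the original and documents it here rather than
exposing both. Units are each formula's native convention — BMI takes height
in metres, the BMR equations in centimetres — with explicit converters,
because silent m/cm mixing is the classic failure mode of these calculators.

PAL comes from either route:

* **lifestyle lookup** — sedentary/light 1.40–1.69, moderate 1.70–1.99,
  vigorous 2.00–2.40. Which point of the range to use is a clinical choice;
  both the range and its midpoint are returned, and TEE accepts any PAL.
  PAL takes no sex argument: the BMR absorbs the gender difference.
* **time allocation** — PAL = Σ(hours × PAR)/24 over a 24 h day (validated
  to 1e-9 h), PAR ≥ 1 (1 = rest). Both the exact PAL and a one-decimal
  half-up rounding are reported, because that is how such worked tables are
  conventionally printed; `REFERENCE_DAY_ACTIVITIES` carries the nine-row
  reference day (Σ time×PAR = 42.6, PAL 1.8) used in tests and the CLI.

Caloric balance CB = CC − PEE − REE − TEF holds exactly by construction in
`EnergyComponents`. TEF is a pass-through parameter defaulting to 0: it is
not measured by any instrument in this system's scope.

## Food plans

The macronutrient split reads α, γ, β as *energy-share* fractions of the
day's energy (the natural reading of a "contribution ratio to energy
expenditure"), not gram multipliers; grams follow from the Atwater factors
4/4/9 kcal/g. Fiber and water carry zero energy; soluble fiber's partial
absorbability is real but has no agreed accounting rule, so it is excluded.

Plan validation compares day totals per nutrient (energy, the three macro
gram targets, fiber and water when targeted, and any targeted
micronutrient) at a relative tolerance (default 5%), with relative error
|actual − target| / max(target, 1e-9). Per-meal checks apply only to
energy and only when the plan declares meal energy fractions — how energy is
distributed between meals is a nutritionist's input, not a computation.

Substitution equivalence is defined on the three caloric macronutrients: a
candidate is accepted at the energy-matched quantity
q = q₀·E_target/E_candidate when each macro at q is within tolerance
(default 15%, relative) of the target portion's. Zero-energy foods cannot
energy-match and are skipped. Ranking (summed relative macro error, ties by
food id) is deterministic and independent of table order. Micronutrients do
not filter candidates; defining "equivalent" on them would silently empty
the candidate set for most real tables.

Hydration rules are cumulative strict-threshold increments: the goal is
base + Σ extra over rules whose threshold the temperature strictly exceeds,
which makes the goal monotone in temperature and leaves it untouched at or
below the first threshold.

## Intake accounting

A planned meal is counted as consumed exactly once when any of
confirm / partial / substitution / removal is logged for it; substitution
and removal act as *composition modifiers* (swap or drop an item), and a
partial percentage scales the modified composition. Confirm and partial are
mutually exclusive per (day, meal). This makes daily statistics a pure
function of the set of entries — order-independent — and avoids
double-counting when several in-meal edits are logged, at the cost of not
modelling "ate the meal twice", which the logging vocabulary cannot express
anyway. Extra foods count against the day total only; attributing them to a
meal would require information the log does not carry.

Device exports are ingested as `timestamp,value` CSV. Malformed rows are
rejected per-row with their line number (a batch never aborts); duplicate
timestamps are skipped first-wins, within the file and against
already-ingested device entries, so re-ingesting overlapping exports is
idempotent.

Day boundaries are the local calendar date of the timestamp; a named event
key ("train", "competition") overrides the date and selects the event
variant of the plan.

## Preference model

The learner is a per-(food, context) exponentially decayed acceptance
frequency, context = (meal type, day of week):
score ← score·d + (1 − d)·outcome, outcome 1 for acceptance (confirmed meal
containing the food, extra food, substitution target) and 0 for rejection
(substitution source); defaults d = 0.8, prior 0.5. Scores are bounded in
[0, 1] by induction. Recommendation ranks the nutritional-equivalence set by
score, then macro error, then food id.

This is a deliberate baseline: reinforcement learning is the obvious richer
choice, but without a defined state/action/reward design a deterministic,
testable estimator behind the same `recommend` interface is worth more. A
consequence of recency weighting, visible in the tests: ranking recovery
(Kendall tau against a planted ranking) improves with log length through the
prior-to-data transition and then plateaus with bounded noise rather than
converging — the estimator tracks drifting preferences instead of averaging
them away.

## Synthetic data

The generator is a pure function of its seed (one `numpy` PCG64 stream per
artifact). Defaults — the conditions under which the test-suite results
hold: 12 foods across seven food classes with class-typical macro densities,
energy set *exactly* to 4P + 4C + 9L (Atwater-consistent by construction,
unlike real tables, which carry measurement and rounding noise); a 7-day
plan of four meals plus "train"/"competition" event variants, targets set
self-consistently from the plan's own totals; a simulated week at 85% meal
adherence, 10% substitution rate among eaten meals, ~8 water sips/day of
~200 ± 50 mL, and ~400 ± 100 active kcal/day — unremarkable values for a
moderately adherent adult, chosen once and kept.

Not emulated: food-table measurement error, day-to-day appetite correlation,
meal-skipping patterns that depend on weekday, device clock drift, or
notification-driven behaviour change. Passing tests on this data therefore
demonstrates exact bookkeeping and algorithmic correctness, not behavioural
realism.

## Interaction-cost model

Operator times: K 0.12, P 1.1, H 0.4, B 0.1, M 1.35 s; R (system response)
and D (draw) are deployment measurements, default 0 and injectable per
task. The repeat prefix binds a single following operator ("42K"); grouped
repetition is not part of the notation. Reported times are rounded half-up
to 2 decimals (`decimal`-based, not banker's rounding).

`interaction_report` recomputes every row of the shipped task table from its
sequence with T_acquire = 0 and flags disagreements above 5 ms rather than
silently matching. Two rows flag under the default times: the statistics
view (sequence PBPB recomputes to 2.40 s against a recorded 1.20 s — the
recorded value matches a single PB view) and the consent screen (PBPBPBR
recorded at 4.60 s, consistent only with R = 1.0 s, which the report
confirms when given that R). Flagging is the correct behaviour: the engine's
job is to derive times from sequences, not to reproduce a table at any
cost. That all remaining rows agree to the penny is the evidence the
T_acquire = 0 reading of the table is right.

## Numerical choices

* Nutrient arithmetic is plain float component-wise bookkeeping with no
  hidden rounding; CSV writing preserves full precision and reading uses
  round-trip float parsing, so write→read is exact equality.
* Tolerances: fraction sums (α+γ+β, 24 h coverage) at 1e-9 absolute;
  plan validation and substitution tolerances are user parameters with
  defaults 0.05 and 0.15.
* Relative errors against a zero target use a 1e-9 floor: a nonzero actual
  against a zero target reads as a huge error (flagged/excluded) instead of
  a crash; fraction-of-target against a zero target reports `None`.
* Problem sizes in tests (food tables of 10–30, five-seed plan sweeps,
  30-seed tau curves at up to 400 events) keep any single suite well under
  a minute while still exercising every branch; they are sizes at which the
  brute-force oracles remain trivially auditable.

## Known limitations

* Body-composition estimators that require skinfold or girth protocols
  (Evans, Withers, Lee, and related) are out of scope; lean-mass equations
  accept a measured lean mass instead.
* TEF is never estimated, only subtracted if supplied.
* The preference context is (meal type, weekday); months, weather or
  location contexts would extend the key but are not implemented.
* Live device APIs are out of scope by design; the CSV contracts are the
  integration surface.
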