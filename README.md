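# nutricontrol

A computational toolkit for nutritionist-supervised, multi-device nutrition
control: it estimates a person's energy needs, turns them into validated food
plans, accounts for everything the person logs (meals, substitutions, water,
smartwatch activity), recommends nutritionally equivalent food swaps aligned
with learned preferences, and estimates the human–computer interaction cost
of every logging task with a keystroke-level model (KLM). It is aimed at
digital-health engineers and nutrition researchers who need the numeric core
of such a system without any UI, cloud, or device dependencies — device
streams are ingested as plain CSV exports.

## The models at the core

**Energy expenditure.** Resting energy expenditure (REE) is approximated by
the classic BMR equation family — Harris–Benedict (original coefficients),
Mifflin-St Jeor, Katch-McArdle, and Cunningham — plus BMI and fat-free mass.
The physical activity level, PAL = TEE/REE, scales REE to total energy
expenditure either from a lifestyle-category lookup (sedentary/light
1.40–1.69, moderate 1.70–1.99, vigorous 2.00–2.40) or from a 24-hour time
allocation, PAL = Σ(hours × PAR)/24, where PAR is each activity's energy
cost as a multiple of BMR. Daily caloric balance is CB = CC − PEE − REE −
TEF, with the thermic effect of food (TEF) carried as a parameter defaulting
to 0.

**Food plans.** A plan's daily energy E is split over the caloric
macronutrients by fractions α (protein), γ (carbohydrate), β (lipid) with
α + γ + β = 1, converted to grams by the Atwater factors 4/4/9 kcal/g.
Plans are validated against targets per nutrient; substitutes are found by
solving the energy-matched quantity q = q₀·E_target/E_candidate and
filtering on relative macro error; daily water goals rise with environment
temperature through per-plan hydration rules.

**Interaction cost.** A task's time is T_task = T_acquire + T_execute with
T_execute the sum of KLM operator times over its operator string: K
(keystroke, 0.12 s), P (point, 1.1 s), H (homing, 0.4 s), B (button press,
0.1 s), M (mental preparation, 1.35 s), plus measured R (response) and D
(draw). Strings support repeat prefixes ("42K" = 42 keystrokes).

## Worked example

```python
from nutricontrol import energy, klm
from nutricontrol.plan import macro_energy_split

ree = energy.ree_harris_benedict("male", weight_kg=70, height_cm=175, age_years=30)
day = energy.pal_from_time_allocation(energy.REFERENCE_DAY_ACTIVITIES)
print(f"REE {ree:.1f} kcal/day, PAL {day.pal_1dp}, TEE {energy.tee(ree, day.pal):.0f} kcal/day")

split = macro_energy_split(energy.tee(ree, day.pal), alpha=0.3, gamma=0.5, beta=0.2)
print(f"protein {split.grams_protein:.0f} g, carbs {split.grams_carbs:.0f} g, "
      f"lipids {split.grams_lipids:.0f} g")

t = klm.execute_time(klm.parse_klm("PBPBMHKKKMHPBPB"))
print(f"logging one extra food costs {t.seconds} s")
```

prints

```
REE 1702.0 kcal/day, PAL 1.8, TEE 3021 kcal/day
protein 227 g, carbs 378 g, lipids 67 g
logging one extra food costs 8.66 s
```

i.e. a 30-year-old, 70 kg, 1.75 m man at this activity profile expends about
3000 kcal/day; a 30/50/20 energy split prescribes those gram quantities; and
manually logging a single out-of-plan food costs the user 8.66 s of
interaction, which is why the package also models smart-bottle/smartwatch
ingestion that costs 0 s.

The same estimates are available from the shell:

```bash
nutricontrol energy --sex male --weight 70 --height 175 --age 30 --lifestyle moderate
nutricontrol klm time "PBPBMHKKKMHPBPB"
nutricontrol klm report          # recompute the full interaction-task table
nutricontrol fixtures --out demo --seed 7   # synthetic food table, plan, week log
```

## Layout

| module | contents |
| --- | --- |
| `nutricontrol.model` | nutrient-vector algebra, persons, appointments, plans, logs |
| `nutricontrol.energy` | BMR/REE equations, PAL, TEE, caloric balance |
| `nutricontrol.plan` | macro split, plan totals/validation, substitution, hydration |
| `nutricontrol.intake` | meal/water/activity logging, device CSV ingestion, daily stats |
| `nutricontrol.klm` | operator-string parser, task timing, interaction report |
| `nutricontrol.preferences` | decayed acceptance-frequency preference model |
| `nutricontrol.fixtures` | seeded synthetic food tables, plans, adherence weeks |
| `nutricontrol.io` / `nutricontrol.cli` | CSV/JSON readers and writers, `nutricontrol` CLI |
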