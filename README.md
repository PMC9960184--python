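# kneesim

A quantitative simulator of alignment and gap-balancing decisions in total
knee arthroplasty (TKA), for surgical training and workflow analysis.

Navigated and robotic TKA turns every surgical step — tibial slope,
varus/valgus cut orientation, resection heights, femoral rotation, component
size and position, soft-tissue releases — into a number, and every number
feeds back into the four joint gaps measured medially and laterally at 0°
(extension) and 90° (flexion). Learning how these decisions couple, and how
the modern alignment philosophies (mechanical, kinematic, restricted
kinematic, functional, patient-specific, ...) choose them differently, is
hard to do safely in the operating room. `kneesim` provides that feedback
loop on synthetic patient cases: a deterministic forward model from decisions
to gaps, rule-based target planners for eleven alignment workflows and three
balancing goals, a fully automatic traffic-light grader for trainee plans,
and a reproducible synthetic cohort generator.

## The model

For a case with measured baseline gaps G₀ (med/lat × ext/flex), a plan
changes the gaps affinely. With side sign σ (medial +1, lateral −1):

```
G[s,ext] = G0[s,ext] + h + σ·k_vv·vv_t − k_s·slope + res_distal[s] + R[s,ext] − k_ffd·FFD
G[s,flex] = G0[s,flex] + h + σ·k_vv·vv_t + k_s·slope + fem_post[s]  + R[s,flex]
fem_post[s] = res_post[s] + σ·k_rot·rot − k_flex·flex − size·2mm − ap
```

where `k_vv = 0.5 mm/°` is the centre-pivot coronal split (one degree of
tibial varus/valgus re-orientation moves each compartment 0.5 mm, in
opposite directions), slope moves extension and flexion gaps oppositely,
distal femoral resections act mm-for-mm on extension gaps only, posterior
decisions on flexion gaps only (the program is anterior-referenced), and `R`
is the cumulative effect of the selected level on a standardised six-level
varus or valgus release ladder (level 0 = approach only, level 5 = maximal,
including the superficial MCL in varus knees). The predicted limb axis is
`HKA = vv_tibia + vv_femur` (varus positive). All decisions live on a 0.1
mm / 0.1° grid; cartilage is recorded in 0.5 mm steps (2.0 mm = intact,
negative = bone defect).

Planners use the cartilage-corrected native joint-line angles
(`MPTA*, mLDFA*`) for the kinematic family, respect each workflow's
boundaries (e.g. rKA: ±5° per bone, |HKA| ≤ 3°), and grade-out against three
balancing goals: **A** four equal gaps, **B** flexion 2 mm looser than
extension, **C** lateral flexion 2 mm looser than medial flexion with both
extension gaps equal to the medial flexion gap. A goal that no plan inside
the workflow's boundaries can reach raises the **blue flag**.

Trainee plans are graded per decision: within 1 mm/1° of the algorithmic
target = green, 1–2 = orange, beyond 2 = red, rolled up into four categories
(bony cuts, gap balancing, HKA, time; time budgets 3/2/5 min per subunit,
>10 min total orange, >12 min red).

## Worked example

Generate five synthetic cases, plan one of them under kinematic alignment,
and compare philosophies:

```
$ kneesim cohort --n 5 --seed 7 --out demo
wrote 5 cases (seed 7); mean MPTA 86.9 deg

$ kneesim plan --cases demo.json --case-id case-0002 --workflow KA
case-0002 KA/C: tibia_slope=0.0 tibia_vv=2.8 tibia_height=0.0 femur_distal_vv=-0.2
  ... release_type=valgus release_level=1 hka_post=2.6 [BLUE: goal not achievable]
```

Case `case-0002` is a mild varus knee (MPTA 87.0°, 6.5° fixed flexion
deformity). KA cuts parallel to its native joint lines (tibia 2.8° varus,
post-implant HKA 2.6° varus) — but the flexion contracture costs both
extension gaps 1.6 mm that measured resection cannot buy back, so the
balancing goal is flagged blue. The comparison screen makes the
philosophical differences explicit (excerpt):

```
$ kneesim compare --cases demo.json --case-id case-0002 --workflows MA-TF,KA,FA
                       MA-TF      KA      FA
tibia_vv                 0.0     2.8     3.0
femur_distal_vv          0.0    -0.2    -0.9
release_type           varus  valgus   varus
release_level              3       1       0
hka_post                 0.0     2.6     2.1
max_residual             0.1   3.725   0.025
goal_met                True   False    True
```

Mechanical alignment keeps the limb neutral but needs a level-3 medial
release; functional alignment buys balance with 3° of tibial varus and no
release. Grading a trainee session (one deliberately sloppy tibial cut):

```
$ kneesim grade --log session.csv --cases demo.json
OK case-0000 MA-TF/A overall=green bony_cuts:green gap_balancing:green hka:green time:green
~  case-0001 MA-TF/A overall=orange bony_cuts:orange gap_balancing:orange hka:orange time:green
OK case-0002 MA-TF/A overall=green bony_cuts:green gap_balancing:green hka:green time:green
pass rate: 100.0% of 3
```

The same operations are available as library calls
(`kneesim.plan_target`, `kneesim.evaluate`, `kneesim.compare_workflows`,
`kneesim.generate_cohort`, ...); see `docs/methods.md` for the model's
assumptions and parameter meanings.

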