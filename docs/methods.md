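# Methods

## Scope and reference frames

`kneesim` models the decision layer of a navigated TKA: it maps quantitative
cut and release decisions onto the four joint gaps and the predicted limb
axis, plans algorithm-optimal targets per alignment philosophy, and grades
arbitrary plans against them. It does not model 3D bone geometry, implant
catalogues, or patient-specific soft-tissue response.

All gap predictions are deltas from a **navigation baseline**: the all-zero
plan reproduces the case's stored gap state exactly. Coronal angles
(`tibia.vv`, `femur.distal_vv`) are absolute to each bone's mechanical axis
(0 = mechanical cut), because that is how navigation displays them and how
the post-implant axis `HKA = vv_t + vv_f` composes. Slope, rotation,
resection heights, size and AP position are deltas from the navigation
system's reference plan, which already realises the conventional slope and
rotational target; the shipped workflow rules therefore default these fields
to 0 rather than to absolute textbook values. This choice keeps the model's
fixed point meaningful (a symmetric knee under any workflow's rule plan stays
symmetric) at the cost of not displaying absolute slope numbers.

## The affine forward model

Per side `s` with sign `σ_med = +1, σ_lat = −1`:

```
G[s,ext] = G0[s,ext] + tib(s) − k_slope·slope + distal_res[s] + R[s,ext]
           − k_ffd·FFD + k_ffd·hyperext + gap_offset_ext
G[s,flex] = G0[s,flex] + tib(s) + k_slope·slope + fem_post(s) + R[s,flex]
            + gap_offset_flex
tib(s)      = height + σ_s·k_vv_split·vv_t
fem_post(s) = post_res[s] + σ_s·k_rot_split·rotation − k_flex·flexion
              − size_index·size_ap_step − ap_shift
```

The model is deterministic and affine in every decision (superposition
holds), mirror-symmetric under med↔lat swap with sign negation, and keeps
distal femoral decisions out of the flexion gaps and posterior-side
decisions out of the extension gaps (anterior referencing).

**Sign conventions.** Varus positive throughout; posterior slope positive;
external rotation positive. A varus tibial re-cut about the centre pivot
deepens the *medial* and spares the lateral resection: with MPTA < 90 the
medial plateau lies more distal, so tilting the plane into varus moves its
medial edge deeper. The same limb logic fixes the femoral pivot coupling,
`res_med − res_lat = k_condyle_pivot·vv_f`: a native-matching varus femoral
cut relieves the medial side. The net medio-lateral extension-gap change of
a plan is then proportional to its HKA change, which is the physically
sensible coupling (both native-matching cuts in a varus knee open the tight
medial compartment). External rotation deepens the posterior-medial
resection (opens the medial flexion gap).

**Coefficients** (all in `SimConfig`, overridable from YAML):

| parameter | default | meaning |
|---|---|---|
| `k_vv_split` | 0.5 mm/° | centre-pivot coronal split per side (fixed property of the simulated workflow) |
| `k_slope` | 0.5 mm/° | slope effect, extension −, flexion + (chosen symmetric to the coronal split) |
| `k_rot_split` | 0.5 mm/° | femoral rotation split on the posterior condyles |
| `k_flex` | 0.5 mm/° | femoral flexion effect on the flexion gap |
| `size_ap_step` | 2.0 mm | posterior resection change per implant size index |
| `k_ffd` | 0.25 mm/° | extension-gap cost of fixed flexion deformity (direction from clinical reasoning; magnitude an open parameter) |
| `k_cart_angle` | 0.5 °/mm | joint-line tilt per mm of asymmetric cartilage loss |
| `k_condyle_pivot` | 1.0 mm/° | linearised condyle half-width for the distal femoral pivot |
| `resolution` | 0.1 | decision grid (validated, never silently rounded) |
| `balance_tolerance` | 1.0 mm | balancing-goal acceptance band |
| `search_step` | 0.5° | planner/feasibility grid step |

**Native angles.** Pre-arthritic MPTA/mLDFA are estimated by adding the
cartilage loss back toward the worn side:
`native = measured + k_cart_angle·(loss_med − loss_lat)` per bone. Symmetric
loss cancels. The distal femoral pivot sits on the most prominent condyle,
judged on remaining distal cartilage; ties pivot medially.

**Cartilage compensation** of the kinematic-family planners enters through
these native angles only; resection pairs are then derived from the pivot
coupling. Folding the wear additionally into the resection values would
double-count the same correction.

## Release ladders

Six cumulative levels per deformity direction, strictly lateralised (a varus
ladder only opens the medial compartment), level 0 the approach alone. The
magnitudes used by commercial trainers are not public; the shipped
defaults are literature-informed plausible values chosen once at design
time, with flexion effects tracking extension effects:

| level | varus structures | (med_ext, med_flex) mm |
|---|---|---|
| 0 | approach only | 0, 0 |
| 1 | medial osteophytes | 0.5, 0.5 |
| 2 | deep MCL, anterior fibres | 1.0, 1.0 |
| 3 | deep MCL + posteromedial capsule | 2.0, 1.5 |
| 4 | semimembranosus / POL | 2.5, 2.0 |
| 5 | superficial MCL (maximal) | 4.0, 3.5 |

The valgus ladder mirrors laterally (osteophytes → ITB → posterolateral
capsule → popliteus → LCL). Only the structure (six levels, zero start,
cumulative monotone, strict laterality) is load-bearing; the tables are
config-replaceable and responses are standard values, not patient-specific.

## Balancing goals and residuals

Goal A: four equal gaps. Goal B: flexion = extension + 2 mm, med = lat per
pose. Goal C: lat flex = med flex + 2 mm, both extension gaps = med flex.
Residuals are signed deviations from the goal relations relative to an
anchor gap (med ext for A/B, med flex for C); a goal is met when the largest
absolute residual is within `balance_tolerance`. Planner gap targets are
anchored on the looser extension side, so planners open tight compartments
rather than closing loose ones.

## Planners

Tibia-first workflows fix the tibial cut by rule, then for every release
level solve the femur in closed form: per-side distal resections match the
extension targets (the implied coronal angle clamped into the workflow's
per-bone and limb boundaries, the symmetric part preserved), rotation takes
the flexion asymmetry and symmetric posterior resections the rest.
Femur-first workflows emit the measured-resection rule plan and report the
residual imbalance. Search workflows (aMA-TF, FA, FA-FF) additionally grid
the free coronal/slope decisions at `search_step`.

Candidate ranking is lexicographic and deterministic: goal met first, then
the workflow's objective — release level for the adjusted-mechanical policy,
maximal residual for the functional policy — then deviation from the
philosophy's reference anatomy (mechanical or native), then the smallest
parameter vector. Emitted decisions are snapped to the 0.1 grid (snapping
error ≤ 0.05 mm per term, well inside the tolerance).

Registry defaults (all config-overridable): MA-TF (0/0, goal A), aMA-TF
(±3° per bone, |HKA| ≤ 3, fewest releases), CV (native tibial varus clamped
to [0, 3]°), AA (3° varus tibia / 3° valgus femur), PSA (native within ±3°,
goal C), iKA (native tibia, femur gap-solved, unrestricted), FA (grid
optimum within ±3° tibia / ±5° femur / |HKA| ≤ 3, goal C), MA-FF (measured
resection 0/0), KA (unrestricted native restoration, rotation 0 to the
posterior condyles), rKA (KA with ±5° per bone, |HKA| ≤ 3), FA-FF
(functional alignment executed femur-first: femoral cuts from native
anatomy within ±3°, tibial vv/slope and release solved to balance). FA-FF
completes the registry at eleven workflows; it is the common femur-first
execution order of functional alignment on image-based robotic systems.

**Feasibility / blue flag.** `goal_feasible` reuses the planner's exhaustive
search: since the search minimises the residual over the workflow's whole
discrete decision space, the goal is feasible iff the best plan meets it.
The test suite cross-checks this against an independent finer-grid brute
force derived directly from the affine gap arithmetic, excluding a
knife-edge band around the tolerance where grid resolution legitimately
decides.

## Evaluation

Per-decision deltas against the target plan; green iff |Δ| ≤ 1, orange iff
1 < |Δ| ≤ 2, red beyond ("within" read inclusive, so exactly 1.0 is green
and exactly 2.0 orange; angles and lengths share thresholds in native
units). Component size is graded in millimetre-equivalents
(`size_index·size_ap_step`). The release level is reported but graded only
through its gap effect. Categories: bony cuts = worst decision colour; gap
balancing = grade of the largest balance residual of the trainee's gaps;
HKA = grade of the deviation from the target's predicted axis; time = 3/2/5
min subunit budgets (over budget orange, never red) with totals >10 min
orange, >12 min red. The overall colour is the worst category — time
included, though in practice it rarely decides alone — or blue when the
goal is infeasible; blue and red do not pass.

## Synthetic cohorts

`PhenotypeParams` encodes an arthritic-population model: MPTA ~ N(87, 2.5²)
and mLDFA ~ N(87.5, 2²) (truncated to [80, 95], snapped to 0.5°), a
non-negative joint-line convergence angle acting in the deformity
direction, `hka_dev = (90 − MPTA) + (mLDFA − 90) ± JLCA`. Cartilage loss
lands on the concave compartment, scales with |hka_dev|
(`cart_severity` = 0.35 mm/° with multiplicative spread, posterior surfaces
milder), and never exceeds the concave side on the convex side; the
Kellgren–Lawrence grade follows the worst loss deterministically. Gap
asymmetry puts `gap_asym·|hka_dev|` of extra laxity on the convex side —
default 1.0 mm/°, the same mm-per-degree scale as the cut model's coronal
split, so a joint-line-restoring cut of the deformity magnitude removes the
asymmetry it mimics. Per-gap Gaussian laxity noise (1.0 mm) and occasional
FFD (30%) or hyperextension (10%) complete the case.

What the generator does **not** emulate: correlated flexion/extension laxity
envelopes, rotational (posterior-condylar) phenotypes, osteophyte volume,
extra-articular deformity, and non-Caucasian phenotype frequencies (the
emulated source population is Caucasian-only). Passing tests therefore show
internal consistency of model + planners + grader on realistic coronal
phenotypes, not clinical validity on any real population.

Problem sizes in the shipped tests and acceptance script — 10,000 cases for
distributional recovery, 125-case cohorts for scenario enumeration
(125 × 11 workflows × 3 goals = 4125 scenarios), 100 cases for the
feasibility cross-check — are the package's own choices balancing
statistical resolution against desk-scale runtimes.

## File formats

Cases serialise to JSON (one object per case) or CSV (one row per case)
with columns `case_id, age, sex, height, weight, hka_dev, mpta, mldfa,
kl_grade, cartilage_<surface> ×6, ffd, hyperextension, initial_<gap> ×4`;
session logs carry `case_id, workflow_id, goal_id`, all plan fields and the
three subunit times. Floats are written at one decimal (the 0.1 grid), so
round-trips are loss-free and outputs byte-stable; every CLI artefact embeds
the effective model configuration. Config YAML: a `model` section overriding
`SimConfig` fields and an optional `release_ladders` section with
replacement tables.

## Known limitations

Soft-tissue effects are standard values; the FFD gap cost is linear and
symmetric; slope/rotation are modelled as deltas, so absolute slope targets
are not displayed; the feasibility search is exact only on its grid;
planner tie-breaks, while deterministic, are one defensible convention among
several.
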