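"""Alignment-philosophy planners, goal feasibility and workflow comparison.

Eleven alignment workflows are registered, split into two families:

* **tibia-first** (MA-TF, aMA-TF, CV, AA, PSA, iKA, FA): the tibial cut is
  fixed by the philosophy's rule, a release level is selected, and the
  femoral parameters are solved so the resulting gaps satisfy the balancing
  goal (within the workflow's boundaries);
* **femur-first** (MA-FF, KA, rKA, FA-FF): femoral and tibial cuts follow the
  philosophy's measured-resection rule and the residual imbalance is
  reported.  FA-FF is the femur-first execution of functional alignment:
  femoral cuts from native anatomy within a safe zone, then the tibial cut,
  slope and release are solved to balance.

Coronal cut angles are absolute to each bone's mechanical axis (0 =
mechanical); slope and rotation are deltas from the navigation reference
plan.  Planner searches run on a 0.5-degree grid (``SimConfig.search_step``)
and all emitted decisions are snapped to the 0.1 grid.  Tie-breaking is
lexicographic and therefore fully deterministic: goal met first, then the
workflow's objective (release level for the adjusted-mechanical policy,
maximal residual for the functional policy), then deviation from the
philosophy's reference anatomy, then the smallest parameter vector.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .goals import BalancingGoal, check_balance, get_goal
from .model import (
    compute_gaps,
    compute_hka,
    derive_distal_resections,
    native_angles_from_cartilage,
)
from .releases import N_LEVELS
from .types import (
    VV_HARD_LIMIT,
    CutPlan,
    FemurPlan,
    GapState,
    KneeCase,
    SimConfig,
    snap,
)


class Boundaries(BaseModel):
    """Hard limits a workflow imposes on its own plans (degrees)."""

    model_config = ConfigDict(frozen=True)

    max_tibia_vv: float = Field(default=3.0, ge=0.0)
    max_femur_vv: float = Field(default=3.0, ge=0.0)
    max_hka: float = Field(default=3.0, ge=0.0)  # may be inf (unrestricted)
    max_slope_dev: float = Field(default=3.0, ge=0.0)  # delta from reference slope


class WorkflowDefinition(BaseModel):
    """Rule set of one alignment philosophy.

    ``*_mode`` fields select how each coronal decision is obtained:
    ``fixed`` (the rule value), ``native`` (restore the cartilage-corrected
    pre-arthritic angle, optionally clamped), ``search`` (grid-optimised) or
    ``solve`` (closed-form from the gap targets).
    """

    model_config = ConfigDict(frozen=True)

    workflow_id: str
    family: Literal["tibia_first", "femur_first"]
    strategy: Literal[
        "tibia_first_solve",
        "tibia_first_search",
        "femur_first_measured",
        "femur_first_tibia_solve",
    ]
    tibia_vv_mode: Literal["fixed", "native", "search"] = "fixed"
    tibia_vv_value: float = 0.0
    tibia_vv_clamp: Optional[tuple[float, float]] = None
    slope_rule: float = 0.0
    femur_vv_mode: Literal["fixed", "native", "solve"] = "fixed"
    femur_vv_value: float = 0.0
    femur_vv_clamp: Optional[tuple[float, float]] = None
    rotation_mode: Literal["fixed", "solve"] = "solve"
    rotation_value: float = 0.0
    objective: Literal["min_release", "min_residual"] = "min_release"
    cartilage_comp: bool = False  # native angles are cartilage-corrected
    dev_reference: Literal["mechanical", "native"] = "mechanical"
    boundaries: Boundaries = Boundaries()
    goal: BalancingGoal = BalancingGoal(goal_id="A")
    description: str = ""


UNRESTRICTED = Boundaries(
    max_tibia_vv=VV_HARD_LIMIT,
    max_femur_vv=VV_HARD_LIMIT,
    max_hka=math.inf,
    max_slope_dev=3.0,
)


def default_workflows() -> dict[str, WorkflowDefinition]:
    """The registry of shipped alignment workflows.

    The rule parameters are documented literature defaults, not constants:
    every entry can be overridden from the ``workflows`` config section.
    """
    goal_a = BalancingGoal(goal_id="A")
    goal_c = BalancingGoal(goal_id="C")
    wfs = [
        WorkflowDefinition(
            workflow_id="MA-TF",
            family="tibia_first",
            strategy="tibia_first_solve",
            tibia_vv_mode="fixed",
            tibia_vv_value=0.0,
            femur_vv_mode="fixed",
            femur_vv_value=0.0,
            boundaries=Boundaries(max_tibia_vv=0.0, max_femur_vv=0.0, max_hka=0.0),
            goal=goal_a,
            description="Mechanical alignment, gap balanced: both cuts perpendicular "
            "to the mechanical axes, femur solved to the goal.",
        ),
        WorkflowDefinition(
            workflow_id="aMA-TF",
            family="tibia_first",
            strategy="tibia_first_search",
            tibia_vv_mode="search",
            femur_vv_mode="solve",
            dev_reference="mechanical",
            boundaries=Boundaries(max_tibia_vv=3.0, max_femur_vv=3.0, max_hka=3.0),
            goal=goal_a,
            description="Adjusted mechanical alignment: up to 3 deg coronal "
            "adjustment per bone, chosen to minimise the release level.",
        ),
        WorkflowDefinition(
            workflow_id="CV",
            family="tibia_first",
            strategy="tibia_first_solve",
            tibia_vv_mode="native",
            tibia_vv_clamp=(0.0, 3.0),
            femur_vv_mode="fixed",
            femur_vv_value=0.0,
            cartilage_comp=True,
            boundaries=Boundaries(max_tibia_vv=3.0, max_femur_vv=0.0, max_hka=3.0),
            goal=goal_a,
            description="Constitutional varus: tibial cut follows the native varus "
            "joint line up to 3 deg, femur mechanical.",
        ),
        WorkflowDefinition(
            workflow_id="AA",
            family="tibia_first",
            strategy="tibia_first_solve",
            tibia_vv_mode="fixed",
            tibia_vv_value=3.0,
            femur_vv_mode="fixed",
            femur_vv_value=-3.0,
            boundaries=Boundaries(max_tibia_vv=3.0, max_femur_vv=3.0, max_hka=0.0),
            goal=goal_a,
            description="Anatomical alignment: 3 deg varus tibia, 3 deg valgus "
            "femur, restoring the average oblique joint line.",
        ),
        WorkflowDefinition(
            workflow_id="PSA",
            family="tibia_first",
            strategy="tibia_first_solve",
            tibia_vv_mode="native",
            tibia_vv_clamp=(-3.0, 3.0),
            femur_vv_mode="native",
            femur_vv_clamp=(-3.0, 3.0),
            cartilage_comp=True,
            dev_reference="native",
            boundaries=Boundaries(max_tibia_vv=3.0, max_femur_vv=3.0, max_hka=3.0),
            goal=goal_c,
            description="Patient-specific alignment: native joint lines within a "
            "+/-3 deg safe zone.",
        ),
        WorkflowDefinition(
            workflow_id="iKA",
            family="tibia_first",
            strategy="tibia_first_solve",
            tibia_vv_mode="native",
            femur_vv_mode="solve",
            cartilage_comp=True,
            dev_reference="native",
            boundaries=UNRESTRICTED,
            goal=goal_c,
            description="Inverse kinematic alignment: tibia restores the native "
            "joint line, femur is gap-solved.",
        ),
        WorkflowDefinition(
            workflow_id="FA",
            family="tibia_first",
            strategy="tibia_first_search",
            tibia_vv_mode="search",
            femur_vv_mode="solve",
            objective="min_residual",
            dev_reference="native",
            boundaries=Boundaries(max_tibia_vv=3.0, max_femur_vv=5.0, max_hka=3.0),
            goal=goal_c,
            description="Functional alignment (tibia-first): both cuts optimised "
            "within boundaries to minimise residual imbalance, then releases.",
        ),
        WorkflowDefinition(
            workflow_id="MA-FF",
            family="femur_first",
            strategy="femur_first_measured",
            tibia_vv_mode="fixed",
            tibia_vv_value=0.0,
            femur_vv_mode="fixed",
            femur_vv_value=0.0,
            rotation_mode="fixed",
            rotation_value=0.0,
            boundaries=Boundaries(max_tibia_vv=0.0, max_femur_vv=0.0, max_hka=0.0),
            goal=goal_a,
            description="Mechanical alignment, measured resection: landmark-driven "
            "cuts, gaps accepted as they result.",
        ),
        WorkflowDefinition(
            workflow_id="KA",
            family="femur_first",
            strategy="femur_first_measured",
            tibia_vv_mode="native",
            femur_vv_mode="native",
            rotation_mode="fixed",
            rotation_value=0.0,
            cartilage_comp=True,
            dev_reference="native",
            boundaries=UNRESTRICTED,
            goal=goal_c,
            description="Kinematic alignment: unrestricted restoration of the "
            "pre-arthritic joint lines, rotation to the posterior condyles.",
        ),
        WorkflowDefinition(
            workflow_id="rKA",
            family="femur_first",
            strategy="femur_first_measured",
            tibia_vv_mode="native",
            tibia_vv_clamp=(-5.0, 5.0),
            femur_vv_mode="native",
            femur_vv_clamp=(-5.0, 5.0),
            rotation_mode="fixed",
            rotation_value=0.0,
            cartilage_comp=True,
            dev_reference="native",
            boundaries=Boundaries(max_tibia_vv=5.0, max_femur_vv=5.0, max_hka=3.0),
            goal=goal_c,
            description="Restricted kinematic alignment: KA with +/-5 deg per bone "
            "and +/-3 deg overall limb boundaries.",
        ),
        WorkflowDefinition(
            workflow_id="FA-FF",
            family="femur_first",
            strategy="femur_first_tibia_solve",
            femur_vv_mode="native",
            femur_vv_clamp=(-3.0, 3.0),
            rotation_mode="fixed",
            rotation_value=0.0,
            objective="min_residual",
            dev_reference="native",
            boundaries=Boundaries(max_tibia_vv=3.0, max_femur_vv=3.0, max_hka=3.0),
            goal=goal_c,
            description="Functional alignment (femur-first): femoral cuts from "
            "native anatomy within a safe zone, tibial cut/slope and release "
            "solved to balance.",
        ),
    ]
    return {wf.workflow_id: wf for wf in wfs}


_REGISTRY = default_workflows()


def get_workflow(workflow_id: str) -> WorkflowDefinition:
    try:
        return _REGISTRY[workflow_id]
    except KeyError:
        valid = ", ".join(_REGISTRY)
        raise ValueError(f"unknown workflow {workflow_id!r}; valid ids: {valid}") from None


def workflow_ids() -> list[str]:
    return list(_REGISTRY)


# ---------------------------------------------------------------------------
# planner internals


def _clamp(v: float, lo: float, hi: float) -> float:
    return min(max(v, lo), hi)


def _rule_angle(
    mode: str,
    value: float,
    clamp: Optional[tuple[float, float]],
    native: float,
    bound: float,
) -> float:
    """Resolve a fixed/native coronal rule to a grid angle within its bound."""
    if mode == "fixed":
        v = value
    else:  # native
        v = native
        if clamp is not None:
            v = _clamp(v, *clamp)
    v = _clamp(v, -bound, bound)
    v = _clamp(v, -VV_HARD_LIMIT, VV_HARD_LIMIT)
    return snap(v)


def _hka_window(vv_t: float, max_hka: float) -> tuple[float, float]:
    if math.isinf(max_hka):
        return (-math.inf, math.inf)
    return (-max_hka - vv_t, max_hka - vv_t)


def _solve_femur(
    case: KneeCase,
    tibia,
    vv_t: float,
    level: int,
    rtype: str,
    wf: WorkflowDefinition,
    goal: BalancingGoal,
    config: SimConfig,
    native_f: float,
) -> CutPlan:
    """Closed-form femoral solve: per-side distal resections match the goal's
    extension targets (subject to the coronal clamp), rotation and symmetric
    posterior resections match the flexion targets."""
    base = CutPlan(tibia=tibia, femur=FemurPlan(), release_level=level, release_type=rtype)
    g1 = compute_gaps(case, base, config)
    d = goal.target_gaps(g1).as_array() - g1.as_array()
    d_me, d_le, d_mf, d_lf = d

    kp = config.k_condyle_pivot
    b = wf.boundaries
    lo_h, hi_h = _hka_window(vv_t, b.max_hka)
    if wf.femur_vv_mode == "fixed":
        vv_f = wf.femur_vv_value
    elif wf.femur_vv_mode == "native":
        vv_f = native_f
        if wf.femur_vv_clamp is not None:
            vv_f = _clamp(vv_f, *wf.femur_vv_clamp)
        vv_f = _clamp(vv_f, max(-b.max_femur_vv, lo_h), min(b.max_femur_vv, hi_h))
    else:  # solve: the angle implied by the per-side extension deficits
        vv_f = (d_me - d_le) / kp if kp > 0 else 0.0
        vv_f = _clamp(vv_f, max(-b.max_femur_vv, lo_h), min(b.max_femur_vv, hi_h))
    vv_f = snap(_clamp(vv_f, -VV_HARD_LIMIT, VV_HARD_LIMIT))

    asym = kp * vv_f  # res_med - res_lat
    sym = (d_me + d_le) / 2.0
    res_med = snap(sym + asym / 2.0)
    res_lat = snap(res_med - asym)

    kr = config.k_rot_split
    if wf.rotation_mode == "solve" and kr > 0:
        rot = snap(_clamp((d_mf - d_lf) / (2.0 * kr), -VV_HARD_LIMIT, VV_HARD_LIMIT))
    else:
        rot = snap(wf.rotation_value)
    post_med = snap(d_mf - kr * rot)
    post_lat = snap(d_lf + kr * rot)

    femur = FemurPlan(
        distal_vv=vv_f,
        distal_res_med=res_med,
        distal_res_lat=res_lat,
        rotation=rot,
        post_res_med=post_med,
        post_res_lat=post_lat,
    )
    return base.model_copy(update={"femur": femur})


def _measured_femur(
    case: KneeCase, vv_f: float, rot: float, config: SimConfig
) -> FemurPlan:
    res_med, res_lat = derive_distal_resections(vv_f, case, config)
    return FemurPlan(
        distal_vv=snap(vv_f),
        distal_res_med=res_med,
        distal_res_lat=res_lat,
        rotation=snap(rot),
        post_res_med=0.0,
        post_res_lat=0.0,
    )


def _candidates(case, wf, goal, config):
    """Yield every candidate plan of the workflow's discrete decision space."""
    from .types import TibiaPlan

    mpta_n, mldfa_n = (
        native_angles_from_cartilage(case, config)
        if wf.cartilage_comp or wf.tibia_vv_mode == "native" or wf.femur_vv_mode == "native"
        else (case.mpta, case.mldfa)
    )
    native_t = 90.0 - mpta_n
    native_f = mldfa_n - 90.0
    b = wf.boundaries
    slope = snap(_clamp(wf.slope_rule, -b.max_slope_dev, b.max_slope_dev))

    if wf.tibia_vv_mode == "search":
        n = int(round(b.max_tibia_vv / config.search_step))
        vv_grid = [snap(i * config.search_step) for i in range(-n, n + 1)]
    else:
        vv_grid = [
            _rule_angle(
                wf.tibia_vv_mode, wf.tibia_vv_value, wf.tibia_vv_clamp, native_t, b.max_tibia_vv
            )
        ]

    if wf.strategy in ("tibia_first_solve", "tibia_first_search"):
        for vv_t in vv_grid:
            tibia = TibiaPlan(slope=slope, vv=vv_t, height=0.0)
            for rtype in ("varus", "valgus"):
                for level in range(N_LEVELS):
                    yield _solve_femur(
                        case, tibia, vv_t, level, rtype, wf, goal, config, native_f
                    ), native_t, native_f
    elif wf.strategy == "femur_first_measured":
        vv_t = vv_grid[0]
        lo_h, hi_h = _hka_window(vv_t, b.max_hka)
        vv_f = _rule_angle(
            wf.femur_vv_mode, wf.femur_vv_value, wf.femur_vv_clamp, native_f, b.max_femur_vv
        )
        vv_f = snap(_clamp(vv_f, max(-VV_HARD_LIMIT, lo_h), min(VV_HARD_LIMIT, hi_h)))
        femur = _measured_femur(case, vv_f, wf.rotation_value, config)
        tibia = TibiaPlan(slope=slope, vv=vv_t, height=0.0)
        for rtype in ("varus", "valgus"):
            for level in range(N_LEVELS):
                yield CutPlan(
                    tibia=tibia, femur=femur, release_level=level, release_type=rtype
                ), native_t, native_f
    else:  # femur_first_tibia_solve: femur by rule, tibia/slope/release searched
        vv_f = _rule_angle(
            wf.femur_vv_mode, wf.femur_vv_value, wf.femur_vv_clamp, native_f, b.max_femur_vv
        )
        femur = _measured_femur(case, vv_f, wf.rotation_value, config)
        lo_h, hi_h = _hka_window(vv_f, b.max_hka)  # window now constrains the tibia
        n_v = int(round(b.max_tibia_vv / config.search_step))
        n_s = int(round(b.max_slope_dev / config.search_step))
        for i in range(-n_v, n_v + 1):
            vv_t = snap(i * config.search_step)
            if not (lo_h - 1e-9 <= vv_t <= hi_h + 1e-9):
                continue
            for j in range(-n_s, n_s + 1):
                tibia = TibiaPlan(slope=snap(j * config.search_step), vv=vv_t, height=0.0)
                for rtype in ("varus", "valgus"):
                    for level in range(N_LEVELS):
                        yield CutPlan(
                            tibia=tibia, femur=femur, release_level=level, release_type=rtype
                        ), native_t, native_f


def _objective_key(plan, gaps, met, maxres, wf, native_t, native_f):
    if wf.dev_reference == "native":
        ref_t, ref_f = native_t, native_f
    else:
        ref_t = ref_f = 0.0
    dev = (
        abs(plan.tibia.vv - ref_t)
        + abs(plan.femur.distal_vv - ref_f)
        + abs(plan.tibia.slope - 0.0)
    )
    maxres = round(maxres, 9)
    tiebreak = (
        plan.tibia.vv,
        plan.femur.distal_vv,
        plan.tibia.slope,
        plan.release_type == "valgus",
        plan.release_level,
    )
    if wf.objective == "min_residual":
        # functional policy: smallest residual, then fewest releases, then
        # smallest deviation from the reference anatomy
        main = (maxres, plan.release_level, round(dev, 9))
    elif met:
        # adjusted-mechanical policy: among goal-met plans, fewest releases
        # first, then the smallest deviation from the reference
        main = (plan.release_level, round(dev, 9), maxres)
    else:
        main = (maxres, plan.release_level, round(dev, 9))
    return (0 if met else 1,) + main + tiebreak


def plan_target(
    case: KneeCase,
    wf: "WorkflowDefinition | str",
    config: SimConfig | None = None,
    goal: "BalancingGoal | str | None" = None,
) -> tuple[CutPlan, GapState]:
    """The algorithm-optimal plan for *case* under workflow *wf* and the gaps
    it produces (the "target" column of the evaluation screen).

    Deterministic: the workflow's discrete decision space is enumerated
    exhaustively and ranked by the lexicographic objective described in the
    module docstring.  Emitted plans are snapped to the 0.1 grid and respect
    the workflow's boundaries.
    """
    if isinstance(wf, str):
        wf = get_workflow(wf)
    config = config or SimConfig()
    goal = get_goal(goal) if goal is not None else wf.goal

    best_key, best = None, None
    for plan, native_t, native_f in _candidates(case, wf, goal, config):
        gaps = compute_gaps(case, plan, config)
        met, res = check_balance(gaps, goal)
        maxres = float(np.max(np.abs(res)))
        key = _objective_key(plan, gaps, met, maxres, wf, native_t, native_f)
        if best_key is None or key < best_key:
            best_key, best = key, (plan, gaps)
    return best


def goal_feasible(
    case: KneeCase,
    wf: "WorkflowDefinition | str",
    config: SimConfig | None = None,
    goal: "BalancingGoal | str | None" = None,
) -> bool:
    """True iff some plan inside the workflow's boundaries (coronal grid at
    ``search_step``, all six release levels, gap-solving dimensions in closed
    form) satisfies the balancing goal.

    The planner search minimises the residual over exactly that space, so the
    goal is feasible iff the best plan meets it.  ``False`` is the simulator's
    blue flag: the goal cannot be achieved with this workflow even with
    perfect cuts.
    """
    if isinstance(wf, str):
        wf = get_workflow(wf)
    goal_r = get_goal(goal) if goal is not None else wf.goal
    _, gaps = plan_target(case, wf, config, goal_r)
    met, _ = check_balance(gaps, goal_r)
    return met


class ComparisonNotActivatedError(RuntimeError):
    """Raised when a comparison is requested before all listed workflows have
    been attempted in the session (the comparison screen only unlocks after
    the exercises are performed)."""


#: decision rows of the comparison table, in display order
COMPARISON_ROWS = [
    "tibia_slope",
    "tibia_vv",
    "tibia_height",
    "femur_distal_vv",
    "femur_distal_res_med",
    "femur_distal_res_lat",
    "femur_rotation",
    "femur_post_res_med",
    "femur_post_res_lat",
    "femur_flexion",
    "femur_size_index",
    "femur_ap_shift",
    "release_type",
    "release_level",
    "hka_post",
    "gap_med_ext",
    "gap_lat_ext",
    "gap_med_flex",
    "gap_lat_flex",
    "max_residual",
    "goal_met",
]


class ComparisonTable:
    """Side-by-side decision table: one column per workflow, one row per
    decision field, for a single case."""

    def __init__(self, case_id: str, frame: pd.DataFrame):
        self.case_id = case_id
        self.frame = frame

    def delta(self, a: str, b: str) -> pd.Series:
        """Pairwise numeric difference between two workflow columns."""
        fa = pd.to_numeric(self.frame[a], errors="coerce")
        fb = pd.to_numeric(self.frame[b], errors="coerce")
        return fa - fb

    def __str__(self) -> str:
        return f"case {self.case_id}\n{self.frame.to_string()}"


def _plan_column(case, wf, config, goal):
    plan, gaps = plan_target(case, wf, config, goal)
    met, res = check_balance(gaps, get_goal(goal) if goal is not None else wf.goal)
    t, f = plan.tibia, plan.femur
    return {
        "tibia_slope": t.slope,
        "tibia_vv": t.vv,
        "tibia_height": t.height,
        "femur_distal_vv": f.distal_vv,
        "femur_distal_res_med": f.distal_res_med,
        "femur_distal_res_lat": f.distal_res_lat,
        "femur_rotation": f.rotation,
        "femur_post_res_med": f.post_res_med,
        "femur_post_res_lat": f.post_res_lat,
        "femur_flexion": f.flexion,
        "femur_size_index": f.size_index,
        "femur_ap_shift": f.ap_shift,
        "release_type": plan.release_type,
        "release_level": plan.release_level,
        "hka_post": compute_hka(case, plan),
        "gap_med_ext": gaps.med_ext,
        "gap_lat_ext": gaps.lat_ext,
        "gap_med_flex": gaps.med_flex,
        "gap_lat_flex": gaps.lat_flex,
        "max_residual": round(float(np.max(np.abs(res))), 6),
        "goal_met": met,
    }


def compare_workflows(
    case: KneeCase,
    ids: Iterable[str],
    config: SimConfig | None = None,
    goal: "BalancingGoal | str | None" = None,
    attempted: Optional[Iterable[str]] = None,
) -> ComparisonTable:
    """Target plans of several workflows for one case, side by side.

    When *attempted* is given (the workflows already exercised in the
    session), ids outside it make the comparison refuse, mirroring the
    activation rule of the comparison screen.
    """
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("comparison needs at least two workflow ids")
    for wid in ids:
        get_workflow(wid)  # raises with the list of valid ids
    if attempted is not None:
        missing = [w for w in ids if w not in set(attempted)]
        if missing:
            raise ComparisonNotActivatedError(
                "comparison is only activated after the listed workflows have "
                f"been attempted; not yet attempted: {', '.join(missing)}"
            )
    cols = {wid: _plan_column(case, get_workflow(wid), config, goal) for wid in ids}
    frame = pd.DataFrame(cols, index=COMPARISON_ROWS)
    return ComparisonTable(case.case_id, frame)


__all__ = [
    "Boundaries",
    "WorkflowDefinition",
    "default_workflows",
    "get_workflow",
    "workflow_ids",
    "plan_target",
    "goal_feasible",
    "ComparisonTable",
    "ComparisonNotActivatedError",
    "compare_workflows",
    "COMPARISON_ROWS",
]
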