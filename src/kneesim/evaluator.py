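"""Fully automatic traffic-light evaluation of a trainee's plan.

Every decision is compared with the algorithm-based target of the chosen
workflow.  A delta within 1 mm / 1 degree is green, between 1 and 2 is
orange, beyond 2 is red (boundaries inclusive on the more lenient colour:
exactly 1.0 is green, exactly 2.0 is orange).  Four categories roll the
decisions up — bony cuts, gap balancing, HKA and time — each taking the
worst colour of its members; the overall colour is the worst category, or
blue when the balancing goal is unachievable under the workflow regardless
of cut quality.  An exercise is passed when the overall colour is green or
orange.

Time budgets: tibia 3 min, soft tissue 2 min, femur 5 min per subunit
(over budget = orange); totals over 10 min are orange, over 12 min red.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .goals import BalancingGoal, check_balance, get_goal
from .model import compute_gaps, compute_hka
from .types import CutPlan, GapState, KneeCase, SimConfig
from .workflows import WorkflowDefinition, get_workflow, goal_feasible, plan_target

Colour = Literal["green", "orange", "red", "blue"]

_SEVERITY = {"green": 0, "orange": 1, "red": 2, "blue": 3}
_EPS = 1e-9

GREEN_LIMIT = 1.0  # mm or degrees
ORANGE_LIMIT = 2.0

SUBUNIT_BUDGETS_S = {"tibia_s": 180.0, "soft_tissue_s": 120.0, "femur_s": 300.0}
TOTAL_ORANGE_S = 600.0  # 10 min
TOTAL_RED_S = 720.0  # 12 min

CATEGORIES = ("bony_cuts", "gap_balancing", "hka", "time")


def worst(colours: Sequence[str]) -> str:
    return max(colours, key=lambda c: _SEVERITY[c])


def grade_delta(delta: float) -> Colour:
    """Traffic-light colour of a single decision deviation (mm or degrees)."""
    if not math.isfinite(delta):
        raise ValueError(f"delta must be finite, got {delta!r}")
    d = abs(delta)
    if d <= GREEN_LIMIT + _EPS:
        return "green"
    if d <= ORANGE_LIMIT + _EPS:
        return "orange"
    return "red"


class TimeRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    tibia_s: float = Field(ge=0.0)
    soft_tissue_s: float = Field(ge=0.0)
    femur_s: float = Field(ge=0.0)

    @property
    def total_s(self) -> float:
        return self.tibia_s + self.soft_tissue_s + self.femur_s


def grade_time(t: TimeRecord) -> tuple[dict[str, Colour], Colour]:
    """Per-subunit colours against the predefined budgets plus the total
    colour.  Subunits over budget are orange (never red); only the overall
    time can turn red."""
    sub = {
        name: ("green" if getattr(t, name) <= budget + _EPS else "orange")
        for name, budget in SUBUNIT_BUDGETS_S.items()
    }
    total = t.total_s
    if total <= TOTAL_ORANGE_S + _EPS:
        total_colour: Colour = "green"
    elif total <= TOTAL_RED_S + _EPS:
        total_colour = "orange"
    else:
        total_colour = "red"
    return sub, total_colour


class DecisionDelta(BaseModel):
    model_config = ConfigDict(frozen=True)

    field: str
    trainee: float
    target: float
    delta: float
    colour: Colour
    in_bony_rollup: bool = True


class EvaluationReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    workflow_id: str
    goal_id: str
    deltas: tuple[DecisionDelta, ...]
    categories: dict[str, Colour]
    subunit_time_colours: dict[str, Colour]
    blue_flag: bool
    overall: Colour
    passed: bool
    trainee_gaps: GapState
    target_gaps: GapState
    max_balance_residual: float
    hka_trainee: float
    hka_target: float
    total_time_s: float


def _bony_fields(plan: CutPlan, config: SimConfig) -> list[tuple[str, float]]:
    t, f = plan.tibia, plan.femur
    return [
        ("tibia_slope", t.slope),
        ("tibia_vv", t.vv),
        ("tibia_height", t.height),
        ("femur_distal_vv", f.distal_vv),
        ("femur_distal_res_med", f.distal_res_med),
        ("femur_distal_res_lat", f.distal_res_lat),
        ("femur_rotation", f.rotation),
        ("femur_post_res_med", f.post_res_med),
        ("femur_post_res_lat", f.post_res_lat),
        ("femur_flexion", f.flexion),
        ("femur_size_mm", f.size_index * config.size_ap_step),
        ("femur_ap_shift", f.ap_shift),
    ]


def evaluate(
    case: KneeCase,
    wf: "WorkflowDefinition | str",
    goal: "BalancingGoal | str | None",
    trainee_plan: CutPlan,
    time: TimeRecord,
    config: SimConfig | None = None,
) -> EvaluationReport:
    """Grade *trainee_plan* against the workflow's algorithmic target.

    Bony cuts take the worst per-decision colour; gap balancing grades the
    largest balance residual of the trainee's resulting gaps; HKA grades the
    deviation of the predicted limb axis from the target's; time follows the
    predefined budgets.  The blue flag is raised when the goal is infeasible
    under the workflow, and then dominates the overall colour.
    """
    if isinstance(wf, str):
        wf = get_workflow(wf)
    config = config or SimConfig()
    goal_r = get_goal(goal) if goal is not None else wf.goal

    target_plan, target_gaps = plan_target(case, wf, config, goal_r)

    deltas: list[DecisionDelta] = []
    for (name, tr), (_, tg) in zip(
        _bony_fields(trainee_plan, config), _bony_fields(target_plan, config)
    ):
        d = tr - tg
        deltas.append(
            DecisionDelta(field=name, trainee=tr, target=tg, delta=d, colour=grade_delta(d))
        )
    bony = worst([d.colour for d in deltas])
    # the release decision is reported but graded through its gap effect only
    deltas.append(
        DecisionDelta(
            field="release_level",
            trainee=float(trainee_plan.release_level),
            target=float(target_plan.release_level),
            delta=float(trainee_plan.release_level - target_plan.release_level),
            colour=grade_delta(trainee_plan.release_level - target_plan.release_level),
            in_bony_rollup=False,
        )
    )

    trainee_gaps = compute_gaps(case, trainee_plan, config)
    _, residuals = check_balance(trainee_gaps, goal_r)
    max_residual = float(np.max(np.abs(residuals)))
    gap_colour = grade_delta(max_residual)

    hka_tr = compute_hka(case, trainee_plan)
    hka_tg = compute_hka(case, target_plan)
    hka_colour = grade_delta(hka_tr - hka_tg)

    sub_colours, time_colour = grade_time(time)

    categories: dict[str, Colour] = {
        "bony_cuts": bony,
        "gap_balancing": gap_colour,
        "hka": hka_colour,
        "time": time_colour,
    }
    blue = not goal_feasible(case, wf, config, goal_r)
    overall: Colour = "blue" if blue else worst(list(categories.values()))
    return EvaluationReport(
        case_id=case.case_id,
        workflow_id=wf.workflow_id,
        goal_id=goal_r.goal_id,
        deltas=tuple(deltas),
        categories=categories,
        subunit_time_colours=sub_colours,
        blue_flag=blue,
        overall=overall,
        passed=overall in ("green", "orange"),
        trainee_gaps=trainee_gaps,
        target_gaps=target_gaps,
        max_balance_residual=max_residual,
        hka_trainee=hka_tr,
        hka_target=hka_tg,
        total_time_s=time.total_s,
    )


def aggregate(reports: Sequence[EvaluationReport]) -> dict:
    """Batch summary: pass rate (percent), overall colour distribution
    (percent), red counts per category, and total-time statistics."""
    if not reports:
        raise ValueError("aggregate needs at least one report")
    n = len(reports)
    n_passed = sum(r.passed for r in reports)
    colour_counts = {c: 0 for c in ("green", "orange", "red", "blue")}
    for r in reports:
        colour_counts[r.overall] += 1
    times = [r.total_time_s for r in reports]
    return {
        "n": n,
        "pass_rate_pct": 100.0 * n_passed / n,
        "colour_distribution_pct": {c: 100.0 * k / n for c, k in colour_counts.items()},
        "category_red_counts": {
            cat: sum(r.categories[cat] == "red" for r in reports) for cat in CATEGORIES
        },
        "mean_time_s": float(np.mean(times)),
        "min_time_s": float(np.min(times)),
        "max_time_s": float(np.max(times)),
    }


__all__ = [
    "Colour",
    "CATEGORIES",
    "GREEN_LIMIT",
    "ORANGE_LIMIT",
    "SUBUNIT_BUDGETS_S",
    "TOTAL_ORANGE_S",
    "TOTAL_RED_S",
    "worst",
    "grade_delta",
    "grade_time",
    "TimeRecord",
    "DecisionDelta",
    "EvaluationReport",
    "evaluate",
    "aggregate",
]
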