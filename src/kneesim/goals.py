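"""The three gap-balancing goals and the balance check.

Goal A: all four gaps equal (the traditional target).
Goal B: both flexion gaps 2 mm larger than the extension gaps, medial equal
        to lateral within each pose.
Goal C: lateral flexion gap 2 mm larger than the medial flexion gap; both
        extension gaps equal to the medial flexion gap (the target used by
        the kinematic-family philosophies).

Residuals are signed deviations from the goal's gap relations, expressed
relative to the goal's anchor gap (medial extension for A and B, medial
flexion for C); the anchor's own residual is 0 by construction.  A goal is
met when the largest absolute residual is within the tolerance (1 mm by
default, the same band the traffic-light grader calls green).
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .types import GapState

GOAL_IDS = ("A", "B", "C")


class BalancingGoal(BaseModel):
    model_config = ConfigDict(frozen=True)

    goal_id: Literal["A", "B", "C"]
    tolerance: float = Field(default=1.0, gt=0.0)  # mm
    flexion_offset: float = 2.0  # mm, the "2 mm larger" of goals B and C

    def residuals(self, gaps: GapState) -> tuple[float, float, float, float]:
        """Signed deviations (mm) from the goal relations, ordered
        ``(med_ext, lat_ext, med_flex, lat_flex)``."""
        me, le, mf, lf = gaps.as_array()
        off = self.flexion_offset
        if self.goal_id == "A":
            return (0.0, le - me, mf - me, lf - me)
        if self.goal_id == "B":
            return (0.0, le - me, mf - (me + off), lf - (me + off))
        # goal C, anchored on the medial flexion gap
        return (me - mf, le - mf, 0.0, lf - (mf + off))

    def target_gaps(self, current: GapState) -> GapState:
        """A concrete gap vector satisfying the goal relations, anchored so
        that the tight side is opened rather than the loose side closed: the
        extension reference is the larger of the two current extension gaps."""
        g = max(current.med_ext, current.lat_ext)
        off = self.flexion_offset
        if self.goal_id == "A":
            return GapState(med_ext=g, lat_ext=g, med_flex=g, lat_flex=g)
        if self.goal_id == "B":
            return GapState(med_ext=g, lat_ext=g, med_flex=g + off, lat_flex=g + off)
        return GapState(med_ext=g, lat_ext=g, med_flex=g, lat_flex=g + off)


_DEFAULT_GOALS = {gid: BalancingGoal(goal_id=gid) for gid in GOAL_IDS}


def get_goal(goal: "str | BalancingGoal") -> BalancingGoal:
    if isinstance(goal, BalancingGoal):
        return goal
    try:
        return _DEFAULT_GOALS[goal]
    except KeyError:
        raise ValueError(f"unknown balancing goal {goal!r}; valid: {', '.join(GOAL_IDS)}") from None


def check_balance(gaps: GapState, goal: "str | BalancingGoal") -> tuple[bool, tuple[float, float, float, float]]:
    """Whether *gaps* satisfy *goal* within its tolerance, plus the signed
    residuals of the four gaps from the goal relations."""
    goal = get_goal(goal)
    res = goal.residuals(gaps)
    met = float(np.max(np.abs(res))) <= goal.tolerance + 1e-9
    return met, res


__all__ = ["GOAL_IDS", "BalancingGoal", "get_goal", "check_balance"]
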