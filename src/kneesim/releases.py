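"""Standardised six-level soft-tissue release / osteophyte-removal ladders.

One ladder per deformity direction.  The varus ladder works on medial
structures (and therefore only ever opens the medial compartment), the valgus
ladder mirrors it laterally.  Level 0 is the surgical approach alone; level 5
is the maximal release, which in varus knees includes the superficial medial
collateral ligament (sMCL).  Effects are cumulative: the vector stored at a
level is the total gap change (mm) relative to level 0.

The per-level magnitudes are standard values, not patient-specific responses;
they can be overridden from the ``release_ladders`` config section.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .types import GAP_KEYS, CutPlan, KneeCase, SimConfig

N_LEVELS = 6

#: cumulative (med_ext, lat_ext, med_flex, lat_flex) effects in mm
DEFAULT_VARUS_TABLE = [
    ("approach only", (0.0, 0.0, 0.0, 0.0)),
    ("medial osteophyte removal", (0.5, 0.0, 0.5, 0.0)),
    ("deep MCL, anterior fibres", (1.0, 0.0, 1.0, 0.0)),
    ("deep MCL + posteromedial capsule", (2.0, 0.0, 1.5, 0.0)),
    ("semimembranosus / POL", (2.5, 0.0, 2.0, 0.0)),
    ("superficial MCL (maximal)", (4.0, 0.0, 3.5, 0.0)),
]

DEFAULT_VALGUS_TABLE = [
    ("approach only", (0.0, 0.0, 0.0, 0.0)),
    ("lateral osteophyte removal", (0.0, 0.5, 0.0, 0.5)),
    ("iliotibial band", (0.0, 1.0, 0.0, 1.0)),
    ("posterolateral capsule", (0.0, 2.0, 0.0, 1.5)),
    ("popliteus tendon", (0.0, 2.5, 0.0, 2.0)),
    ("LCL (maximal)", (0.0, 4.0, 0.0, 3.5)),
]


class ReleaseStep(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    effect: tuple[float, float, float, float]  # (med_ext, lat_ext, med_flex, lat_flex)


class ReleaseLadder(BaseModel):
    """An ordered six-level release ladder for one deformity direction."""

    model_config = ConfigDict(frozen=True)

    type: Literal["varus", "valgus"]
    levels: tuple[ReleaseStep, ...]

    @field_validator("levels")
    @classmethod
    def _six_levels(cls, v):
        if len(v) != N_LEVELS:
            raise ValueError(f"a ladder must have exactly {N_LEVELS} levels, got {len(v)}")
        return v

    @model_validator(mode="after")
    def _structure(self) -> "ReleaseLadder":
        table = np.array([step.effect for step in self.levels])
        if np.any(table[0] != 0.0):
            raise ValueError("level 0 (approach only) must have zero effect")
        if np.any(table < 0.0):
            raise ValueError("release effects must be non-negative (releases only open gaps)")
        # strict laterality: the opposite compartment is untouched at every level
        opposite = (1, 3) if self.type == "varus" else (0, 2)
        if np.any(table[:, opposite] != 0.0):
            raise ValueError(f"a {self.type} ladder must not affect the opposite compartment")
        # cumulative effects are component-wise non-decreasing with level
        if np.any(np.diff(table, axis=0) < 0.0):
            raise ValueError("cumulative effects must be non-decreasing with level")
        return self


def _build(type_: str, table) -> ReleaseLadder:
    return ReleaseLadder(
        type=type_,
        levels=tuple(ReleaseStep(label=lbl, effect=tuple(eff)) for lbl, eff in table),
    )


def default_ladder(type_: Literal["varus", "valgus"]) -> ReleaseLadder:
    table = DEFAULT_VARUS_TABLE if type_ == "varus" else DEFAULT_VALGUS_TABLE
    return _build(type_, table)


def get_ladder(type_: Literal["varus", "valgus"], config: SimConfig | None = None) -> ReleaseLadder:
    """The ladder for *type_*, honouring a ``release_ladders`` config override.

    Override format: ``{"varus": [[label, [me, le, mf, lf]], ...], "valgus": ...}``
    (six entries; structural invariants are re-validated).
    """
    if config is not None and config.release_ladders and type_ in config.release_ladders:
        return _build(type_, config.release_ladders[type_])
    return default_ladder(type_)


def release_effect(ladder: ReleaseLadder, level: int) -> np.ndarray:
    """Cumulative gap effect (mm, ``[med_ext, lat_ext, med_flex, lat_flex]``)
    of performing releases up to *level* on *ladder*."""
    if not isinstance(level, (int, np.integer)) or not 0 <= level < N_LEVELS:
        raise ValueError(f"release level must be an integer in 0..{N_LEVELS - 1}, got {level!r}")
    return np.array(ladder.levels[level].effect, dtype=float)


def min_release_for_goal(
    case: KneeCase,
    plan_wo_release: CutPlan,
    goal,
    ladder: ReleaseLadder,
    config: SimConfig | None = None,
) -> Optional[int]:
    """Smallest release level on *ladder* that brings *plan_wo_release* within
    the balancing goal's tolerance for *case*, or ``None`` if no level does."""
    from .goals import check_balance
    from .model import compute_gaps

    for level in range(N_LEVELS):
        plan = plan_wo_release.model_copy(
            update={"release_level": level, "release_type": ladder.type}
        )
        gaps = compute_gaps(case, plan, config)
        met, _ = check_balance(gaps, goal)
        if met:
            return level
    return None


__all__ = [
    "N_LEVELS",
    "ReleaseStep",
    "ReleaseLadder",
    "default_ladder",
    "get_ladder",
    "release_effect",
    "min_release_for_goal",
]
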