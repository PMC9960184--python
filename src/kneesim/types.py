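"""Domain types for the TKA alignment simulator.

All quantitative surgical decisions live on a 0.1 mm / 0.1 degree grid, the
resolution at which navigation and robotic systems accept input.  Cartilage
thickness is recorded in 0.5 mm increments, where 2.0 mm denotes an intact
surface, 0.0 complete loss and negative values a bone defect.

Sign conventions used throughout the package:

* coronal angles (``vv``, ``hka_dev``): varus positive;
* tibial slope: posterior positive;
* femoral rotation: external positive, referenced to the posterior
  condylar line (the navigation reference axis);
* gaps: millimetres, larger = looser.
"""

from __future__ import annotations

import math
from typing import Iterator, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

Side = Literal["med", "lat"]
Pose = Literal["ext", "flex"]

#: absolute tolerance for grid membership checks (no silent rounding)
GRID_TOL = 1e-6

#: hard limit on any coronal cut re-orientation, degrees
VV_HARD_LIMIT = 10.0

CARTILAGE_SURFACES = (
    "tibia_med",
    "tibia_lat",
    "femur_distal_med",
    "femur_distal_lat",
    "femur_post_med",
    "femur_post_lat",
)

GAP_KEYS = ("med_ext", "lat_ext", "med_flex", "lat_flex")


def on_grid(value: float, step: float = 0.1) -> bool:
    """True if *value* is an integer multiple of *step* within ``GRID_TOL``."""
    return abs(value - round(value / step) * step) <= GRID_TOL


def snap(value: float, step: float = 0.1) -> float:
    """Snap *value* to the nearest multiple of *step* (used by planners only;
    user input is validated, never silently rounded)."""
    return round(round(value / step) * step, 6)


def _require_grid(value: float, name: str, step: float = 0.1) -> float:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite")
    if not on_grid(value, step):
        raise ValueError(f"{name}={value} is not a multiple of {step}")
    return float(value)


class SimConfig(BaseModel):
    """Coefficients of the affine cut-to-gap model and planner settings.

    The 0.5 mm/deg coronal split and the 0.1 grid are fixed properties of the
    simulated navigation workflow; every other coefficient is an open model
    parameter with a documented default (see docs/methods.md).
    """

    model_config = ConfigDict(frozen=True)

    k_vv_split: float = 0.5  # mm gap change per degree of tibial vv, per side
    k_slope: float = 0.5  # mm per degree of tibial slope (ext -, flex +)
    k_rot_split: float = 0.5  # mm per degree of femoral rotation, per side
    k_flex: float = 0.5  # mm flexion-gap change per degree of femoral flexion
    size_ap_step: float = 2.0  # mm of posterior resection per implant size index
    k_ffd: float = 0.25  # mm of extension-gap loss per degree of FFD
    k_cart_angle: float = 0.5  # deg of joint-line obliquity per mm of cartilage loss
    k_condyle_pivot: float = 1.0  # mm distal-resection change per degree of femoral vv
    gap_offset_ext: float = 0.0  # implant/insert build-height constant, mm
    gap_offset_flex: float = 0.0
    resolution: float = 0.1
    cart_min: float = -2.0
    balance_tolerance: float = 1.0  # mm, balancing-goal acceptance band
    search_step: float = 0.5  # deg, planner/feasibility grid step
    release_ladders: dict | None = None  # optional override tables, see releases.py

    @field_validator(
        "k_vv_split",
        "k_slope",
        "k_rot_split",
        "k_flex",
        "size_ap_step",
        "k_ffd",
        "k_cart_angle",
        "k_condyle_pivot",
        "balance_tolerance",
        "search_step",
    )
    @classmethod
    def _non_negative(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @field_validator("resolution")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("resolution must be > 0")
        return v


class GapState(BaseModel):
    """The four joint gaps (medial/lateral x extension/flexion), in mm."""

    model_config = ConfigDict(frozen=True)

    med_ext: float
    lat_ext: float
    med_flex: float
    lat_flex: float

    @field_validator("med_ext", "lat_ext", "med_flex", "lat_flex")
    @classmethod
    def _finite(cls, v: float, info) -> float:
        if not math.isfinite(v):
            raise ValueError(f"{info.field_name} must be finite")
        return float(v)

    def __getitem__(self, key: tuple[Side, Pose]) -> float:
        side, pose = key
        return getattr(self, f"{side}_{pose}")

    def as_array(self) -> np.ndarray:
        """Gaps as ``[med_ext, lat_ext, med_flex, lat_flex]``."""
        return np.array([self.med_ext, self.lat_ext, self.med_flex, self.lat_flex])

    @classmethod
    def from_array(cls, values) -> "GapState":
        me, le, mf, lf = (float(v) for v in values)
        return cls(med_ext=me, lat_ext=le, med_flex=mf, lat_flex=lf)

    def shifted(self, delta) -> "GapState":
        return GapState.from_array(self.as_array() + np.asarray(delta, dtype=float))


class CartilageMap(BaseModel):
    """Cartilage thickness of the six articular surfaces, mm, on the 0.5 grid.

    2.0 = intact, 0.0 = complete loss, negative = bone defect.
    """

    model_config = ConfigDict(frozen=True)

    tibia_med: float = 2.0
    tibia_lat: float = 2.0
    femur_distal_med: float = 2.0
    femur_distal_lat: float = 2.0
    femur_post_med: float = 2.0
    femur_post_lat: float = 2.0

    @field_validator(*CARTILAGE_SURFACES)
    @classmethod
    def _valid_thickness(cls, v: float, info) -> float:
        if not math.isfinite(v):
            raise ValueError(f"{info.field_name} must be finite")
        if not on_grid(v, 0.5):
            raise ValueError(f"{info.field_name}={v} is not a multiple of 0.5")
        if v > 2.0 + GRID_TOL or v < -2.0 - GRID_TOL:
            raise ValueError(f"{info.field_name}={v} outside [-2.0, 2.0]")
        return float(v)

    def loss(self, surface: str) -> float:
        """Cartilage loss of *surface* relative to an intact 2.0 mm layer."""
        return 2.0 - getattr(self, surface)

    def items(self) -> Iterator[tuple[str, float]]:
        for s in CARTILAGE_SURFACES:
            yield s, getattr(self, s)


class KneeCase(BaseModel):
    """One patient's anatomy: radiographic angles, cartilage map, deformity
    and the four navigation gaps measured at the start of surgery."""

    model_config = ConfigDict(frozen=True)

    case_id: str
    age: float = 68.0
    sex: Literal["F", "M"] = "F"
    height: float = 168.0  # cm
    weight: float = 80.0  # kg
    hka_dev: float = 0.0  # signed deviation from neutral HKA, varus positive, deg
    mpta: float = 90.0
    mldfa: float = 90.0
    kl_grade: int = Field(default=0, ge=0, le=4)  # Kellgren-Lawrence
    cartilage: CartilageMap = CartilageMap()
    ffd: float = Field(default=0.0, ge=0.0)  # fixed flexion deformity, deg
    hyperextension: float = Field(default=0.0, ge=0.0)
    initial_gaps: GapState = GapState(med_ext=18, lat_ext=18, med_flex=18, lat_flex=18)

    @field_validator("mpta", "mldfa")
    @classmethod
    def _angle_range(cls, v: float, info) -> float:
        if not 75.0 <= v <= 100.0:
            raise ValueError(f"{info.field_name}={v} outside [75, 100] degrees")
        return float(v)

    @model_validator(mode="after")
    def _check(self) -> "KneeCase":
        if self.ffd > 0 and self.hyperextension > 0:
            raise ValueError("ffd and hyperextension are mutually exclusive")
        if min(self.initial_gaps.as_array()) <= 0:
            raise ValueError("all initial gaps must be > 0")
        return self


class TibiaPlan(BaseModel):
    """Tibial cut: posterior slope, coronal re-orientation about the centre
    pivot, and resection-height adjustment at the cut centre."""

    model_config = ConfigDict(frozen=True)

    slope: float = 0.0  # deg, posterior positive
    vv: float = 0.0  # deg, varus positive
    height: float = 0.0  # mm, resection depth at the cut centre

    @field_validator("slope", "vv", "height")
    @classmethod
    def _grid(cls, v: float, info) -> float:
        return _require_grid(v, info.field_name)

    @field_validator("vv")
    @classmethod
    def _hard_limit(cls, v: float) -> float:
        if abs(v) > VV_HARD_LIMIT + GRID_TOL:
            raise ValueError(f"|vv| must be <= {VV_HARD_LIMIT} degrees")
        return v


class FemurPlan(BaseModel):
    """The seven femoral decision degrees of freedom.

    The program is anterior-referenced: size, AP position and femoral flexion
    act on the posterior resection (flexion gap) only.  ``distal_vv`` pivots on
    the most prominent condyle (ties pivot medially); planners emit
    ``(distal_res_med, distal_res_lat)`` pairs consistent with it.
    """

    model_config = ConfigDict(frozen=True)

    distal_vv: float = 0.0  # deg, varus positive
    distal_res_med: float = 0.0  # mm
    distal_res_lat: float = 0.0  # mm
    rotation: float = 0.0  # deg, external positive, to the posterior condylar line
    post_res_med: float = 0.0  # mm
    post_res_lat: float = 0.0  # mm
    flexion: float = 0.0  # deg
    size_index: int = 0  # signed offset from the templated size
    ap_shift: float = 0.0  # mm, posterior positive

    @field_validator(
        "distal_vv",
        "distal_res_med",
        "distal_res_lat",
        "rotation",
        "post_res_med",
        "post_res_lat",
        "flexion",
        "ap_shift",
    )
    @classmethod
    def _grid(cls, v: float, info) -> float:
        return _require_grid(v, info.field_name)

    @field_validator("distal_vv", "rotation")
    @classmethod
    def _hard_limit(cls, v: float) -> float:
        if abs(v) > VV_HARD_LIMIT + GRID_TOL:
            raise ValueError(f"magnitude must be <= {VV_HARD_LIMIT} degrees")
        return v


class CutPlan(BaseModel):
    """A complete set of decisions: tibia, femur and soft-tissue release."""

    model_config = ConfigDict(frozen=True)

    tibia: TibiaPlan = TibiaPlan()
    femur: FemurPlan = FemurPlan()
    release_level: int = Field(default=0, ge=0, le=5)
    release_type: Literal["varus", "valgus"] = "varus"

    @classmethod
    def neutral(cls) -> "CutPlan":
        return cls()
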