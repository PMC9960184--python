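"""Deterministic affine forward model: cut plan -> joint gaps and limb axis.

The all-zero plan reproduces the case's measured navigation gaps exactly; the
model is affine in every decision, so plan effects superpose.  Reference
frames: coronal angles are absolute to the mechanical axis of each bone
(0 = mechanical cut); slope, rotation, resection heights and AP position are
deltas from the navigation system's reference plan, whose predicted gaps are
the stored baseline.

Couplings implemented (per side ``s`` with sign ``sigma_med=+1, sigma_lat=-1``):

* tibial contribution to all four gaps:
  ``tib(s) = height + sigma_s * k_vv_split * vv``  — the coronal re-cut pivots
  on the tibial centre, 0.5 mm per degree per side, opposite directions
  (varus-positive deepens the medial, spares the lateral resection);
* tibial slope moves extension and flexion gaps in opposite directions
  (``-k_slope*slope`` in extension, ``+k_slope*slope`` in flexion);
* distal femoral resections contribute mm-for-mm to the extension gaps only;
* the posterior contribution
  ``fem_post(s) = post_res_s + sigma_s*k_rot_split*rotation
  - k_flex*flexion - size_index*size_ap_step - ap_shift``
  acts on the flexion gaps only (anterior referencing: size/AP/flexion act on
  the posterior resection);
* the selected release level adds the ladder's cumulative effect vector;
* a fixed flexion deformity costs ``k_ffd`` mm of extension gap per degree
  (hyperextension adds the same amount).
"""

from __future__ import annotations

from .releases import get_ladder, release_effect
from .types import CutPlan, GapState, KneeCase, SimConfig, snap


def compute_gaps(case: KneeCase, plan: CutPlan, config: SimConfig | None = None) -> GapState:
    """Predicted gap state of *case* under *plan*.

    Deterministic and affine in every plan parameter; plan fields are
    validated to the 0.1 grid at construction (off-grid values raise a
    validation error naming the field).
    """
    config = config or SimConfig()
    g0 = case.initial_gaps
    t, f = plan.tibia, plan.femur
    ladder = get_ladder(plan.release_type, config)
    r = release_effect(ladder, plan.release_level)

    ext_deformity = -config.k_ffd * case.ffd + config.k_ffd * case.hyperextension

    out = {}
    for side, sigma, i_ext, i_flex in (("med", 1.0, 0, 2), ("lat", -1.0, 1, 3)):
        tib = t.height + sigma * config.k_vv_split * t.vv
        fem_distal = f.distal_res_med if side == "med" else f.distal_res_lat
        post_res = f.post_res_med if side == "med" else f.post_res_lat
        fem_post = (
            post_res
            + sigma * config.k_rot_split * f.rotation
            - config.k_flex * f.flexion
            - f.size_index * config.size_ap_step
            - f.ap_shift
        )
        out[f"{side}_ext"] = (
            g0[side, "ext"]
            + tib
            - config.k_slope * t.slope
            + fem_distal
            + r[i_ext]
            + ext_deformity
            + config.gap_offset_ext
        )
        out[f"{side}_flex"] = (
            g0[side, "flex"]
            + tib
            + config.k_slope * t.slope
            + fem_post
            + r[i_flex]
            + config.gap_offset_flex
        )
    return GapState(**out)


def compute_hka(case: KneeCase, plan: CutPlan) -> float:
    """Predicted post-implant coronal deviation from neutral, degrees, varus
    positive.  Components implanted perpendicular to their mechanical axes
    (both vv = 0) give a neutral limb."""
    return plan.tibia.vv + plan.femur.distal_vv


def native_angles_from_cartilage(
    case: KneeCase, config: SimConfig | None = None
) -> tuple[float, float]:
    """Pre-arthritic (native) MPTA and mLDFA estimated by adding the measured
    cartilage loss back onto the worn side.

    Each millimetre of asymmetric loss tilts the measured joint line by
    ``k_cart_angle`` degrees toward the worn side, so
    ``native = measured + k_cart_angle * (loss_med - loss_lat)`` for each
    bone's own distal surfaces.  Symmetric loss leaves the angles unchanged.
    Used by the kinematic-family planners (KA/rKA/iKA/PSA/CV).
    """
    config = config or SimConfig()
    c = case.cartilage
    k = config.k_cart_angle
    mpta_n = case.mpta + k * (c.loss("tibia_med") - c.loss("tibia_lat"))
    mldfa_n = case.mldfa + k * (c.loss("femur_distal_med") - c.loss("femur_distal_lat"))
    return mpta_n, mldfa_n


def distal_pivot_side(case: KneeCase) -> str:
    """Side of the most prominent distal femoral condyle (the coronal pivot);
    prominence is judged on remaining distal cartilage, ties pivot medially."""
    c = case.cartilage
    return "med" if c.femur_distal_med >= c.femur_distal_lat else "lat"


def derive_distal_resections(
    distal_vv: float, case: KneeCase, config: SimConfig | None = None
) -> tuple[float, float]:
    """Distal resection pair (med, lat) implied by re-orienting the distal cut
    by *distal_vv* about the most prominent condyle.

    The pivot-side resection is unchanged; the other side changes by
    ``k_condyle_pivot`` mm per degree (a linearised condyle half-width).  A
    varus re-cut deepens the medial relative to the lateral resection:
    ``res_med - res_lat = k_condyle_pivot * distal_vv``.
    """
    config = config or SimConfig()
    k = config.k_condyle_pivot
    if distal_pivot_side(case) == "med":
        return 0.0, snap(-k * distal_vv)
    return snap(k * distal_vv), 0.0


def distal_vv_from_resections(
    res_med: float, res_lat: float, config: SimConfig | None = None
) -> float:
    """Coronal re-orientation implied by a distal resection pair (the inverse
    of the pivot coupling, independent of which condyle pivots)."""
    config = config or SimConfig()
    return (res_med - res_lat) / config.k_condyle_pivot


__all__ = [
    "compute_gaps",
    "compute_hka",
    "native_angles_from_cartilage",
    "distal_pivot_side",
    "derive_distal_resections",
    "distal_vv_from_resections",
]
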