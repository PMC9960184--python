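"""Synthetic patient-case generator.

Emulates the structure and phenotype statistics of an intraoperative
navigation database of arthritic knees: normally distributed coronal bone
morphology (population mean MPTA 87 degrees rather than the mechanical 90),
cartilage loss concentrated on the concave compartment of the deformity and
growing with its magnitude, deformity-driven laxity asymmetry of the four
navigation gaps (convex side larger), and occasional fixed flexion deformity
or hyperextension.

Every distributional choice beyond the normality of the bony angles and the
MPTA mean is an explicit, documented parameter of :class:`PhenotypeParams`;
no real patient is reproduced or reproducible.  The laxity-asymmetry scale
defaults to 1 mm of medio-lateral gap difference per degree of coronal
deformity — the same mm-per-degree scale as the cut model's centre-pivot
split (0.5 mm per side per degree), so that a joint-line-restoring cut of
the deformity magnitude removes the asymmetry it mimics.

The generator mirrors a Caucasian-only source population; phenotype
frequencies in other populations differ and are not modelled.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .types import CartilageMap, GapState, KneeCase, snap


class PhenotypeParams(BaseModel):
    """Distribution parameters of the synthetic cohort (degrees, mm)."""

    model_config = ConfigDict(frozen=True)

    mpta_mean: float = 87.0
    mpta_sd: float = Field(default=2.5, gt=0.0)
    mldfa_mean: float = 87.5
    mldfa_sd: float = Field(default=2.0, gt=0.0)
    jlca_mean: float = 1.0  # joint-line convergence angle, >= 0 after truncation
    jlca_sd: float = Field(default=1.0, gt=0.0)
    angle_lo: float = 80.0  # resampling bounds for mpta/mldfa
    angle_hi: float = 95.0
    base_gap: float = Field(default=18.0, gt=0.0)
    laxity_sd: float = Field(default=1.0, ge=0.0)  # per-gap measurement/laxity noise
    gap_asym: float = Field(default=1.0, ge=0.0)  # mm of med-lat difference per deg
    cart_severity: float = Field(default=0.35, ge=0.0)  # mm loss per deg of |hka|
    ffd_prob: float = Field(default=0.3, ge=0.0, le=1.0)
    ffd_mean: float = Field(default=5.0, ge=0.0)
    hyperext_prob: float = Field(default=0.1, ge=0.0, le=1.0)
    hyperext_mean: float = Field(default=3.0, ge=0.0)


def _trunc_normal(rng, mean, sd, lo, hi) -> float:
    # resampling truncation; keeps the shape near-normal for realistic bounds
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def _loss(rng, base: float, lo: float = 0.0, hi: float = 4.0) -> float:
    """One surface's cartilage loss: severity-scaled with multiplicative
    spread, snapped to the 0.5 grid.  Zero severity gives zero loss."""
    if base <= 0:
        return 0.0
    raw = base * rng.uniform(0.6, 1.4)
    return snap(min(max(raw, lo), hi), 0.5)


def generate_case(
    params: PhenotypeParams | None = None,
    rng: Optional[np.random.Generator] = None,
    case_id: str = "case-000",
) -> KneeCase:
    """Draw one synthetic knee.

    The coronal deviation is assembled as
    ``hka_dev = (90 - mpta) + (mldfa - 90) + sign * jlca`` with the
    joint-line convergence angle acting in the direction of the bony
    deformity.  Cartilage loss lands on the concave compartment (medial for
    varus), never exceeding it on the convex side; the Kellgren-Lawrence
    grade follows the worst loss deterministically.
    """
    params = params or PhenotypeParams()
    rng = rng if rng is not None else np.random.default_rng()

    mpta = snap(_trunc_normal(rng, params.mpta_mean, params.mpta_sd, params.angle_lo, params.angle_hi), 0.5)
    mldfa = snap(_trunc_normal(rng, params.mldfa_mean, params.mldfa_sd, params.angle_lo, params.angle_hi), 0.5)
    jlca = max(0.0, rng.normal(params.jlca_mean, params.jlca_sd))
    bony = (90.0 - mpta) + (mldfa - 90.0)
    sign = 1.0 if bony >= 0 else -1.0
    hka_dev = snap(bony + sign * jlca, 0.1)

    concave_med = hka_dev >= 0  # varus: medial compartment concave and worn
    sev = params.cart_severity * abs(hka_dev)
    losses = {}
    for region, scale in (("tibia", 1.0), ("femur_distal", 1.0), ("femur_post", 0.6)):
        concave_loss = _loss(rng, sev * scale)
        convex_loss = _loss(rng, sev * scale * 0.25, hi=concave_loss)
        med_loss, lat_loss = (concave_loss, convex_loss) if concave_med else (convex_loss, concave_loss)
        losses[f"{region}_med"] = med_loss
        losses[f"{region}_lat"] = lat_loss
    cartilage = CartilageMap(**{k: 2.0 - v for k, v in losses.items()})

    worst_loss = max(losses.values())
    kl = min(4, 1 + int(worst_loss >= 0.5) + int(worst_loss >= 1.5) + int(worst_loss >= 2.5))

    ffd = hyper = 0.0
    u = rng.random()
    if u < params.ffd_prob:
        ffd = snap(min(abs(rng.normal(params.ffd_mean, 2.0)), 15.0), 0.5)
    elif u < params.ffd_prob + params.hyperext_prob:
        hyper = snap(min(abs(rng.normal(params.hyperext_mean, 1.5)), 10.0), 0.5)

    # convex side of the deformity is the lax (larger) side
    asym = params.gap_asym * abs(hka_dev)
    med_shift = -asym / 2.0 if concave_med else asym / 2.0
    gaps = {}
    for key, shift in (
        ("med_ext", med_shift),
        ("lat_ext", -med_shift),
        ("med_flex", med_shift),
        ("lat_flex", -med_shift),
    ):
        noise = rng.normal(0.0, params.laxity_sd) if params.laxity_sd > 0 else 0.0
        gaps[key] = snap(max(params.base_gap + shift + noise, 2.0), 0.1)

    age = float(np.clip(round(rng.normal(68.0, 9.0)), 45, 90))
    sex = "F" if rng.random() < 0.6 else "M"
    height = float(round(rng.normal(162.0 if sex == "F" else 175.0, 7.0)))
    weight = float(round(rng.normal(78.0 if sex == "F" else 90.0, 12.0)))

    return KneeCase(
        case_id=case_id,
        age=age,
        sex=sex,
        height=height,
        weight=max(weight, 45.0),
        hka_dev=hka_dev,
        mpta=mpta,
        mldfa=mldfa,
        kl_grade=kl,
        cartilage=cartilage,
        ffd=ffd,
        hyperextension=hyper,
        initial_gaps=GapState(**gaps),
    )


def generate_cohort(
    n: int,
    params: PhenotypeParams | None = None,
    seed: int = 0,
) -> tuple[list[KneeCase], dict]:
    """Generate *n* valid cases plus a manifest recording parameters, seed
    and summary statistics.  Reproducible: the same ``(params, seed)`` yield
    the identical cohort."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or PhenotypeParams()
    rng = np.random.default_rng(seed)
    cases = [generate_case(params, rng, case_id=f"case-{i:04d}") for i in range(n)]

    mptas = np.array([c.mpta for c in cases])
    mldfas = np.array([c.mldfa for c in cases])
    hkas = np.array([c.hka_dev for c in cases])
    manifest = {
        "n": n,
        "seed": seed,
        "params": params.model_dump(),
        "summary": {
            "mpta_mean": round(float(mptas.mean()), 3),
            "mpta_sd": round(float(mptas.std(ddof=1)), 3) if n > 1 else 0.0,
            "mldfa_mean": round(float(mldfas.mean()), 3),
            "hka_dev_mean": round(float(hkas.mean()), 3),
            "varus_fraction": round(float(np.mean(hkas > 0)), 3),
            "ffd_fraction": round(float(np.mean([c.ffd > 0 for c in cases])), 3),
            "mean_gap": round(float(np.mean([c.initial_gaps.as_array().mean() for c in cases])), 3),
        },
    }
    return cases, manifest


__all__ = ["PhenotypeParams", "generate_case", "generate_cohort"]
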