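import pytest

from kneesim import (
    CutPlan,
    FemurPlan,
    GapState,
    KneeCase,
    SimConfig,
    TibiaPlan,
    generate_cohort,
)


@pytest.fixture(scope="session")
def config():
    return SimConfig()


@pytest.fixture
def neutral_case():
    """Mechanically neutral anatomy, intact cartilage, symmetric 18 mm gaps."""
    return KneeCase(case_id="neutral")


@pytest.fixture
def varus_case():
    """Tibial-driven varus knee: MPTA 86, medial compartment 4 mm tighter."""
    return KneeCase(
        case_id="varus",
        mpta=86.0,
        mldfa=90.0,
        hka_dev=4.0,
        initial_gaps=GapState(med_ext=16.0, lat_ext=20.0, med_flex=16.0, lat_flex=20.0),
    )


@pytest.fixture(scope="session")
def small_cohort():
    cases, _ = generate_cohort(25, seed=11)
    return cases


def add_plans(a: CutPlan, b: CutPlan) -> CutPlan:
    """Component-wise sum of two plans (releases must both be level 0)."""
    assert a.release_level == 0 and b.release_level == 0
    return CutPlan(
        tibia=TibiaPlan(
            slope=round(a.tibia.slope + b.tibia.slope, 6),
            vv=round(a.tibia.vv + b.tibia.vv, 6),
            height=round(a.tibia.height + b.tibia.height, 6),
        ),
        femur=FemurPlan(
            distal_vv=round(a.femur.distal_vv + b.femur.distal_vv, 6),
            distal_res_med=round(a.femur.distal_res_med + b.femur.distal_res_med, 6),
            distal_res_lat=round(a.femur.distal_res_lat + b.femur.distal_res_lat, 6),
            rotation=round(a.femur.rotation + b.femur.rotation, 6),
            post_res_med=round(a.femur.post_res_med + b.femur.post_res_med, 6),
            post_res_lat=round(a.femur.post_res_lat + b.femur.post_res_lat, 6),
            flexion=round(a.femur.flexion + b.femur.flexion, 6),
            size_index=a.femur.size_index + b.femur.size_index,
            ap_shift=round(a.femur.ap_shift + b.femur.ap_shift, 6),
        ),
    )
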