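"""Alignment-workflow planners: rule examples, boundary respect, balance
soundness, and the feasibility (blue-flag) oracle cross-check."""

import math

import numpy as np
import pytest

from kneesim import (
    CutPlan,
    GapState,
    KneeCase,
    PhenotypeParams,
    SimConfig,
    check_balance,
    compare_workflows,
    compute_gaps,
    compute_hka,
    default_ladder,
    generate_cohort,
    get_goal,
    get_workflow,
    goal_feasible,
    native_angles_from_cartilage,
    plan_target,
    workflow_ids,
)
from kneesim.releases import N_LEVELS, release_effect
from kneesim.types import FemurPlan, TibiaPlan
from kneesim.workflows import ComparisonNotActivatedError

TIBIA_FIRST = ["MA-TF", "aMA-TF", "CV", "AA", "PSA", "iKA", "FA"]
FEMUR_FIRST = ["MA-FF", "KA", "rKA", "FA-FF"]


class TestRegistry:
    def test_eleven_workflows_registered(self):
        assert len(workflow_ids()) == 11
        assert set(TIBIA_FIRST + FEMUR_FIRST) == set(workflow_ids())

    def test_families(self):
        for wid in TIBIA_FIRST:
            assert get_workflow(wid).family == "tibia_first"
        for wid in FEMUR_FIRST:
            assert get_workflow(wid).family == "femur_first"

    def test_unknown_workflow_lists_valid_ids(self):
        with pytest.raises(ValueError, match="MA-TF"):
            get_workflow("nope")


class TestPlannerExamples:
    def test_neutral_anatomy_is_the_mechanical_fixed_point(self, neutral_case):
        plan, gaps = plan_target(neutral_case, "MA-TF")
        assert plan.tibia.vv == 0.0 and plan.femur.distal_vv == 0.0
        assert compute_hka(neutral_case, plan) == 0.0
        assert plan.release_level == 0
        assert check_balance(gaps, "A")[0]

    def test_ka_restores_native_joint_lines(self, varus_case):
        plan, _ = plan_target(varus_case, "KA")
        assert plan.tibia.vv == pytest.approx(4.0)  # 90 - MPTA 86
        assert plan.femur.distal_vv == pytest.approx(varus_case.mldfa - 90.0)
        assert plan.femur.rotation == 0.0  # to the posterior condylar line

    def test_rka_clamps_the_tibial_cut(self):
        case = KneeCase(case_id="v", mpta=83.0, mldfa=90.0, hka_dev=7.0)
        plan, _ = plan_target(case, "rKA")
        assert plan.tibia.vv == pytest.approx(5.0)
        # limb boundary: overall axis stays within 3 degrees
        assert abs(compute_hka(case, plan)) <= 3.0 + 1e-9

    def test_ma_ff_reports_residual_without_gap_solving(self, varus_case):
        plan, gaps = plan_target(varus_case, "MA-FF")
        f = plan.femur
        assert (f.distal_vv, f.rotation, f.post_res_med, f.post_res_lat) == (0, 0, 0, 0)
        met, res = check_balance(gaps, "A")
        assert max(abs(r) for r in res) > 0  # imbalance is reported, not hidden


class TestInvariants:
    def test_boundary_respect_on_generated_cases(self, small_cohort, config):
        for case in small_cohort:
            for wid in workflow_ids():
                wf = get_workflow(wid)
                plan, _ = plan_target(case, wf, config)
                b = wf.boundaries
                assert abs(plan.tibia.vv) <= b.max_tibia_vv + 1e-9
                assert abs(plan.femur.distal_vv) <= b.max_femur_vv + 1e-9
                assert abs(compute_hka(case, plan)) <= b.max_hka + 1e-9
                assert abs(plan.tibia.slope) <= b.max_slope_dev + 1e-9

    def test_balance_soundness_of_goal_solving_workflows(self, small_cohort, config):
        """Whenever the goal is feasible, the solving planners return a plan
        that actually meets it."""
        for case in small_cohort:
            for wid in TIBIA_FIRST + ["FA-FF"]:
                wf = get_workflow(wid)
                if goal_feasible(case, wf, config):
                    _, gaps = plan_target(case, wf, config)
                    assert check_balance(gaps, wf.goal)[0], (case.case_id, wid)

    def test_ka_identity_with_intact_cartilage(self):
        cases, _ = generate_cohort(40, PhenotypeParams(cart_severity=0.0), seed=5)
        for case in cases:
            plan, _ = plan_target(case, "KA")
            # planned joint-line angles equal the native (here: measured) ones
            assert 90.0 - plan.tibia.vv == pytest.approx(case.mpta)
            assert 90.0 + plan.femur.distal_vv == pytest.approx(case.mldfa)

    def test_mechanical_alignment_hka_is_zero_for_every_case(self, small_cohort):
        for case in small_cohort:
            for wid in ("MA-TF", "MA-FF"):
                plan, _ = plan_target(case, wid)
                assert compute_hka(case, plan) == 0.0

    def test_cartilage_compensation_shifts_the_planned_angle(self):
        from kneesim import CartilageMap

        case = KneeCase(
            case_id="worn",
            mpta=86.0,
            hka_dev=5.0,
            cartilage=CartilageMap(tibia_med=0.0),
            initial_gaps=GapState(med_ext=15, lat_ext=20, med_flex=15, lat_flex=20),
        )
        mpta_n, _ = native_angles_from_cartilage(case)
        assert mpta_n == pytest.approx(87.0)
        plan, _ = plan_target(case, "KA")
        assert plan.tibia.vv == pytest.approx(90.0 - 87.0)


class TestFeasibility:
    def test_neutral_case_feasible_under_every_workflow(self, neutral_case):
        for wid in workflow_ids():
            assert goal_feasible(neutral_case, wid), wid

    def test_uncorrectable_lateral_laxity_is_blue_under_ma_ff(self):
        case = KneeCase(
            case_id="lax",
            initial_gaps=GapState(med_ext=18, lat_ext=18, med_flex=18, lat_flex=24),
        )
        assert not goal_feasible(case, "MA-FF", goal="A")

    def test_agrees_with_independent_finer_brute_force(self, config):
        """Blue-flag search (0.5-degree grid) vs an independent brute force at
        0.25 degrees on 100 random cases: no disagreement outside the
        knife-edge band around the tolerance."""
        cases, _ = generate_cohort(100, seed=17)
        tol = config.balance_tolerance
        band = 0.5
        checked = 0
        for case in cases:
            for wid in workflow_ids():
                wf = get_workflow(wid)
                margin = _brute_force_min_residual(case, wf, config, step=0.25)
                feasible = goal_feasible(case, wf, config)
                if margin <= tol - band:
                    assert feasible, (case.case_id, wid, margin)
                    checked += 1
                elif margin >= tol + band:
                    assert not feasible, (case.case_id, wid, margin)
                    checked += 1
        assert checked >= 100  # the cross-check actually exercised both sides


def _reachable_sum_interval(case, wf, config):
    """Interval (or point) of achievable tibia+femur coronal sums, degrees."""
    mpta_n, mldfa_n = native_angles_from_cartilage(case, config)
    b = wf.boundaries

    def resolve(mode, value, clamp, native, bound):
        if mode == "search":
            return (-bound, bound)
        v = value if mode == "fixed" else native
        if clamp is not None:
            v = min(max(v, clamp[0]), clamp[1])
        v = min(max(v, -bound), bound)
        v = min(max(v, -10.0), 10.0)
        return (v, v)

    t_lo, t_hi = resolve(wf.tibia_vv_mode, wf.tibia_vv_value, wf.tibia_vv_clamp,
                         90.0 - mpta_n, b.max_tibia_vv)
    if wf.femur_vv_mode == "solve":
        f_lo, f_hi = -min(b.max_femur_vv, 10.0), min(b.max_femur_vv, 10.0)
    else:
        f_lo, f_hi = resolve(wf.femur_vv_mode, wf.femur_vv_value, wf.femur_vv_clamp,
                             mldfa_n - 90.0, b.max_femur_vv)
    lo, hi = t_lo + f_lo, t_hi + f_hi
    if not math.isinf(b.max_hka):
        # the femoral angle is clamped into the limb window, not rejected
        lo = min(max(lo, -b.max_hka), b.max_hka)
        hi = min(max(hi, -b.max_hka), b.max_hka)
    return lo, hi


def _brute_force_min_residual(case, wf, config, step=0.25):
    """Independent estimate of the smallest achievable max-residual under the
    workflow's boundaries, by direct arithmetic on the affine gap model.

    Tibia-first planners can zero every goal relation except the
    medio-lateral extension difference (per-side distal and posterior
    resections are free), which cut re-orientation changes degree-for-degree;
    measured-resection planners have no free dimensions beyond the release;
    the femur-first functional variant frees tibial vv and slope.
    """
    goal = wf.goal
    g0 = case.initial_gaps.as_array()
    best = math.inf
    for rtype in ("varus", "valgus"):
        ladder = default_ladder(rtype)
        for level in range(N_LEVELS):
            r = release_effect(ladder, level)
            if wf.strategy in ("tibia_first_solve", "tibia_first_search"):
                e0 = (g0[1] - g0[0]) + (r[1] - r[0])  # lat-med extension diff
                # goals A/B anchor on the medial extension gap, so the full
                # difference is the residual; goal C anchors on the medial
                # flexion gap, which the free posterior resections centre
                # between the two extension gaps, halving it
                scale = 0.5 if goal.goal_id == "C" else 1.0
                lo, hi = _reachable_sum_interval(case, wf, config)
                if lo > hi:
                    continue
                for s in np.arange(lo, hi + step / 2, step):
                    best = min(best, scale * abs(e0 - s))
            elif wf.strategy == "femur_first_measured":
                plan = _measured_rule_plan(case, wf, config, rtype, level)
                _, res = check_balance(compute_gaps(case, plan, config), goal)
                best = min(best, max(abs(x) for x in res))
            else:  # femur-first with tibial solve: affine in (vv_t, slope)
                plan = _measured_rule_plan(case, wf, config, rtype, level)
                g = compute_gaps(case, plan, config).as_array()
                r1_0, r2_0 = g[0] - g[2], g[1] - g[2]
                r3_0 = g[3] - g[2] - goal.flexion_offset
                b = wf.boundaries
                v_lo, v_hi = -b.max_tibia_vv, b.max_tibia_vv
                if not math.isinf(b.max_hka):
                    vv_f = plan.femur.distal_vv
                    v_lo = max(v_lo, -b.max_hka - vv_f)
                    v_hi = min(v_hi, b.max_hka - vv_f)
                if v_lo > v_hi:
                    continue
                v = np.arange(v_lo, v_hi + step / 2, step)[:, None]
                s = np.arange(-b.max_slope_dev, b.max_slope_dev + step / 2, step)[None, :]
                worst = np.maximum(
                    np.abs(r1_0 - s), np.maximum(np.abs(r2_0 - v - s), np.abs(r3_0 - v))
                )
                best = min(best, float(worst.min()))
    return best


def _measured_rule_plan(case, wf, config, rtype, level):
    from kneesim.model import derive_distal_resections

    mpta_n, mldfa_n = native_angles_from_cartilage(case, config)
    b = wf.boundaries

    def resolve(mode, value, clamp, native, bound):
        v = value if mode == "fixed" else native
        if clamp is not None:
            v = min(max(v, clamp[0]), clamp[1])
        return min(max(v, -min(bound, 10.0)), min(bound, 10.0))

    if wf.strategy == "femur_first_measured":
        vv_t = resolve(wf.tibia_vv_mode, wf.tibia_vv_value, wf.tibia_vv_clamp,
                       90.0 - mpta_n, b.max_tibia_vv)
        if not math.isinf(b.max_hka):
            pass  # femoral clamp below handles the limb window
    else:
        vv_t = 0.0
    vv_f = resolve(wf.femur_vv_mode, wf.femur_vv_value, wf.femur_vv_clamp,
                   mldfa_n - 90.0, b.max_femur_vv)
    if wf.strategy == "femur_first_measured" and not math.isinf(b.max_hka):
        vv_f = min(max(vv_f, -b.max_hka - vv_t), b.max_hka - vv_t)
    from kneesim.types import snap

    vv_t, vv_f = snap(vv_t), snap(vv_f)
    med, lat = derive_distal_resections(vv_f, case, config)
    return CutPlan(
        tibia=TibiaPlan(slope=0.0, vv=vv_t, height=0.0),
        femur=FemurPlan(distal_vv=vv_f, distal_res_med=med, distal_res_lat=lat,
                        rotation=snap(wf.rotation_value)),
        release_level=level,
        release_type=rtype,
    )


class TestComparison:
    def test_neutral_case_gives_identical_decisions(self, neutral_case):
        table = compare_workflows(neutral_case, ["MA-TF", "KA"], goal="A")
        decision_rows = table.frame.loc["tibia_slope":"release_level"]
        assert (decision_rows["MA-TF"] == decision_rows["KA"]).all()

    def test_varus_case_tibial_vv_differs_by_native_varus(self, varus_case):
        table = compare_workflows(varus_case, ["MA-TF", "KA"])
        assert table.delta("KA", "MA-TF")["tibia_vv"] == pytest.approx(4.0)

    def test_activation_rule(self, neutral_case):
        with pytest.raises(ComparisonNotActivatedError, match="KA"):
            compare_workflows(neutral_case, ["MA-TF", "KA"], attempted={"MA-TF"})
        # attempted workflows unlock the comparison
        table = compare_workflows(neutral_case, ["MA-TF", "KA"], attempted={"MA-TF", "KA"})
        assert list(table.frame.columns) == ["MA-TF", "KA"]

    def test_needs_two_workflows_and_known_ids(self, neutral_case):
        with pytest.raises(ValueError):
            compare_workflows(neutral_case, ["MA-TF"])
        with pytest.raises(ValueError, match="valid ids"):
            compare_workflows(neutral_case, ["MA-TF", "bogus"])
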