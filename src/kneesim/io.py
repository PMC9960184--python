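"""File round-tripping: cases, plans, session logs, reports, config.

All float output is fixed to one decimal place (the 0.1 decision grid), so
writes are deterministic and loss-free for on-grid values; cartilage (0.5
grid) and times round-trip at the same precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .evaluator import EvaluationReport, TimeRecord
from .types import CartilageMap, CutPlan, FemurPlan, GapState, KneeCase, SimConfig, TibiaPlan

_CART_COLS = [f"cartilage_{s}" for s in (
    "tibia_med", "tibia_lat", "femur_distal_med", "femur_distal_lat",
    "femur_post_med", "femur_post_lat")]
_GAP_COLS = [f"initial_{k}" for k in ("med_ext", "lat_ext", "med_flex", "lat_flex")]

CASE_COLUMNS = (
    ["case_id", "age", "sex", "height", "weight", "hka_dev", "mpta", "mldfa",
     "kl_grade"] + _CART_COLS + ["ffd", "hyperextension"] + _GAP_COLS
)

PLAN_FIELDS = [
    "tibia_slope", "tibia_vv", "tibia_height",
    "femur_distal_vv", "femur_distal_res_med", "femur_distal_res_lat",
    "femur_rotation", "femur_post_res_med", "femur_post_res_lat",
    "femur_flexion", "femur_size_index", "femur_ap_shift",
    "release_type", "release_level",
]

SESSION_COLUMNS = ["case_id", "workflow_id", "goal_id"] + PLAN_FIELDS + [
    "tibia_s", "soft_tissue_s", "femur_s"]


def _f1(v: float) -> float:
    return round(float(v), 1)


class SchemaError(ValueError):
    pass


def case_to_dict(case: KneeCase) -> dict:
    d = {
        "case_id": case.case_id,
        "age": _f1(case.age),
        "sex": case.sex,
        "height": _f1(case.height),
        "weight": _f1(case.weight),
        "hka_dev": _f1(case.hka_dev),
        "mpta": _f1(case.mpta),
        "mldfa": _f1(case.mldfa),
        "kl_grade": int(case.kl_grade),
        "ffd": _f1(case.ffd),
        "hyperextension": _f1(case.hyperextension),
    }
    for name, v in case.cartilage.items():
        d[f"cartilage_{name}"] = _f1(v)
    for k in ("med_ext", "lat_ext", "med_flex", "lat_flex"):
        d[f"initial_{k}"] = _f1(getattr(case.initial_gaps, k))
    return {c: d[c] for c in CASE_COLUMNS}


def case_from_dict(d: dict) -> KneeCase:
    missing = [c for c in CASE_COLUMNS if c not in d]
    if missing:
        raise SchemaError(f"case record missing columns: {', '.join(missing)}")
    return KneeCase(
        case_id=str(d["case_id"]),
        age=float(d["age"]),
        sex=str(d["sex"]),
        height=float(d["height"]),
        weight=float(d["weight"]),
        hka_dev=float(d["hka_dev"]),
        mpta=float(d["mpta"]),
        mldfa=float(d["mldfa"]),
        kl_grade=int(d["kl_grade"]),
        cartilage=CartilageMap(**{c.removeprefix("cartilage_"): float(d[c]) for c in _CART_COLS}),
        ffd=float(d["ffd"]),
        hyperextension=float(d["hyperextension"]),
        initial_gaps=GapState(**{c.removeprefix("initial_"): float(d[c]) for c in _GAP_COLS}),
    )


def save_cases_json(cases: Sequence[KneeCase], path) -> None:
    Path(path).write_text(json.dumps([case_to_dict(c) for c in cases], indent=1) + "\n")


def load_cases_json(path) -> list[KneeCase]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [case_from_dict(d) for d in data]


def save_cases_csv(cases: Sequence[KneeCase], path) -> None:
    pd.DataFrame([case_to_dict(c) for c in cases], columns=CASE_COLUMNS).to_csv(path, index=False)


def load_cases_csv(path) -> list[KneeCase]:
    df = pd.read_csv(path)
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"case file missing columns: {', '.join(missing)}")
    return [case_from_dict(row) for row in df.to_dict("records")]


def load_cases(path) -> list[KneeCase]:
    path = Path(path)
    return load_cases_csv(path) if path.suffix.lower() == ".csv" else load_cases_json(path)


def plan_to_dict(plan: CutPlan) -> dict:
    t, f = plan.tibia, plan.femur
    return {
        "tibia_slope": _f1(t.slope), "tibia_vv": _f1(t.vv), "tibia_height": _f1(t.height),
        "femur_distal_vv": _f1(f.distal_vv),
        "femur_distal_res_med": _f1(f.distal_res_med),
        "femur_distal_res_lat": _f1(f.distal_res_lat),
        "femur_rotation": _f1(f.rotation),
        "femur_post_res_med": _f1(f.post_res_med),
        "femur_post_res_lat": _f1(f.post_res_lat),
        "femur_flexion": _f1(f.flexion),
        "femur_size_index": int(f.size_index),
        "femur_ap_shift": _f1(f.ap_shift),
        "release_type": plan.release_type,
        "release_level": int(plan.release_level),
    }


def plan_from_dict(d: dict) -> CutPlan:
    missing = [c for c in PLAN_FIELDS if c not in d]
    if missing:
        raise SchemaError(f"plan record missing columns: {', '.join(missing)}")
    return CutPlan(
        tibia=TibiaPlan(slope=float(d["tibia_slope"]), vv=float(d["tibia_vv"]),
                        height=float(d["tibia_height"])),
        femur=FemurPlan(
            distal_vv=float(d["femur_distal_vv"]),
            distal_res_med=float(d["femur_distal_res_med"]),
            distal_res_lat=float(d["femur_distal_res_lat"]),
            rotation=float(d["femur_rotation"]),
            post_res_med=float(d["femur_post_res_med"]),
            post_res_lat=float(d["femur_post_res_lat"]),
            flexion=float(d["femur_flexion"]),
            size_index=int(d["femur_size_index"]),
            ap_shift=float(d["femur_ap_shift"]),
        ),
        release_level=int(d["release_level"]),
        release_type=str(d["release_type"]),
    )


def load_session_log(path) -> list[dict]:
    """Trainee session log (CSV or JSON): one entry per exercise with the
    case id, workflow, goal, every plan field and the three subunit times."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        records = pd.read_csv(path).to_dict("records")
    else:
        records = json.loads(path.read_text())
        if isinstance(records, dict):
            records = [records]
    out = []
    for i, rec in enumerate(records):
        missing = [c for c in SESSION_COLUMNS if c not in rec]
        if missing:
            raise SchemaError(f"session log entry {i} missing columns: {', '.join(missing)}")
        out.append(
            {
                "case_id": str(rec["case_id"]),
                "workflow_id": str(rec["workflow_id"]),
                "goal_id": str(rec["goal_id"]),
                "plan": plan_from_dict(rec),
                "time": TimeRecord(
                    tibia_s=float(rec["tibia_s"]),
                    soft_tissue_s=float(rec["soft_tissue_s"]),
                    femur_s=float(rec["femur_s"]),
                ),
            }
        )
    return out


def save_session_log(entries: Sequence[dict], path) -> None:
    rows = []
    for e in entries:
        row = {"case_id": e["case_id"], "workflow_id": e["workflow_id"], "goal_id": e["goal_id"]}
        row.update(plan_to_dict(e["plan"]))
        t = e["time"]
        row.update({"tibia_s": _f1(t.tibia_s), "soft_tissue_s": _f1(t.soft_tissue_s),
                    "femur_s": _f1(t.femur_s)})
        rows.append(row)
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def report_to_dict(report: EvaluationReport) -> dict:
    return {
        "case_id": report.case_id,
        "workflow_id": report.workflow_id,
        "goal_id": report.goal_id,
        "overall": report.overall,
        "passed": report.passed,
        "blue_flag": report.blue_flag,
        "categories": dict(report.categories),
        "subunit_time_colours": dict(report.subunit_time_colours),
        "max_balance_residual": _f1(report.max_balance_residual),
        "hka_trainee": _f1(report.hka_trainee),
        "hka_target": _f1(report.hka_target),
        "total_time_s": _f1(report.total_time_s),
        "deltas": [
            {"field": d.field, "trainee": _f1(d.trainee), "target": _f1(d.target),
             "delta": _f1(d.delta), "colour": d.colour}
            for d in report.deltas
        ],
        "trainee_gaps": {k: _f1(v) for k, v in report.trainee_gaps.model_dump().items()},
        "target_gaps": {k: _f1(v) for k, v in report.target_gaps.model_dump().items()},
    }


def load_config(path) -> SimConfig:
    """YAML config: top-level ``model`` section overrides SimConfig fields,
    ``release_ladders`` supplies override tables."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    fields = dict(data.get("model", {}))
    if "release_ladders" in data:
        fields["release_ladders"] = data["release_ladders"]
    return SimConfig(**fields)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=False) + "\n")


__all__ = [
    "CASE_COLUMNS", "PLAN_FIELDS", "SESSION_COLUMNS", "SchemaError",
    "case_to_dict", "case_from_dict",
    "save_cases_json", "load_cases_json", "save_cases_csv", "load_cases_csv",
    "load_cases", "plan_to_dict", "plan_from_dict",
    "load_session_log", "save_session_log", "report_to_dict",
    "load_config", "dump_json",
]
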