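"""End-to-end validation report.

``run_full_validation`` wires the stages together per analyte: variance
assessment -> model-order selection -> weighted fit -> Hubaux-Vos LOD ->
cyclic accuracy/precision -> LOQ -> matrix effect / recovery / process
efficiency (when spike sets are present) -> stability ANOVA (when stability
records are present).  A stage failure for one analyte is recorded in its
entry without aborting the others.  JSON output is deterministic: keys are
sorted and floats are serialized with 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import math
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from . import calibration as cal
from . import limits as lim
from . import matrix as mx
from . import performance as perf
from . import stability as stab
from .panel import Analyte


def _sig6(value: float) -> float:
    if value == 0 or not math.isfinite(value):
        return value
    return float(f"{value:.6g}")


def _clean(obj: Any) -> Any:
    """Recursively round floats and stringify keys for stable JSON output."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, float):
        return _sig6(obj)
    return obj


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(_clean(config), sort_keys=True).encode()).hexdigest()[:16]


def run_full_validation(
    measurements: pd.DataFrame,
    panel: Iterable[Analyte],
    config: dict | None = None,
) -> dict:
    """Execute every applicable validation stage for every target analyte."""
    config = dict(config or {})
    is_conc = float(config.get("is_concentration", 20.0))
    alpha = float(config.get("lod_alpha", 0.05))
    beta = float(config.get("lod_beta", 0.05))
    targets = [a for a in panel if not a.is_internal_standard]

    report: dict[str, Any] = {
        "metadata": {
            "config_hash": config_hash(config),
            "is_concentration_ng_ml": is_conc,
            "seed": config.get("seed"),
            "n_analytes": len(targets),
        },
        "analytes": {},
    }

    for analyte in targets:
        entry: dict[str, Any] = {"internal_standard": analyte.internal_standard_id}
        try:
            entry.update(_validate_one(measurements, analyte.id, is_conc, alpha, beta))
        except Exception as err:  # per-analyte isolation
            entry["error"] = f"{type(err).__name__}: {err}"
            entry["passed"] = False
        report["analytes"][analyte.id] = entry

    report["metadata"]["n_failed"] = sum(
        1 for e in report["analytes"].values() if not e.get("passed", False)
    )
    return _clean(report)


def _validate_one(
    measurements: pd.DataFrame, analyte_id: str, is_conc: float, alpha: float, beta: float
) -> dict[str, Any]:
    mine = measurements[measurements["analyte_id"] == analyte_id]
    calib = mine[mine["role"] == "calibrator"]
    if calib.empty:
        raise cal.CalibrationError("no calibrator records")

    x, y = cal.ratio_data(calib, is_conc)
    assessment = cal.assess_variance(x, y)
    selection = cal.select_model_order(x, y, assessment.chosen_weighting)
    model = cal.fit_calibration(
        x, y, assessment.chosen_weighting, selection.order,
        analyte_id=analyte_id, is_concentration=is_conc,
    )
    lod = lim.hubaux_vos_lod(
        x, y, assessment.chosen_weighting, alpha=alpha, beta=beta, is_concentration=is_conc
    )
    ap = perf.accuracy_precision_report(
        calib, selection.order, assessment.chosen_weighting, is_conc, analyte_id=analyte_id
    )
    passed, failures = perf.evaluate_acceptance(ap)
    levels = sorted(calib["level_ng_ml"].unique())
    loq = lim.assign_loq(
        levels,
        {lv: (ap.bias_intra[lv], ap.bias_inter[lv]) for lv in levels},
        {lv: (ap.cv_intra[lv], ap.cv_inter[lv]) for lv in levels},
    )

    entry: dict[str, Any] = {
        "calibration": {
            "weighting": model.weighting,
            "order": model.order,
            "coefficients": {"a2": model.a2, "a1": model.a1, "a0": model.a0},
            "residual_sd": model.residual_sd,
            "n": model.n,
            "range_ng_ml": list(model.range_ng_ml),
            "mandel_f": selection.mandel_f,
            "mandel_critical": selection.mandel_critical,
            "lof_p_linear": selection.lof_p_linear,
            "heteroscedastic": assessment.heteroscedastic,
            "variance_power_estimate": assessment.variance_power_estimate,
        },
        "limits": {
            "lod_hubaux_vos_ng_ml": lod,
            "loq_ng_ml": loq,
            "alpha": alpha,
            "beta": beta,
        },
        "accuracy_precision": {
            "bias_intra_pct": ap.bias_intra,
            "bias_inter_pct": ap.bias_inter,
            "cv_intra_pct": ap.cv_intra,
            "cv_inter_pct": ap.cv_inter,
            "mean_bias_intra_pct": ap.mean_bias_intra,
            "mean_bias_inter_pct": ap.mean_bias_inter,
            "mean_cv_intra_pct": ap.mean_cv_intra,
            "mean_cv_inter_pct": ap.mean_cv_inter,
            "failures": failures,
        },
    }

    set1 = mine[mine["role"] == "me_set1"]
    set2 = mine[mine["role"] == "me_set2"]
    set3 = mine[mine["role"] == "me_set3"]
    if not set1.empty and not set2.empty:
        me = mx.matrix_effect(set1, set2)
        section = {
            "me_pct": me.mean_pct,
            "me_rsd_pct": me.rsd_level_pct,
            "ion_enhancement_pct": mx.ion_enhancement(me.mean_pct),
            "classification": mx.classify_matrix_effect(me.mean_pct),
        }
        if not set3.empty:
            er = mx.extraction_recovery(set3, set1)
            section["er_pct"] = er.mean_pct
            section["er_rsd_pct"] = er.rsd_level_pct
            section["pe_pct"] = mx.process_efficiency(me.mean_pct, er.mean_pct)
        entry["matrix_effect"] = section
    else:
        entry["matrix_effect"] = {"status": "not assessed"}

    stab_frame = mine[mine["role"] == "stability"]
    if not stab_frame.empty:
        results = stab.stability_report(stab_frame)
        entry["stability"] = [
            {
                "level_ng_ml": r.level_ng_ml,
                "factor": r.factor,
                "f": r.f_statistic,
                "p": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    else:
        entry["stability"] = {"status": "not assessed"}

    # the validation acceptance criterion is accuracy/precision (plus an
    # assignable LOQ); stability significance is characterized, not gating
    entry["passed"] = bool(passed and loq is not None)
    return entry


def write_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_markdown(report: dict, path: str | Path) -> None:
    lines = ["# Validation report", ""]
    meta = report["metadata"]
    lines += [
        f"- analytes: {meta['n_analytes']} ({meta['n_failed']} failed)",
        f"- IS concentration: {meta['is_concentration_ng_ml']} ng/mL",
        f"- config hash: `{meta['config_hash']}`",
        "",
        "| analyte | model | weighting | LOD (ng/mL) | LOQ (ng/mL) | ME% | ER% | PE% | pass |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    for aid, entry in report["analytes"].items():
        if "error" in entry:
            lines.append(f"| {aid} | error: {entry['error']} | | | | | | | no |")
            continue
        calib = entry["calibration"]
        lim_ = entry["limits"]
        me = entry.get("matrix_effect", {})
        def pct(key):
            return f"{mx.round_percent(me[key])}" if key in me else "-"
        lines.append(
            f"| {aid} | {calib['order']} | {calib['weighting']} "
            f"| {lim_['lod_hubaux_vos_ng_ml']:.2g} | {lim_['loq_ng_ml']} "
            f"| {pct('me_pct')} | {pct('er_pct')} | {pct('pe_pct')} "
            f"| {'yes' if entry['passed'] else 'no'} |"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_schema() -> dict:
    with resources.as_file(resources.files("spotval.data").joinpath("report_schema.json")) as p:
        return json.loads(Path(p).read_text())


def validate_report(report: dict) -> list[str]:
    """Check a report against the shipped schema (minimal structural check:
    required keys and primitive types).  Returns a list of problems."""
    schema = load_schema()
    problems: list[str] = []

    def check(obj, spec, path):
        if spec["type"] == "object":
            if not isinstance(obj, dict):
                problems.append(f"{path}: expected object")
                return
            for key, sub in spec.get("required_properties", {}).items():
                if key not in obj:
                    problems.append(f"{path}.{key}: missing")
                else:
                    check(obj[key], sub, f"{path}.{key}")
            if "additional" in spec:
                for key, value in obj.items():
                    if key not in spec.get("required_properties", {}):
                        check(value, spec["additional"], f"{path}.{key}")
        elif spec["type"] == "number":
            if not isinstance(obj, (int, float)) or isinstance(obj, bool):
                problems.append(f"{path}: expected number, got {type(obj).__name__}")
        elif spec["type"] == "any":
            pass

    check(report, schema, "report")
    return problems
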