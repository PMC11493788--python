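"""Cyclic accuracy and precision evaluation.

Accuracy follows the rotating back-calculation protocol: within each day the
model is rebuilt from all curves but one and the held-out curve is
back-calculated (intra-day); across days the model is rebuilt from two days
and the third day is back-calculated (inter-day).  Bias% per level is
averaged over folds.  Precision is the CV% of back-calculated concentrations,
within-day (averaged over days) or over all replicates of all days.
Acceptance: |bias| <= 20% at every level and CV% strictly below 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import warnings

from .calibration import (
    CalibrationError,
    NonQuantifiableError,
    back_calculate,
    fit_calibration,
    ratio_data,
)


class PerformanceError(ValueError):
    pass


@dataclass
class AccuracyPrecisionReport:
    analyte_id: str
    levels: list[float]
    bias_intra: dict[float, float]
    bias_inter: dict[float, float]
    cv_intra: dict[float, float]
    cv_inter: dict[float, float]
    mean_bias_intra: float = field(init=False)
    mean_bias_inter: float = field(init=False)
    mean_cv_intra: float = field(init=False)
    mean_cv_inter: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_bias_intra = float(np.mean(list(self.bias_intra.values())))
        self.mean_bias_inter = float(np.mean(list(self.bias_inter.values())))
        self.mean_cv_intra = float(np.mean(list(self.cv_intra.values())))
        self.mean_cv_inter = float(np.mean(list(self.cv_inter.values())))


def _fit_fold(frame: pd.DataFrame, order: str, weighting: str, is_concentration: float):
    x, y = ratio_data(frame, is_concentration)
    return fit_calibration(x, y, weighting, order, is_concentration=is_concentration)


def _back_calc_fold(model, y: float) -> float | None:
    """Fold-robust inversion: saturating-model apex overshoot clamps to the
    vertex (the fitted maximum); genuinely non-quantifiable responses are
    dropped with a warning rather than aborting the cyclic procedure."""
    try:
        return back_calculate(model, y, apex_clamp=float("inf"))
    except NonQuantifiableError as err:
        warnings.warn(f"dropping non-quantifiable fold record ({err})")
        return None


def _bias_frame(model, held: pd.DataFrame) -> pd.DataFrame:
    out = []
    for row in held.itertuples(index=False):
        conc = _back_calc_fold(model, row.area_analyte / row.area_is)
        if conc is None:
            continue
        out.append((row.level_ng_ml, 100.0 * (conc - row.level_ng_ml) / row.level_ng_ml))
    return pd.DataFrame(out, columns=["level_ng_ml", "bias_pct"])


def intra_day_accuracy(
    frame: pd.DataFrame, order: str, weighting: str, is_concentration: float = 20.0
) -> dict[float, float]:
    """Per-level bias% from leave-one-curve-out folds within each day."""
    folds = []
    for day, day_frame in frame.groupby("day"):
        curves = sorted(day_frame["curve"].unique())
        if len(curves) < 2:
            raise PerformanceError(f"day {day} has fewer than two curves")
        for held_curve in curves:
            model = _fit_fold(
                day_frame[day_frame["curve"] != held_curve], order, weighting, is_concentration
            )
            folds.append(_bias_frame(model, day_frame[day_frame["curve"] == held_curve]))
    pooled = pd.concat(folds, ignore_index=True)
    return {float(k): float(v) for k, v in pooled.groupby("level_ng_ml")["bias_pct"].mean().items()}


def inter_day_accuracy(
    frame: pd.DataFrame, order: str, weighting: str, is_concentration: float = 20.0
) -> dict[float, float]:
    """Per-level bias% from leave-one-day-out folds."""
    days = sorted(frame["day"].unique())
    if len(days) < 3:
        raise PerformanceError("inter-day accuracy needs at least three days")
    folds = []
    for held_day in days:
        model = _fit_fold(frame[frame["day"] != held_day], order, weighting, is_concentration)
        folds.append(_bias_frame(model, frame[frame["day"] == held_day]))
    pooled = pd.concat(folds, ignore_index=True)
    return {float(k): float(v) for k, v in pooled.groupby("level_ng_ml")["bias_pct"].mean().items()}


def precision_cv(
    frame: pd.DataFrame,
    order: str,
    weighting: str,
    is_concentration: float = 20.0,
    mode: str = "intra",
    on: str = "concentration",
) -> dict[float, float]:
    """Per-level CV%.

    ``mode='intra'``: CV within each day, averaged over days.
    ``mode='inter'``: CV over all replicates pooled across days.
    ``on='concentration'`` computes CVs of back-calculated concentrations
    from a model fitted to all records (reporting scale); ``on='ratio'``
    uses the raw response ratios instead.
    """
    if mode not in ("intra", "inter"):
        raise PerformanceError(f"unknown mode {mode!r}")
    work = frame.copy()
    if on == "concentration":
        model = _fit_fold(frame, order, weighting, is_concentration)
        work["value"] = [
            _back_calc_fold(model, r.area_analyte / r.area_is)
            for r in work.itertuples(index=False)
        ]
        work = work.dropna(subset=["value"])
    elif on == "ratio":
        work["value"] = work["area_analyte"] / work["area_is"]
    else:
        raise PerformanceError(f"unknown precision basis {on!r}")

    def _cv(values: np.ndarray) -> float:
        m = float(np.mean(values))
        if m == 0:
            raise PerformanceError("zero mean; CV undefined")
        return 100.0 * float(np.std(values, ddof=1)) / m

    out: dict[float, float] = {}
    for level, level_frame in work.groupby("level_ng_ml"):
        if mode == "inter":
            out[float(level)] = _cv(level_frame["value"].to_numpy())
        else:
            day_cvs = [
                _cv(day_frame["value"].to_numpy())
                for _, day_frame in level_frame.groupby("day")
                if len(day_frame) >= 2
            ]
            if not day_cvs:
                raise PerformanceError(f"level {level}: no day with >= 2 replicates")
            out[float(level)] = float(np.mean(day_cvs))
    return out


def accuracy_precision_report(
    frame: pd.DataFrame,
    order: str,
    weighting: str,
    is_concentration: float = 20.0,
    analyte_id: str = "",
) -> AccuracyPrecisionReport:
    return AccuracyPrecisionReport(
        analyte_id=analyte_id,
        levels=sorted(float(v) for v in frame["level_ng_ml"].unique()),
        bias_intra=intra_day_accuracy(frame, order, weighting, is_concentration),
        bias_inter=inter_day_accuracy(frame, order, weighting, is_concentration),
        cv_intra=precision_cv(frame, order, weighting, is_concentration, mode="intra"),
        cv_inter=precision_cv(frame, order, weighting, is_concentration, mode="inter"),
    )


def evaluate_acceptance(
    report: AccuracyPrecisionReport, bias_limit: float = 20.0, cv_limit: float = 20.0
) -> tuple[bool, list[str]]:
    """Boundary semantics: |bias| <= limit passes, CV must be strictly below."""
    failures: list[str] = []
    for label, table in (("intra", report.bias_intra), ("inter", report.bias_inter)):
        for level, bias in table.items():
            if abs(bias) > bias_limit:
                failures.append(f"{label}-day bias {bias:+.1f}% at {level:g} ng/mL exceeds +/-{bias_limit:g}%")
    for label, table in (("intra", report.cv_intra), ("inter", report.cv_inter)):
        for level, cv in table.items():
            if not cv < cv_limit:
                failures.append(f"{label}-day CV {cv:.1f}% at {level:g} ng/mL is not below {cv_limit:g}%")
    return (not failures, failures)
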