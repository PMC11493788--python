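"""Weighted calibration on the concentration-ratio scale.

The calibration axes are x = nominal concentration / IS concentration and
y = analyte peak area / IS peak area.  Replicated designs are assessed for
heteroscedasticity, a weighting (none, 1/x or 1/x^2) is chosen from the
empirical variance-vs-concentration power law, model order (linear vs
quadratic) is decided by Mandel's fitting test together with a pure-error
lack-of-fit test, and measured responses are converted back to ng/mL by
inverting the fitted function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

WEIGHTINGS = ("none", "1/x", "1/x2")

#: variance ~ x^k exponent implied by each weighting choice
WEIGHTING_POWER = {"none": 0.0, "1/x": 1.0, "1/x2": 2.0}


class CalibrationError(ValueError):
    """Raised when a calibration cannot be fitted or inverted."""


class NonQuantifiableError(CalibrationError):
    """Back-calculation produced no usable concentration."""


@dataclass
class MeasurementRecord:
    """One injection of one analyte: raw areas plus acquisition metadata."""

    analyte_id: str
    role: str
    day: int
    curve: int
    replicate: int
    level_ng_ml: float
    area_analyte: float
    area_is: float

    def response_ratio(self) -> float:
        if self.area_is <= 0:
            raise CalibrationError(f"non-positive IS area for {self.analyte_id}")
        return self.area_analyte / self.area_is

    def concentration_ratio(self, is_concentration: float) -> float:
        return self.level_ng_ml / is_concentration


def ratio_data(frame: pd.DataFrame, is_concentration: float) -> tuple[np.ndarray, np.ndarray]:
    """Extract (x, y) calibration arrays from a measurement table."""
    area_is = frame["area_is"].to_numpy(float)
    if np.any(area_is <= 0):
        raise CalibrationError("non-positive internal-standard area in records")
    y = frame["area_analyte"].to_numpy(float) / area_is
    x = frame["level_ng_ml"].to_numpy(float) / is_concentration
    return x, y


@dataclass
class VarianceAssessment:
    per_level_variance: list[tuple[float, float]]
    heteroscedastic: bool
    p_value: float
    variance_power_estimate: float
    chosen_weighting: str


@dataclass
class CalibrationModel:
    """A fitted calibration: y = a2*x^2 + a1*x + a0 on the ratio scale."""

    analyte_id: str
    order: str  # "linear" | "quadratic"
    weighting: str
    a2: float
    a1: float
    a0: float
    residual_sd: float  # weighted residual sd (unit-weight scale)
    n: int
    is_concentration: float
    range_ng_ml: tuple[float, float]
    mandel_f: float | None = None
    mandel_critical: float | None = None
    lof_f: float | None = None
    lof_p: float | None = None

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.a2 * np.asarray(x, float) ** 2 + self.a1 * np.asarray(x, float) + self.a0

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a2, self.a1, self.a0)


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x2":
        return 1.0 / x**2
    raise CalibrationError(f"unknown weighting {weighting!r}")


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    """Weighted polynomial LS fit; returns coefficients (const first) and
    the weighted residual sum of squares."""
    X = np.vander(x, degree + 1, increasing=True)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    return beta, float(np.sum(w * resid**2))


def assess_variance(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    power_thresholds: tuple[float, float] = (0.5, 1.5),
) -> VarianceAssessment:
    """Decide homo- vs heteroscedasticity and pick a weighting.

    Heteroscedasticity is tested by a one-sided F-test of the per-level
    variance at the highest level against the lowest level.  The variance
    power is the slope of a df-weighted regression of log(s^2) on log(x);
    weighting is `1/x` when the slope is nearer 1 and `1/x2` when >= 1.5.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    levels = np.unique(x)
    if levels.size < 3:
        raise CalibrationError("need at least three concentration levels")
    per_level: list[tuple[float, float]] = []
    counts = []
    for lv in levels:
        vals = y[x == lv]
        if vals.size < 2:
            raise CalibrationError(f"level {lv} has fewer than two replicates")
        per_level.append((float(lv), float(np.var(vals, ddof=1))))
        counts.append(vals.size)

    s2 = np.array([v for _, v in per_level])
    tiny = (1e-12 * float(np.max(np.abs(y)))) ** 2  # numerical zero on the y scale
    if np.all(s2 <= tiny):
        warnings.warn("zero variance at every level; treating as homoscedastic")
        return VarianceAssessment(per_level, False, 1.0, 0.0, "none")

    n_lo, n_hi = counts[0], counts[-1]
    s2_lo, s2_hi = s2[0], s2[-1]
    if s2_lo <= tiny:
        p_value = 0.0
    else:
        f_stat = s2_hi / s2_lo
        p_value = float(stats.f.sf(f_stat, n_hi - 1, n_lo - 1))
    heteroscedastic = p_value < alpha

    ok = s2 > tiny
    dfs = np.array(counts, float)[ok] - 1.0
    slope = _wpolyfit_slope(np.log(levels[ok]), np.log(s2[ok]), dfs)

    if not heteroscedastic:
        weighting = "none"
    elif slope < power_thresholds[0]:
        weighting = "none"
        heteroscedastic = False
    elif slope < power_thresholds[1]:
        weighting = "1/x"
    else:
        weighting = "1/x2"
    return VarianceAssessment(per_level, heteroscedastic, p_value, float(slope), weighting)


def _wpolyfit_slope(t: np.ndarray, z: np.ndarray, w: np.ndarray) -> float:
    tbar = np.average(t, weights=w)
    zbar = np.average(z, weights=w)
    return float(np.sum(w * (t - tbar) * (z - zbar)) / np.sum(w * (t - tbar) ** 2))


def fit_calibration(
    x: np.ndarray,
    y: np.ndarray,
    weighting: str,
    order: str,
    *,
    analyte_id: str = "",
    is_concentration: float = 20.0,
) -> CalibrationModel:
    """Weighted least-squares fit of the calibration polynomial."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    degree = {"linear": 1, "quadratic": 2}.get(order)
    if degree is None:
        raise CalibrationError(f"unknown order {order!r}")
    if np.unique(x).size < degree + 2:
        raise CalibrationError(f"{order} fit needs at least {degree + 2} distinct levels")
    w = _weights(x, weighting)
    beta, wrss = _wls(x, y, w, degree)
    dof = x.size - (degree + 1)
    residual_sd = float(np.sqrt(wrss / dof)) if dof > 0 else 0.0
    a0, a1 = float(beta[0]), float(beta[1])
    a2 = float(beta[2]) if degree == 2 else 0.0
    return CalibrationModel(
        analyte_id=analyte_id,
        order=order,
        weighting=weighting,
        a2=a2,
        a1=a1,
        a0=a0,
        residual_sd=residual_sd,
        n=int(x.size),
        is_concentration=is_concentration,
        range_ng_ml=(float(x.min() * is_concentration), float(x.max() * is_concentration)),
    )


@dataclass
class OrderSelection:
    order: str
    mandel_f: float
    mandel_critical: float
    mandel_significant: bool
    lof_f_linear: float | None
    lof_p_linear: float | None
    lof_f_quadratic: float | None
    lof_p_quadratic: float | None


def _lack_of_fit(x, y, w, beta, degree) -> tuple[float | None, float | None]:
    """Pure-error lack-of-fit F test for a fitted polynomial (weighted)."""
    levels = np.unique(x)
    n, n_levels, p = x.size, levels.size, degree + 1
    df_pe = n - n_levels
    df_lof = n_levels - p
    if df_pe < 1 or df_lof < 1:
        return None, None
    sse_pe = 0.0
    for lv in levels:
        mask = x == lv
        yl, wl = y[mask], w[mask]
        ybar = np.average(yl, weights=wl)
        sse_pe += float(np.sum(wl * (yl - ybar) ** 2))
    X = np.vander(x, p, increasing=True)
    sse_tot = float(np.sum(w * (y - X @ beta) ** 2))
    sse_lof = max(sse_tot - sse_pe, 0.0)
    tiny = n * (1e-10 * float(np.max(np.abs(np.sqrt(w) * y)))) ** 2
    if sse_pe <= tiny:
        return np.inf if sse_lof > tiny else 0.0, 0.0 if sse_lof > tiny else 1.0
    f_stat = (sse_lof / df_lof) / (sse_pe / df_pe)
    return float(f_stat), float(stats.f.sf(f_stat, df_lof, df_pe))


def select_model_order(
    x: np.ndarray,
    y: np.ndarray,
    weighting: str,
    mandel_alpha: float = 0.01,
    lof_alpha: float = 0.05,
) -> OrderSelection:
    """Choose linear vs quadratic calibration order.

    Mandel's fitting test compares the drop in weighted residual sum of
    squares when the quadratic term is added (F with 1 and n-3 df).  A
    pure-error lack-of-fit test is run for both orders where replication
    allows.  Quadratic is selected iff Mandel is significant, or the linear
    model shows significant lack of fit while the quadratic does not.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 4:
        raise CalibrationError("order selection needs at least four distinct levels")
    w = _weights(x, weighting)
    beta1, sse1 = _wls(x, y, w, 1)
    beta2, sse2 = _wls(x, y, w, 2)
    dof2 = x.size - 3
    tiny = x.size * (1e-10 * float(np.max(np.abs(np.sqrt(w) * y)))) ** 2
    if sse2 <= tiny:
        mandel_f = 0.0 if sse1 <= tiny else np.inf
    else:
        mandel_f = max(sse1 - sse2, 0.0) / (sse2 / dof2)
    mandel_crit = float(stats.f.ppf(1 - mandel_alpha, 1, dof2))
    mandel_sig = bool(mandel_f > mandel_crit)

    lof_f1, lof_p1 = _lack_of_fit(x, y, w, beta1, 1)
    lof_f2, lof_p2 = _lack_of_fit(x, y, w, beta2, 2)
    if lof_p1 is None:
        warnings.warn("no replication for pure error; Mandel test alone decides the order")
        lof_rule = False
    else:
        lin_misfit = lof_p1 < lof_alpha
        quad_ok = lof_p2 is None or lof_p2 >= lof_alpha
        lof_rule = lin_misfit and quad_ok

    order = "quadratic" if (mandel_sig or lof_rule) else "linear"
    return OrderSelection(
        order=order,
        mandel_f=float(mandel_f),
        mandel_critical=mandel_crit,
        mandel_significant=mandel_sig,
        lof_f_linear=lof_f1,
        lof_p_linear=lof_p1,
        lof_f_quadratic=lof_f2,
        lof_p_quadratic=lof_p2,
    )


def back_calculate(
    model: CalibrationModel, y: float, *, rel_tol: float = 1e-9, apex_clamp: float = 0.10
) -> float:
    """Invert the calibration at response ratio ``y``; returns ng/mL.

    Quadratic models are inverted on the monotone branch that covers the
    calibration range (for a2 < 0, the root below the parabola's vertex).
    A response overshooting a saturating model's apex by at most
    ``apex_clamp`` (relative) is clamped to the vertex -- this absorbs
    fold-fit noise in the cyclic accuracy procedure; larger overshoots and
    roots outside [0, 2 x upper range] raise :class:`NonQuantifiableError`.
    """
    if y < 0:
        raise NonQuantifiableError("negative response ratio")
    upper_x = model.range_ng_ml[1] / model.is_concentration
    tol = max(rel_tol * max(upper_x, 1.0), 1e-12)
    if model.order == "linear" or model.a2 == 0.0:
        if model.a1 == 0:
            raise CalibrationError("zero slope; cannot back-calculate")
        root = (y - model.a0) / model.a1
    else:
        disc = model.a1**2 - 4.0 * model.a2 * (model.a0 - y)
        if disc < 0:
            vertex = -model.a1 / (2.0 * model.a2)
            apex = float(model.predict(vertex))
            clampable = (
                model.a2 < 0
                and apex > 0
                and y <= apex * (1.0 + apex_clamp)
                and 0.0 <= vertex <= 2.0 * upper_x + tol
            )
            if clampable:
                return float(vertex * model.is_concentration)
            raise NonQuantifiableError("response outside the attainable range (no real root)")
        sqrt_disc = np.sqrt(disc)
        r1 = (-model.a1 + sqrt_disc) / (2.0 * model.a2)
        r2 = (-model.a1 - sqrt_disc) / (2.0 * model.a2)
        vertex = -model.a1 / (2.0 * model.a2)
        # ascending branch through the calibration range: slope a1 > 0 means
        # x < vertex when a2 < 0, x > vertex when a2 > 0
        candidates = [r for r in (r1, r2) if (r <= vertex if model.a2 < 0 else r >= vertex)]
        if not candidates:
            raise NonQuantifiableError("no root on the monotone calibration branch")
        mid = 0.5 * (model.range_ng_ml[0] + model.range_ng_ml[1]) / model.is_concentration
        root = min(candidates, key=lambda r: abs(r - mid))
    if root < -tol or root > 2.0 * upper_x + tol:
        raise NonQuantifiableError(
            f"back-calculated ratio {root:.4g} outside [0, {2 * upper_x:.4g}]"
        )
    return float(max(root, 0.0) * model.is_concentration)
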