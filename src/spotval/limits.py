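"""Detection and quantification limits.

Two LOD routes are provided: a weighted Hubaux-Vos construction on the four
lowest calibrators (prediction bands of a weighted linear fit, with the
response variance at a candidate concentration extrapolated by the variance
power law implied by the weighting -- the Currie-style correction for
heteroscedastic data), and an extrapolation from a measured chromatographic
signal-to-noise ratio to S/N = 3.  The LOQ is the lowest calibration level
passing the accuracy (|bias| <= 20%) and precision (CV < 20%) criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize, stats

from .calibration import CalibrationError, WEIGHTING_POWER, _weights, _wls


class DetectionLimitError(ValueError):
    pass


@dataclass
class Chromatogram:
    """A single-trace chromatogram on a regular time grid."""

    time: np.ndarray  # minutes
    intensity: np.ndarray  # counts
    peak_window: tuple[float, float]
    noise_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.time.shape != self.intensity.shape:
            raise DetectionLimitError("time and intensity arrays differ in length")
        for lo, hi in (self.peak_window, self.noise_window):
            if not (self.time[0] <= lo < hi <= self.time[-1]):
                raise DetectionLimitError("window outside the acquired time range")
        p, q = sorted([self.peak_window, self.noise_window])
        if p[1] > q[0]:
            raise DetectionLimitError("peak and noise windows overlap")


@dataclass
class DetectionLimits:
    """Per-analyte limits summary."""

    lod_hubaux_vos_ng_ml: float
    loq_ng_ml: float | None
    alpha: float
    beta: float
    n_points_used: int
    lod_sn_ng_ml: float | None = None


def hubaux_vos_lod(
    x: np.ndarray,
    y: np.ndarray,
    weighting: str = "1/x2",
    alpha: float = 0.05,
    beta: float = 0.05,
    is_concentration: float = 20.0,
    n_lowest_levels: int = 4,
) -> float:
    """Hubaux-Vos detection limit from the low calibrators, in ng/mL.

    A weighted straight line is fitted to the ``n_lowest_levels`` lowest
    distinct levels.  The decision threshold y_c is the upper (1-alpha)
    prediction bound of a blank (x = 0); the LOD is the smallest x whose
    lower (1-beta) prediction bound reaches y_c.  Prediction variance at x
    is s^2 * (x^k + leverage(x)) where k is the variance power implied by
    the weighting (k = 0 for unweighted), i.e. the single-measurement
    variance is extrapolated along the fitted power law.
    """
    if not 0 < alpha < 0.5 or not 0 < beta < 0.5:
        raise DetectionLimitError("alpha and beta must lie in (0, 0.5)")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    levels = np.unique(x)
    if levels.size < n_lowest_levels:
        raise DetectionLimitError(f"need at least {n_lowest_levels} distinct levels")
    keep = np.isin(x, levels[:n_lowest_levels])
    x, y = x[keep], y[keep]

    w = _weights(x, weighting)
    beta_hat, wrss = _wls(x, y, w, 1)
    a0, a1 = float(beta_hat[0]), float(beta_hat[1])
    if a1 <= 0:
        raise DetectionLimitError("non-positive calibration slope: no detection capability")
    dof = x.size - 2
    s2 = wrss / dof
    if s2 <= 0:
        return 0.0

    k = WEIGHTING_POWER[weighting]
    X = np.vander(x, 2, increasing=True)
    xtwx_inv = np.linalg.inv(X.T @ (w[:, None] * X))

    def leverage(x0: float) -> float:
        v = np.array([1.0, x0])
        return float(v @ xtwx_inv @ v)

    def pred_sd(x0: float) -> float:
        meas_var = 1.0 if k == 0 else x0**k
        return float(np.sqrt(s2 * (meas_var + leverage(x0))))

    t_a = float(stats.t.ppf(1 - alpha, dof))
    t_b = float(stats.t.ppf(1 - beta, dof))
    y_c = a0 + t_a * pred_sd(0.0)

    def gap(x0: float) -> float:
        # lower (1-beta) prediction bound at x0 minus the decision threshold
        return (a0 + a1 * x0 - t_b * pred_sd(x0)) - y_c

    hi = float(x.max())
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6 * x.max():
            raise DetectionLimitError("prediction bands never separate; LOD undefined")
    x_d = float(optimize.brentq(gap, 0.0, hi, xtol=1e-12, rtol=1e-12))
    return x_d * is_concentration


def measure_sn(chrom: Chromatogram) -> float:
    """Signal-to-noise: (peak max - noise median) / noise sd (RMS convention)."""
    t = chrom.time
    peak = chrom.intensity[(t >= chrom.peak_window[0]) & (t <= chrom.peak_window[1])]
    noise = chrom.intensity[(t >= chrom.noise_window[0]) & (t <= chrom.noise_window[1])]
    if peak.size == 0 or noise.size < 2:
        raise DetectionLimitError("empty peak or noise window")
    noise_sd = float(np.std(noise, ddof=1))
    if noise_sd == 0:
        raise DetectionLimitError("noiseless trace: S/N undefined")
    return float((peak.max() - np.median(noise)) / noise_sd)


def extrapolate_lod_sn(sn_measured: float, conc_ng_ml: float) -> float:
    """Concentration at which S/N would reach 3, assuming proportionality."""
    if sn_measured <= 0:
        raise DetectionLimitError("measured S/N must be positive")
    if conc_ng_ml <= 0:
        raise DetectionLimitError("concentration must be positive")
    return 3.0 * conc_ng_ml / sn_measured


def mean_lod_sn(sn_values: Iterable[float], conc_ng_ml: float) -> float:
    """Average the per-replicate S/N-extrapolated LODs."""
    lods = [extrapolate_lod_sn(sn, conc_ng_ml) for sn in sn_values]
    if not lods:
        raise DetectionLimitError("no S/N replicates supplied")
    return float(np.mean(lods))


def assign_loq(
    levels: Iterable[float],
    bias_by_level: Mapping[float, float | Iterable[float]],
    cv_by_level: Mapping[float, float | Iterable[float]],
    bias_limit: float = 20.0,
    cv_limit: float = 20.0,
) -> float | None:
    """Lowest level with |bias| <= bias_limit and CV < cv_limit (strict).

    Mapping values may be scalars or iterables (e.g. intra- and inter-day
    figures together); every entry must pass.  Returns None when no level
    qualifies.
    """
    for level in sorted(levels):
        biases = _as_tuple(bias_by_level[level])
        cvs = _as_tuple(cv_by_level[level])
        if all(abs(b) <= bias_limit for b in biases) and all(c < cv_limit for c in cvs):
            return float(level)
    return None


def _as_tuple(value) -> tuple[float, ...]:
    if np.isscalar(value):
        return (float(value),)
    return tuple(float(v) for v in value)
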