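"""Synthetic dataset generator.

Every data shape the validation pipeline consumes can be generated here with
a known generative truth: replicated multi-day calibration curves with a
configurable variance power law, matrix-effect / recovery spike sets, storage
stability grids, full-factorial extraction-optimization responses, and
Gaussian-peak chromatograms for signal-to-noise work.

Noise model: multiplicative, mean-one log-normal on the response-ratio scale
(ratios stay positive), with the per-point CV chosen so that
sd(y at x) = base_cv * truth(1) * x^(k/2), i.e. var(y) grows as x^k.  Day
effects are a shared mean-one log-normal factor per day.  All randomness
derives from one global seed; each generator draws from a child stream keyed
by a purpose label, so datasets are independent and reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .limits import Chromatogram

MEASUREMENT_COLUMNS = [
    "analyte_id",
    "role",
    "day",
    "curve",
    "replicate",
    "level_ng_ml",
    "temp_c",
    "time_d",
    "run_id",
    "added_ng_ml",
    "area_analyte",
    "area_is",
]

#: nominal IS peak area used to materialize response ratios as area pairs
IS_AREA = 1.0e5


class SimulationError(ValueError):
    pass


@dataclass
class AnalyteTruth:
    """Generative truth for one analyte on the (x, y) ratio scale."""

    order: str = "linear"  # "linear" | "quadratic"
    a2: float = 0.0
    a1: float = 1.0
    a0: float = 0.0
    variance_power: float = 2.0  # k in var(y) ~ x^k
    base_cv: float = 0.08

    def __post_init__(self) -> None:
        if self.order not in ("linear", "quadratic"):
            raise SimulationError(f"unknown order {self.order!r}")
        if self.order == "linear" and self.a2 != 0.0:
            raise SimulationError("linear truth must have a2 = 0")
        if self.base_cv < 0:
            raise SimulationError("base_cv must be non-negative")

    def value(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, float)
        return self.a2 * x**2 + self.a1 * x + self.a0


@dataclass
class SyntheticConfig:
    """Full generative configuration for one synthetic study."""

    levels: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
    curves_per_day: int = 3
    days: int = 3
    is_concentration: float = 20.0
    truth: dict[str, AnalyteTruth] = field(default_factory=dict)
    day_effect_sd: float = 0.0
    me_multiplier: float = 1.28
    er_multiplier: float = 0.93
    seed: int = 0

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, float)
        if lv.size < 2 or np.any(lv <= 0) or np.any(np.diff(lv) <= 0):
            raise SimulationError("levels must be strictly increasing and positive")
        if self.curves_per_day < 1 or self.days < 1:
            raise SimulationError("counts must be positive")
        if self.is_concentration <= 0:
            raise SimulationError("is_concentration must be positive")
        if self.me_multiplier <= 0 or self.er_multiplier <= 0:
            raise SimulationError("effect multipliers must be positive")
        if self.day_effect_sd < 0:
            raise SimulationError("day_effect_sd must be non-negative")
        if not self.truth:
            self.truth = {"A1": AnalyteTruth()}


def default_truth_panel(base_cv: float = 0.08, variance_power: float = 2.0) -> dict[str, AnalyteTruth]:
    """Panel-wide truth built from the packaged reference calibration fixture
    (20 linear and 5 quadratic response functions)."""
    with resources.as_file(
        resources.files("spotval.data").joinpath("calibration_reference.csv")
    ) as p:
        ref = pd.read_csv(p)
    truth = {}
    for row in ref.itertuples(index=False):
        truth[row.analyte_id] = AnalyteTruth(
            order=row.model,
            a2=float(row.a2),
            a1=float(row.a1),
            a0=float(row.a0),
            variance_power=variance_power,
            base_cv=base_cv,
        )
    return truth


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _lognormal_factor(rng: np.random.Generator, cv: np.ndarray | float, size=None) -> np.ndarray:
    """Mean-one multiplicative noise with the requested coefficient of variation."""
    cv = np.asarray(cv, float)
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.standard_normal(size if size is not None else cv.shape)
    return np.exp(sigma * z - 0.5 * sigma**2)


def _point_cv(truth: AnalyteTruth, x: np.ndarray) -> np.ndarray:
    """CV at x such that sd(y) = base_cv * truth(1) * x^(k/2)."""
    mu = np.asarray(truth.value(x), float)
    if np.any(mu <= 0):
        raise SimulationError("truth curve non-positive inside the calibration range")
    sd = truth.base_cv * float(truth.value(1.0)) * np.asarray(x, float) ** (truth.variance_power / 2.0)
    return sd / mu


def _empty_frame(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "analyte_id": pd.Series([""] * n, dtype=object),
            "role": pd.Series([""] * n, dtype=object),
            "day": np.zeros(n, dtype=int),
            "curve": np.zeros(n, dtype=int),
            "replicate": np.zeros(n, dtype=int),
            "level_ng_ml": np.zeros(n),
            "temp_c": np.full(n, np.nan),
            "time_d": np.full(n, np.nan),
            "run_id": np.zeros(n, dtype=int),
            "added_ng_ml": np.full(n, np.nan),
            "area_analyte": np.zeros(n),
            "area_is": np.full(n, IS_AREA),
        }
    )


def generate_calibration(config: SyntheticConfig) -> pd.DataFrame:
    """Replicated calibration records: one row per (analyte, level, curve, day)."""
    rng = _rng(config.seed, "calibration")
    levels = np.asarray(config.levels, float)
    x = levels / config.is_concentration
    rows = []
    day_factors = {
        day: float(_lognormal_factor(rng, config.day_effect_sd, size=()))
        if config.day_effect_sd > 0
        else 1.0
        for day in range(1, config.days + 1)
    }
    for analyte_id, truth in config.truth.items():
        cv = _point_cv(truth, x)
        mu = np.asarray(truth.value(x), float)
        for day in range(1, config.days + 1):
            for curve in range(1, config.curves_per_day + 1):
                noise = _lognormal_factor(rng, cv) if truth.base_cv > 0 else np.ones_like(mu)
                y = mu * day_factors[day] * noise
                frame = _empty_frame(levels.size)
                frame["analyte_id"] = analyte_id
                frame["role"] = "calibrator"
                frame["day"] = day
                frame["curve"] = curve
                frame["replicate"] = curve
                frame["level_ng_ml"] = levels
                frame["area_analyte"] = y * IS_AREA
                rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def generate_me_er_sets(
    config: SyntheticConfig,
    qc_levels: Sequence[float] = (2.0, 15.0, 75.0),
    replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spike sets for the matrix-effect / recovery decomposition.

    set 2 is the neat (matrix-free) response, set 1 multiplies it by the ion
    enhancement factor, set 3 additionally applies the extraction recovery.
    """
    rng = _rng(config.seed, "me_er")
    x = np.asarray(qc_levels, float) / config.is_concentration
    sets: dict[str, list[pd.DataFrame]] = {"me_set1": [], "me_set2": [], "me_set3": []}
    multipliers = {
        "me_set2": 1.0,
        "me_set1": config.me_multiplier,
        "me_set3": config.me_multiplier * config.er_multiplier,
    }
    for analyte_id, truth in config.truth.items():
        mu_neat = np.asarray(truth.value(x), float)
        for role in ("me_set1", "me_set2", "me_set3"):
            for rep in range(1, replicates + 1):
                noise = (
                    _lognormal_factor(rng, np.full(x.size, truth.base_cv))
                    if truth.base_cv > 0
                    else np.ones_like(mu_neat)
                )
                y = mu_neat * multipliers[role] * noise
                frame = _empty_frame(x.size)
                frame["analyte_id"] = analyte_id
                frame["role"] = role
                frame["replicate"] = rep
                frame["level_ng_ml"] = np.asarray(qc_levels, float)
                frame["area_analyte"] = y * IS_AREA
                sets[role].append(frame)
    return tuple(pd.concat(sets[r], ignore_index=True) for r in ("me_set1", "me_set2", "me_set3"))


def generate_stability(
    config: SyntheticConfig,
    temps: Sequence[float] = (-20.0, 4.0, 25.0),
    times: Sequence[float] = (1.0, 14.0, 28.0),
    concs: Sequence[float] = (2.0, 75.0),
    replicates: int = 3,
    degradation_rate: float | Mapping[float, float] = 0.0,
) -> pd.DataFrame:
    """Storage-stability grid; responses decay exponentially per day at the
    temperature-specific degradation rate (0 everywhere in the stable scenario)."""
    rng = _rng(config.seed, "stability")
    rows = []
    for analyte_id, truth in config.truth.items():
        for conc in concs:
            x = conc / config.is_concentration
            mu0 = float(truth.value(x))
            for temp in temps:
                rate = (
                    float(degradation_rate.get(temp, 0.0))
                    if isinstance(degradation_rate, Mapping)
                    else float(degradation_rate)
                )
                for t in times:
                    decay = np.exp(-rate * t)
                    for rep in range(1, replicates + 1):
                        noise = (
                            float(_lognormal_factor(rng, truth.base_cv, size=()))
                            if truth.base_cv > 0
                            else 1.0
                        )
                        frame = _empty_frame(1)
                        frame["analyte_id"] = analyte_id
                        frame["role"] = "stability"
                        frame["replicate"] = rep
                        frame["level_ng_ml"] = conc
                        frame["temp_c"] = temp
                        frame["time_d"] = t
                        frame["area_analyte"] = mu0 * decay * noise * IS_AREA
                        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


@dataclass
class DoeEffects:
    """Linear effect model for DoE responses on coded factors."""

    intercept: float = 1.0
    beta_volume: float = 0.0
    beta_time: float = 0.0
    beta_interaction: float = 0.0
    noise_sd: float = 0.0


def generate_doe_responses(
    design,
    effects: DoeEffects,
    analyte_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Response matrix (runs x analytes) for a factorial design.

    ``design`` is a :class:`spotval.doe.FactorialDesign` with coded columns
    ``coded_volume`` and ``coded_time``.
    """
    rng = _rng(seed, "doe")
    if analyte_ids is None:
        analyte_ids = [f"A{i}" for i in range(1, 26)]
    runs = design.runs
    cv = runs["coded_volume"].to_numpy(float)
    ct = runs["coded_time"].to_numpy(float)
    mu = (
        effects.intercept
        + effects.beta_volume * cv
        + effects.beta_time * ct
        + effects.beta_interaction * cv * ct
    )
    data = {}
    for aid in analyte_ids:
        noise = rng.normal(0.0, effects.noise_sd, size=mu.size) if effects.noise_sd > 0 else 0.0
        data[aid] = mu + noise
    return pd.DataFrame(data, index=runs["run_id"].to_numpy())


@dataclass
class ChromatogramConfig:
    peak_center: float = 6.0  # minutes
    peak_sigma: float = 0.05
    height_per_unit_conc: float = 1000.0  # counts per ng/mL
    baseline_noise_sd: float = 25.0
    sampling_rate: float = 600.0  # points per minute
    duration: float = 13.0

    def __post_init__(self) -> None:
        if self.peak_sigma <= 0 or self.baseline_noise_sd < 0:
            raise SimulationError("invalid chromatogram parameters")
        if not (self.peak_center - 4 * self.peak_sigma >= 0 and self.peak_center + 4 * self.peak_sigma <= self.duration):
            raise SimulationError("duration must cover peak_center +/- 4 sigma")


def generate_chromatogram(cc: ChromatogramConfig, conc_ng_ml: float, seed: int = 0) -> Chromatogram:
    """Gaussian peak over i.i.d. Gaussian baseline noise on a regular grid."""
    rng = _rng(seed, "chromatogram")
    n = int(round(cc.duration * cc.sampling_rate)) + 1
    t = np.linspace(0.0, cc.duration, n)
    peak = cc.height_per_unit_conc * conc_ng_ml * np.exp(
        -0.5 * ((t - cc.peak_center) / cc.peak_sigma) ** 2
    )
    noise = rng.normal(0.0, cc.baseline_noise_sd, size=n) if cc.baseline_noise_sd > 0 else 0.0
    half = 4 * cc.peak_sigma
    noise_end = max(cc.peak_center - 8 * cc.peak_sigma, 0.0)
    return Chromatogram(
        time=t,
        intensity=peak + noise,
        peak_window=(cc.peak_center - half, cc.peak_center + half),
        noise_window=(0.0, noise_end),
    )


def write_measurements(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def read_measurements(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise SimulationError(f"measurements file missing columns: {sorted(missing)}")
    return frame


def config_to_yaml(config: SyntheticConfig, path: str | Path) -> None:
    doc = asdict(config)
    doc["levels"] = list(doc["levels"])
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    truth = {k: AnalyteTruth(**v) for k, v in doc.pop("truth", {}).items()}
    levels = tuple(doc.pop("levels", (2.0, 5.0, 10.0, 20.0, 50.0, 100.0)))
    return SyntheticConfig(levels=levels, truth=truth, **doc)
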