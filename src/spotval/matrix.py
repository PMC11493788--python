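"""Matrix effect, extraction recovery, process efficiency and the
standard-addition fallback quantification.

The three-set spike design: set 1 = blank matrix spiked after extraction,
set 2 = matrix-free (neat) spike, set 3 = matrix spiked before extraction.
ME% compares set 1 to set 2, ER% compares set 3 to set 1, and PE% is their
product / 100.  Percentages are kept unrounded internally; display rounding
is integer percent, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

ACCEPTABLE_WINDOW = (85.0, 115.0)

#: classification bounds on ME% (ion enhancement = ME% - 100)
CLASS_BOUNDS = {
    "suppression": (0.0, 85.0),
    "acceptable": (85.0, 125.0),
    "moderate enhancement": (125.0, 150.0),
    "substantial enhancement": (150.0, np.inf),
}


class MatrixEffectError(ValueError):
    pass


@dataclass
class RatioComparison:
    """ME% or ER% result: per-level percentages plus summary statistics."""

    per_level_pct: dict[float, float]
    mean_pct: float
    rsd_level_pct: float  # RSD of the per-level means
    rsd_replicate_pct: float  # pooled RSD of per-replicate ratios about their level mean
    acceptable: bool


def _ratios(frame: pd.DataFrame) -> pd.Series:
    return frame["area_analyte"] / frame["area_is"]


def _compare_sets(numerator: pd.DataFrame, denominator: pd.DataFrame) -> RatioComparison:
    levels_num = set(numerator["level_ng_ml"].unique())
    levels_den = set(denominator["level_ng_ml"].unique())
    if levels_num != levels_den:
        raise MatrixEffectError(f"level mismatch between sets: {levels_num} vs {levels_den}")
    per_level: dict[float, float] = {}
    rep_pcts: list[np.ndarray] = []
    for level in sorted(levels_num):
        num = _ratios(numerator[numerator["level_ng_ml"] == level]).to_numpy()
        den = _ratios(denominator[denominator["level_ng_ml"] == level]).to_numpy()
        if num.size < 2 or den.size < 2:
            raise MatrixEffectError(f"level {level}: need >= 2 replicates in both sets")
        den_mean = float(np.mean(den))
        if den_mean == 0:
            raise MatrixEffectError(f"level {level}: zero denominator mean")
        per_level[float(level)] = 100.0 * float(np.mean(num)) / den_mean
        rep_pcts.append(100.0 * num / den_mean)
    means = np.array(list(per_level.values()))
    mean_pct = float(np.mean(means))
    rsd_level = 100.0 * float(np.std(means, ddof=1)) / mean_pct if means.size > 1 else 0.0
    pooled = np.concatenate(rep_pcts)
    centred = np.concatenate([p - np.mean(p) for p in rep_pcts])
    rsd_rep = 100.0 * float(np.sqrt(np.sum(centred**2) / (pooled.size - len(rep_pcts)))) / mean_pct
    acceptable = ACCEPTABLE_WINDOW[0] <= mean_pct <= ACCEPTABLE_WINDOW[1]
    return RatioComparison(per_level, mean_pct, rsd_level, rsd_rep, acceptable)


def matrix_effect(set1: pd.DataFrame, set2: pd.DataFrame) -> RatioComparison:
    """ME% = 100 x mean(set 1 response ratios) / mean(set 2) per level."""
    return _compare_sets(set1, set2)


def extraction_recovery(set3: pd.DataFrame, set1: pd.DataFrame) -> RatioComparison:
    """ER% = 100 x mean(set 3 response ratios) / mean(set 1) per level."""
    return _compare_sets(set3, set1)


def process_efficiency(me_pct: float, er_pct: float) -> float:
    """PE% = ME% x ER% / 100 (commutative, computed before any rounding)."""
    if me_pct <= 0 or er_pct <= 0:
        raise MatrixEffectError("ME% and ER% must be positive")
    return me_pct * er_pct / 100.0


def ion_enhancement(me_pct: float) -> float:
    return me_pct - 100.0


def classify_matrix_effect(me_pct: float) -> str:
    """Bucket an ME% value: suppression below the acceptability window,
    moderate enhancement for +25% < IE <= +50%, substantial above +50%."""
    if me_pct <= 0:
        raise MatrixEffectError("ME% must be positive")
    for label, (lo, hi) in CLASS_BOUNDS.items():
        if lo <= me_pct < hi:
            return label
    raise MatrixEffectError(f"unclassifiable ME% {me_pct}")  # pragma: no cover


def round_percent(value: float) -> int:
    """Integer percent, round half away from zero (display convention)."""
    return int(np.floor(abs(value) + 0.5) * np.sign(value))


def standard_addition_quantify(
    added_ng_ml: Sequence[float], response_ratio: Sequence[float]
) -> float:
    """Intrinsic concentration by standard addition: |x-intercept| of the
    unweighted response-vs-added line (a0/a1)."""
    added = np.asarray(added_ng_ml, float)
    resp = np.asarray(response_ratio, float)
    if added.size != resp.size or added.size < 3:
        raise MatrixEffectError("need >= 3 matched (addition, response) points")
    if 0.0 not in added:
        raise MatrixEffectError("a zero-addition point is required")
    X = np.vander(added, 2, increasing=True)
    (a0, a1), *_ = np.linalg.lstsq(X, resp, rcond=None)
    if a1 <= 0:
        raise MatrixEffectError("non-positive standard-addition slope")
    c0 = a0 / a1
    if c0 < -0.05 * float(added.max()):
        raise MatrixEffectError(f"extrapolated concentration {c0:.3g} ng/mL is negative")
    return float(max(c0, 0.0))


def load_matrix_reference() -> pd.DataFrame:
    """Packaged per-analyte ME%/ER% reference table (with RSDs), to which the
    PE% and ion-enhancement identities can be applied as a fixture."""
    with resources.as_file(
        resources.files("spotval.data").joinpath("matrix_effect_reference.csv")
    ) as p:
        return pd.read_csv(p)
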