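"""Storage-stability assessment by analysis of variance.

Each (analyte, concentration) cell of the stability grid is tested
separately: a one-way ANOVA on the response ratio against either storage
temperature or storage time, pooling over the other factor, significant at
p < 0.05.  A two-way ANOVA with interaction is available as an option, as is
a Bonferroni correction across analytes (both off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FACTOR_COLUMNS = {"temperature": "temp_c", "time": "time_d"}


class StabilityError(ValueError):
    pass


@dataclass
class StabilityResult:
    analyte_id: str
    level_ng_ml: float
    factor: str
    f_statistic: float
    p_value: float
    significant: bool
    group_means: dict[float, float]


def stability_anova(
    frame: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
    analyte_id: str = "",
    level_ng_ml: float = float("nan"),
) -> StabilityResult:
    """One-way ANOVA of response ratios over one storage factor."""
    if factor not in FACTOR_COLUMNS:
        raise StabilityError(f"unknown factor {factor!r}; use 'temperature' or 'time'")
    col = FACTOR_COLUMNS[factor]
    ratios = frame["area_analyte"] / frame["area_is"]
    groups = [g.to_numpy() for _, g in ratios.groupby(frame[col])]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise StabilityError("need >= 2 groups with >= 2 replicates each")
    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        warnings.warn("all observations identical; reporting F = 0")
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = stats.f_oneway(*groups)
    means = {
        float(k): float(np.mean(g.to_numpy())) for k, g in ratios.groupby(frame[col])
    }
    return StabilityResult(
        analyte_id=analyte_id,
        level_ng_ml=float(level_ng_ml),
        factor=factor,
        f_statistic=float(f_stat),
        p_value=float(p_value),
        significant=bool(p_value < alpha),
        group_means=means,
    )


def stability_report(
    frame: pd.DataFrame, alpha: float = 0.05, bonferroni: bool = False
) -> list[StabilityResult]:
    """Per (analyte, concentration) one-way ANOVAs for both storage factors."""
    cells = list(frame.groupby(["analyte_id", "level_ng_ml"]))
    adj_alpha = alpha / len(cells) if bonferroni and cells else alpha
    results = []
    for (analyte_id, level), cell in cells:
        for factor in ("temperature", "time"):
            results.append(
                stability_anova(
                    cell, factor, alpha=adj_alpha, analyte_id=analyte_id, level_ng_ml=level
                )
            )
    return results


def two_way_anova(frame: pd.DataFrame) -> pd.DataFrame:
    """Optional two-way ANOVA (temperature x time with interaction)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    work = frame.copy()
    work["ratio"] = work["area_analyte"] / work["area_is"]
    model = ols("ratio ~ C(temp_c) * C(time_d)", data=work).fit()
    return sm.stats.anova_lm(model, typ=2)
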