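"""Design-of-experiments support for the extraction optimization.

A full-factorial design over extraction-solvent volume and sonication time
(3 x 3 by default), principal component analysis of the runs x analytes
response matrix, and multiple linear regression of the PC1 scores on the
orthogonally coded factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


class DesignError(ValueError):
    pass


DEFAULT_FACTORS = (("volume", (250.0, 500.0, 750.0)), ("time", (10.0, 20.0, 30.0)))


def code_levels(levels: Sequence[float]) -> dict[float, float]:
    """Map physical levels to the [-1, +1] orthogonal coding."""
    lo, hi = min(levels), max(levels)
    if hi == lo:
        raise DesignError("factor levels are all identical")
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    return {float(v): (float(v) - mid) / half for v in levels}


@dataclass
class FactorialDesign:
    factors: list[tuple[str, tuple[float, ...]]]
    runs: pd.DataFrame  # run_id, <factor>, coded_<factor>, in randomized order

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def full_factorial(
    factors: Sequence[tuple[str, Sequence[float]]] = DEFAULT_FACTORS,
    seed: int | None = None,
) -> FactorialDesign:
    """Cartesian product of factor levels; run order shuffled under ``seed``
    (``None`` keeps the standard order)."""
    factors = [(name, tuple(float(v) for v in levels)) for name, levels in factors]
    if not factors or any(len(levels) < 2 for _, levels in factors):
        raise DesignError("each factor needs at least two levels")
    codings = {name: code_levels(levels) for name, levels in factors}
    rows = []
    for run_id, combo in enumerate(product(*(levels for _, levels in factors)), start=1):
        row: dict[str, float] = {"run_id": run_id}
        for (name, _), value in zip(factors, combo):
            row[name] = value
            row[f"coded_{name}"] = codings[name][value]
        rows.append(row)
    runs = pd.DataFrame(rows)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(runs))
        runs = runs.iloc[order].reset_index(drop=True)
    return FactorialDesign(factors=factors, runs=runs)


@dataclass
class PcaResult:
    scores: np.ndarray  # runs x components
    loadings: np.ndarray  # variables x components (orthonormal columns)
    explained_variance_ratio: np.ndarray
    scaling: str
    column_means: np.ndarray
    column_scales: np.ndarray
    columns: list[str]

    def reconstruct(self) -> np.ndarray:
        """Scaled data matrix rebuilt from all retained components."""
        return self.scores @ self.loadings.T


def pca_decompose(matrix: pd.DataFrame | np.ndarray, scaling: str = "autoscale") -> PcaResult:
    """PCA of a runs x variables matrix after centering (and unit-variance
    scaling when ``scaling='autoscale'``, the chemometric default).

    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive.
    """
    if isinstance(matrix, pd.DataFrame):
        columns = [str(c) for c in matrix.columns]
        X = matrix.to_numpy(float)
    else:
        X = np.asarray(matrix, float)
        columns = [f"v{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DesignError("PCA needs a matrix with at least 2 rows and 2 columns")
    if np.isnan(X).any():
        raise DesignError("PCA input contains missing values")
    means = X.mean(axis=0)
    if scaling == "autoscale":
        scales = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(scales == 0)
        if dead.size:
            raise DesignError(f"constant column(s) under autoscaling: {[columns[i] for i in dead]}")
    elif scaling == "center":
        scales = np.ones(X.shape[1])
    else:
        raise DesignError(f"unknown scaling {scaling!r}")
    Z = (X - means) / scales

    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Z @ loadings
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr,
        scaling=scaling,
        column_means=means,
        column_scales=scales,
        columns=columns,
    )


@dataclass
class MlrResult:
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    r_squared: float


def mlr_fit(
    pc1_scores: np.ndarray,
    design: FactorialDesign,
    include_interaction: bool = True,
) -> MlrResult:
    """OLS of PC1 scores on the coded factors (optionally their interaction)."""
    runs = design.runs
    y = np.asarray(pc1_scores, float)
    if y.size != len(runs):
        raise DesignError("response length does not match the design")
    names = [name for name, _ in design.factors]
    X = pd.DataFrame({name: runs[f"coded_{name}"].to_numpy(float) for name in names})
    if include_interaction and len(names) >= 2:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                X[f"{names[i]}:{names[j]}"] = X[names[i]] * X[names[j]]
    X = sm.add_constant(X)
    n_params = X.shape[1]
    if len(runs) < n_params + 1:
        raise DesignError("design has too few runs for the requested model")
    if np.linalg.matrix_rank(X.to_numpy()) < n_params:
        raise DesignError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    return MlrResult(
        coefficients=fit.params,
        std_errors=fit.bse,
        p_values=fit.pvalues,
        r_squared=float(fit.rsquared),
    )
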