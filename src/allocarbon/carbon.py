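"""Carbon-stock estimation and the four-method comparison.

Observed carbon of a component is its oven-dry biomass times its
measured carbon concentration.  Predicted carbon comes from one of four
strategies, each evaluated on leave-one-out predictions so no tree is
predicted by a model that saw it:

* Method 1 (direct): the compatible carbon-stock system (CM3) predicts
  component carbon from D.
* Method 2: compatible biomass system (BM1) predictions × the generic
  conversion factor 0.5.
* Method 3: biomass predictions × the mean whole-tree carbon
  concentration of the sample.
* Method 4: biomass predictions × the mean concentration of each
  component.

Comparison statistic: the relative root mean squared error

    RMSE_rc = sqrt( Σ (C_i − Ĉ_i)² / (n − p) ) / mean(Ĉ) × 100  (%)

with p = 8 system parameters.  For the indirect methods the same value
can be written purely in biomass terms (observed biomass rescaled by
concentration/factor against predicted biomass); both routes are
implemented and agree algebraically.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .allometry import COMPONENTS, ComponentVector
from .data import carbon_matrix, concentration_matrix, total_biomass, total_carbon
from .validation import N_SYSTEM_PARAMS, JackknifeResult

__all__ = [
    "FactorKind",
    "ConversionFactors",
    "METHOD_NAMES",
    "observed_carbon",
    "mean_concentrations",
    "conversion_factors_for_method",
    "predict_carbon_by_method",
    "method_error_matrix",
    "rmse_r",
    "rmse_rc",
    "rmse_rc_indirect",
    "rmse_rc_table",
    "bootstrap_rmse_rc",
]

SERIES = COMPONENTS + ("total",)

METHOD_NAMES = {
    1: "direct carbon model",
    2: "biomass x 0.5",
    3: "biomass x tree-mean concentration",
    4: "biomass x component-mean concentrations",
}


class FactorKind(str, Enum):
    FACTOR_05 = "factor_05"
    TREE_MEAN = "tree_mean"
    COMPONENT_MEANS = "component_means"


@dataclass(frozen=True)
class ConversionFactors:
    """Biomass-to-carbon conversion fractions per component."""

    kind: FactorKind
    stem: float
    branch: float
    foliage: float
    root: float

    def __post_init__(self):
        for v in (self.stem, self.branch, self.foliage, self.root):
            if not (0.0 < v < 1.0):
                raise ValueError("conversion fractions must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.stem, self.branch, self.foliage, self.root], dtype=float)


def observed_carbon(biomass, concentrations) -> ComponentVector:
    """Component carbon stocks (kg C) of one tree.

    ``biomass`` and ``concentrations`` are length-4 sequences in
    component order; the total is the sum of the components.
    """
    b = np.asarray(biomass, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if b.shape != (4,) or c.shape != (4,):
        raise ValueError("biomass and concentrations must each have 4 entries")
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")
    if np.any((c <= 0) | (c >= 1)):
        raise ValueError("concentrations must lie in (0, 1)")
    return ComponentVector(*(b * c))


def mean_concentrations(data: pd.DataFrame, kind=FactorKind.COMPONENT_MEANS,
                        biomass_weighted: bool = False) -> ConversionFactors:
    """Sample-mean conversion factors of the requested kind.

    ``component_means``: arithmetic mean of each component's
    concentration across trees.  ``tree_mean``: the mean across trees of
    each tree's total-carbon/total-biomass ratio, applied to every
    component (set ``biomass_weighted`` to pool carbon and biomass over
    all trees instead of averaging per-tree ratios).  ``factor_05``: the
    generic 0.5.
    """
    kind = FactorKind(kind)
    if len(data) < 1:
        raise ValueError("need at least one tree")
    if kind is FactorKind.FACTOR_05:
        return ConversionFactors(kind, 0.5, 0.5, 0.5, 0.5)
    if kind is FactorKind.TREE_MEAN:
        tc, tb = total_carbon(data), total_biomass(data)
        if biomass_weighted:
            f = float(tc.sum() / tb.sum())
        else:
            f = float((tc / tb).mean())
        return ConversionFactors(kind, f, f, f, f)
    means = concentration_matrix(data).mean(axis=0)
    return ConversionFactors(kind, *means)


def conversion_factors_for_method(method: int, data: pd.DataFrame,
                                  biomass_weighted: bool = False) -> ConversionFactors | None:
    """Factors used by an indirect method (None for the direct Method 1)."""
    if method == 1:
        return None
    if method == 2:
        return mean_concentrations(data, FactorKind.FACTOR_05)
    if method == 3:
        return mean_concentrations(data, FactorKind.TREE_MEAN, biomass_weighted)
    if method == 4:
        return mean_concentrations(data, FactorKind.COMPONENT_MEANS)
    raise ValueError(f"method must be 1..4, got {method}")


def predict_carbon_by_method(
    method: int,
    biomass_loo: JackknifeResult,
    carbon_loo: JackknifeResult | None,
    factors: ConversionFactors | None,
) -> np.ndarray:
    """(n, 4) leave-one-out carbon predictions (kg C) for one method.

    Method 1 takes the carbon system's held-out predictions directly;
    Methods 2–4 rescale the biomass system's held-out predictions by
    the given conversion factors.
    """
    if method == 1:
        if carbon_loo is None:
            raise ValueError("Method 1 requires the carbon-system jackknife result")
        return carbon_loo.loo_pred.copy()
    if factors is None:
        raise ValueError(f"Method {method} requires conversion factors")
    return biomass_loo.loo_pred * factors.as_array()[None, :]


def method_error_matrix(
    data: pd.DataFrame,
    biomass_loo: JackknifeResult,
    carbon_loo: JackknifeResult,
    biomass_weighted_tree_mean: bool = False,
) -> pd.DataFrame:
    """Tidy per-tree carbon prediction errors for all four methods.

    Columns: tree, method, component (incl. 'total'), observed_kg,
    predicted_kg, error_kg (observed − predicted).  Both jackknife
    results must come from the same trees.
    """
    n = len(data)
    if biomass_loo.n != n or carbon_loo.n != n:
        raise ValueError("jackknife results and data must cover the same trees")
    for jk, what in ((biomass_loo, "biomass"), (carbon_loo, "carbon")):
        same = np.array_equal(
            jk.model.data[["tree_id", "D_cm"]].to_numpy(), data[["tree_id", "D_cm"]].to_numpy()
        )
        if not same:
            raise ValueError(f"{what} jackknife was fitted on a different tree set")
    obs = carbon_matrix(data)
    obs_full = np.column_stack([obs, obs.sum(axis=1)])
    rows = []
    ok = biomass_loo.converged & carbon_loo.converged
    tree_ids = data["tree_id"].to_numpy()
    for method in (1, 2, 3, 4):
        factors = conversion_factors_for_method(method, data, biomass_weighted_tree_mean)
        pred = predict_carbon_by_method(method, biomass_loo, carbon_loo, factors)
        pred_full = np.column_stack([pred, pred.sum(axis=1)])
        for s, name in enumerate(SERIES):
            for i in np.flatnonzero(ok):
                rows.append(
                    (tree_ids[i], method, name, obs_full[i, s], pred_full[i, s],
                     obs_full[i, s] - pred_full[i, s])
                )
    return pd.DataFrame(
        rows, columns=["tree", "method", "component", "observed_kg", "predicted_kg", "error_kg"]
    )


def rmse_r(observed, predicted, p_params: int = N_SYSTEM_PARAMS) -> float:
    """Relative RMSE in percent: RMSEp scaled by the mean prediction."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    n = y.size
    if n <= p_params:
        raise ValueError(f"n = {n} must exceed p = {p_params}")
    mean_pred = yhat.mean()
    if mean_pred == 0:
        raise ValueError("mean prediction is zero; relative RMSE undefined")
    rmsep = np.sqrt(((y - yhat) ** 2).sum() / (n - p_params))
    return float(rmsep / mean_pred * 100.0)


def rmse_rc(matrix: pd.DataFrame, method: int, component: str,
            p_params: int = N_SYSTEM_PARAMS) -> float:
    """Relative RMSE of carbon prediction (%) for one method × component."""
    sl = matrix[(matrix["method"] == method) & (matrix["component"] == component)]
    if sl.empty:
        raise ValueError(f"no entries for method {method}, component {component!r}")
    return rmse_r(sl["observed_kg"].to_numpy(), sl["predicted_kg"].to_numpy(), p_params)


def rmse_rc_indirect(biomass_obs, biomass_pred, concentrations, factor: float,
                     p_params: int = N_SYSTEM_PARAMS) -> float:
    """Indirect-method relative RMSE written purely in biomass terms.

    Equivalent to :func:`rmse_r` applied to (biomass × concentration)
    against (predicted biomass × factor): the factor cancels between
    numerator and the mean predicted carbon.
    """
    W = np.asarray(biomass_obs, dtype=float)
    What = np.asarray(biomass_pred, dtype=float)
    cc = np.asarray(concentrations, dtype=float)
    n = W.size
    if n <= p_params:
        raise ValueError(f"n = {n} must exceed p = {p_params}")
    if factor <= 0:
        raise ValueError("factor must be positive")
    num = np.sqrt(((W * cc / factor - What) ** 2).sum() / (n - p_params))
    return float(num / What.mean() * 100.0)


def rmse_rc_table(matrix: pd.DataFrame, p_params: int = N_SYSTEM_PARAMS) -> pd.DataFrame:
    """RMSE_rc (%) for every method × component (and total)."""
    out = {}
    for method in sorted(matrix["method"].unique()):
        out[f"method_{method}"] = {
            name: rmse_rc(matrix, method, name, p_params) for name in SERIES
        }
    return pd.DataFrame(out).T


def bootstrap_rmse_rc(matrix: pd.DataFrame, n_boot: int = 2000, seed: int = 0,
                      level: float = 0.95, p_params: int = N_SYSTEM_PARAMS) -> pd.DataFrame:
    """Nonparametric bootstrap CIs for RMSE_rc, resampling trees.

    Returns a tidy frame with point estimate and percentile interval per
    method × component.
    """
    rng = np.random.default_rng(seed)
    trees = matrix["tree"].unique()
    n = trees.size
    # reshape once: observed/predicted arrays indexed [tree, method, series]
    piv_o = matrix.pivot_table(index="tree", columns=["method", "component"], values="observed_kg")
    piv_p = matrix.pivot_table(index="tree", columns=["method", "component"], values="predicted_kg")
    piv_o = piv_o.loc[trees]
    piv_p = piv_p.loc[trees]
    alpha = (1.0 - level) / 2.0
    rows = []
    methods = sorted(matrix["method"].unique())
    idx_samples = rng.integers(0, n, size=(n_boot, n))
    for method in methods:
        for name in SERIES:
            o = piv_o[(method, name)].to_numpy()
            p = piv_p[(method, name)].to_numpy()
            point = rmse_r(o, p, p_params)
            reps = np.empty(n_boot)
            for b in range(n_boot):
                take = idx_samples[b]
                reps[b] = rmse_r(o[take], p[take], p_params)
            lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
            rows.append((method, name, point, lo, hi))
    return pd.DataFrame(rows, columns=["method", "component", "rmse_rc", "ci_lower", "ci_upper"])
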