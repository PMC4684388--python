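"""Jackknife (leave-one-out) validation of compatible systems.

Each of the n trees is held out in turn; the system is refitted on the
remaining n−1 trees (warm-started from the full-data fit) and the
held-out tree is predicted.  From the n rounds we report

* per-parameter means and standard deviations across rounds,
* per-round in-sample adjusted R² (mean and SD across rounds), plus the
  adjusted R² computed from the held-out predictions themselves,
* prediction statistics per component and total from the held-out
  predictions: RMSEp, ME, ME%, MAE, MAE% (kg and percent).

The degrees-of-freedom correction uses p = 8 throughout — the single
joint fit's parameter count — since one system produces all four
component predictions at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import COMPONENTS, AdditiveParams, predict_components
from .nsur import CompatibleSystemModel, SystemResults, fit_nsur

__all__ = [
    "N_SYSTEM_PARAMS",
    "ValidationStats",
    "JackknifeResult",
    "jackknife_fit",
    "validation_stats",
    "validation_table",
    "param_summary",
    "ra2_summary",
]

logger = logging.getLogger(__name__)

#: parameter count of one compatible system, used in d.o.f. corrections
N_SYSTEM_PARAMS = 8

SERIES = COMPONENTS + ("total",)


@dataclass(frozen=True)
class ValidationStats:
    """Prediction statistics for one response series.

    RMSEp uses divisor n − p; ME/MAE are plain means; the percentage
    versions average the per-tree ratio (trees with zero observed
    response are skipped and counted in ``n_skipped_pct``).
    """

    n: int
    p_params: int
    r2: float
    ra2: float
    rmsep: float
    me: float
    me_pct: float
    mae: float
    mae_pct: float
    n_skipped_pct: int = 0


def validation_stats(observed, predicted, p_params: int = N_SYSTEM_PARAMS) -> ValidationStats:
    """Compute R², adjusted R², RMSEp, ME, ME%, MAE and MAE%.

    ``observed`` and ``predicted`` are equal-length 1-d arrays; the
    predictions are expected to be out-of-sample (leave-one-out).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d arrays")
    n = y.size
    if n <= p_params:
        raise ValueError(f"n = {n} must exceed the parameter count p = {p_params}")
    err = y - yhat
    sse = float(err @ err)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    ra2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p_params - 1)
    rmsep = float(np.sqrt(sse / (n - p_params)))
    me = float(err.mean())
    mae = float(np.abs(err).mean())
    nz = y != 0
    n_skipped = int((~nz).sum())
    if n_skipped:
        logger.warning("validation_stats: skipping %d zero observations in percentage stats", n_skipped)
    me_pct = float((err[nz] / y[nz]).mean() * 100.0) if nz.any() else np.nan
    mae_pct = float(np.abs(err[nz] / y[nz]).mean() * 100.0) if nz.any() else np.nan
    return ValidationStats(
        n=n, p_params=p_params, r2=r2, ra2=ra2, rmsep=rmsep,
        me=me, me_pct=me_pct, mae=mae, mae_pct=mae_pct, n_skipped_pct=n_skipped,
    )


@dataclass
class JackknifeResult:
    """n leave-one-out fits of one compatible system.

    ``params_matrix`` holds one row of (a, b, r1..r3, k1..k3) per round;
    ``loo_pred`` the held-out component predictions (n, 4); ``observed``
    the matching observations; ``insample_ra2`` the per-round in-sample
    adjusted R² for each component and the total (n, 5).
    """

    model: CompatibleSystemModel
    params_matrix: np.ndarray
    converged: np.ndarray
    loo_pred: np.ndarray
    observed: np.ndarray
    insample_ra2: np.ndarray
    full_fit: SystemResults

    @property
    def n(self) -> int:
        return self.params_matrix.shape[0]

    @property
    def n_failed(self) -> int:
        return int((~self.converged).sum())

    @property
    def loo_pred_total(self) -> np.ndarray:
        return self.loo_pred.sum(axis=1)

    @property
    def observed_total(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    def series(self, name: str):
        """(observed, loo-predicted) pair for a component or 'total'."""
        if name == "total":
            return self.observed_total, self.loo_pred_total
        j = COMPONENTS.index(name)
        return self.observed[:, j], self.loo_pred[:, j]


def jackknife_fit(
    model: CompatibleSystemModel,
    full_fit: SystemResults | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> JackknifeResult:
    """Leave-one-out refits, warm-started from the full-data fit.

    Rounds that fail to converge are recorded; downstream statistics
    drop them (with a logged count).
    """
    n = model.nobs
    if n < 12:
        raise ValueError(f"jackknife validation needs at least 12 trees; got {n}")
    if full_fit is None:
        full_fit = model.fit(tol=tol, max_iter=max_iter)
    weights = full_fit.weight_spec
    x, Y = model.x, model.endog
    params_matrix = np.empty((n, 8))
    converged = np.zeros(n, dtype=bool)
    loo_pred = np.empty((n, 4))
    insample_ra2 = np.empty((n, 5))
    idx = np.arange(n)
    for t in range(n):
        keep = idx != t
        try:
            raw = fit_nsur(
                x[keep], Y[keep], weights, full_fit.params,
                tol=tol, max_iter=max_iter, sigma0=full_fit.sigma,
            )
        except Exception:  # noqa: BLE001 — a failed round is data, not fatal
            logger.warning("jackknife round %d failed; excluded from statistics", t)
            params_matrix[t] = np.nan
            loo_pred[t] = np.nan
            insample_ra2[t] = np.nan
            continue
        params_matrix[t] = raw["params"].as_array()
        converged[t] = raw["converged"]
        loo_pred[t] = predict_components(raw["params"], x[t : t + 1])[0]
        fitted = raw["fitted"]
        m = n - 1
        for s, name in enumerate(SERIES):
            yo = Y[keep].sum(axis=1) if name == "total" else Y[keep, s]
            yf = fitted.sum(axis=1) if name == "total" else fitted[:, s]
            sse = float(((yo - yf) ** 2).sum())
            sst = float(((yo - yo.mean()) ** 2).sum())
            r2 = 1.0 - sse / sst if sst > 0 else 1.0
            insample_ra2[t, s] = 1.0 - (1.0 - r2) * (m - 1) / (m - N_SYSTEM_PARAMS - 1)
    if not converged.any():
        raise RuntimeError("no jackknife round converged")
    if (~converged).any():
        logger.warning("jackknife: %d of %d rounds did not converge", int((~converged).sum()), n)
    return JackknifeResult(
        model=model,
        params_matrix=params_matrix,
        converged=converged,
        loo_pred=loo_pred,
        observed=Y,
        insample_ra2=insample_ra2,
        full_fit=full_fit,
    )


def param_summary(jk: JackknifeResult) -> pd.DataFrame:
    """Mean and sample SD (divisor n−1) of each parameter across rounds."""
    ok = jk.converged
    if ok.sum() < 2:
        raise ValueError("parameter summary needs at least 2 converged jackknife rounds")
    P = jk.params_matrix[ok]
    return pd.DataFrame(
        {"mean": P.mean(axis=0), "std": P.std(axis=0, ddof=1)},
        index=list(AdditiveParams.NAMES),
    )


def ra2_summary(jk: JackknifeResult) -> pd.DataFrame:
    """Adjusted-R² summary per component and total.

    ``mean``/``std`` summarise the per-round in-sample adjusted R²;
    ``ra2_loo`` is the single adjusted R² computed from the held-out
    predictions across all rounds (both views are reported because the
    round-wise and held-out notions answer different questions).
    """
    ok = jk.converged
    rows = {}
    for s, name in enumerate(SERIES):
        obs, pred = jk.series(name)
        loo = validation_stats(obs[ok], pred[ok])
        rows[name] = {
            "mean": jk.insample_ra2[ok, s].mean(),
            "std": jk.insample_ra2[ok, s].std(ddof=1),
            "ra2_loo": loo.ra2,
        }
    return pd.DataFrame(rows).T


def validation_table(jk: JackknifeResult, p_params: int = N_SYSTEM_PARAMS) -> pd.DataFrame:
    """Held-out prediction statistics per component and total (kg, %)."""
    ok = jk.converged
    rows = {}
    for name in SERIES:
        obs, pred = jk.series(name)
        st = validation_stats(obs[ok], pred[ok], p_params)
        rows[name] = {
            "RMSEp_kg": st.rmsep,
            "ME_kg": st.me,
            "ME_pct": st.me_pct,
            "MAE_kg": st.mae,
            "MAE_pct": st.mae_pct,
            "Ra2": st.ra2,
        }
    return pd.DataFrame(rows).T
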