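"""Nonlinear seemingly unrelated regression (NSUR) for compatible systems.

The four component equations share parameters through the additive
constraint, and their errors are cross-correlated within a tree.  NSUR
estimates the eight system parameters by iterated feasible generalized
least squares (FGLS):

1. given the current cross-equation covariance Σ of the weighted
   residuals, minimise the stacked generalized sum of squares by
   Levenberg–Marquardt with an analytic Jacobian;
2. re-estimate Σ from the weighted residuals (divisor n);
3. repeat until the largest relative parameter change falls below
   tolerance.

Heteroscedasticity is handled by per-equation power-of-predictor
weights: equation m's residual is divided by x^(p_m / 2), where p_m is
the *variance*-power exponent (error variance grows as x^p_m).  The
exponents can be estimated from an unweighted fit by regressing
log squared residuals on log x, or fixed to published values for
Korean pine plantation systems.

Internally the optimiser works in (log a, b, log r1..r3, k1..k3) space,
which enforces positivity of a and the ratios; results are reported in
natural parameter space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .allometry import (
    COMPONENTS,
    AdditiveParams,
    ComponentAllometries,
    ModelSpec,
    PredictorForm,
    reparameterize,
)
from .data import response_matrix, validate_tree_table

__all__ = [
    "WeightSpec",
    "KOREAN_PINE_VARIANCE_EXPONENTS",
    "FitError",
    "start_values",
    "estimate_weight_exponents",
    "fit_nsur",
    "CompatibleSystemModel",
    "SystemResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightSpec:
    """Per-equation variance-power exponents p (error variance ∝ x^p).

    The GLS weight applied to equation m's residual is 1 / x^(p_m / 2),
    i.e. division by the error standard deviation's power trend.
    """

    p_stem: float = 0.0
    p_branch: float = 0.0
    p_foliage: float = 0.0
    p_root: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("weight exponents must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_stem, self.p_branch, self.p_foliage, self.p_root], dtype=float)

    @classmethod
    def unit(cls) -> "WeightSpec":
        return cls(0.0, 0.0, 0.0, 0.0)

    def sd_weights(self, x: np.ndarray) -> np.ndarray:
        """(n, 4) array of x^(p_m/2): divide residuals by this."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return x[:, None] ** (self.as_array()[None, :] / 2.0)


#: Published variance-power exponents for the Korean pine plantation
#: systems (stem, branch, foliage, root), by model label.  The predictor
#: x is D for BM1/CM3 and D^2 H for BM2/CM4.
KOREAN_PINE_VARIANCE_EXPONENTS = {
    "BM1": WeightSpec(2.33, 2.01, 1.67, 2.19),
    "BM2": WeightSpec(0.77, 0.82, 0.60, 0.75),
    "CM3": WeightSpec(2.22, 2.13, 1.93, 2.28),
    "CM4": WeightSpec(0.60, 0.67, 0.72, 0.81),
}


class FitError(RuntimeError):
    """Raised when a system fit cannot be carried out."""


# ---------------------------------------------------------------------------
# system evaluation in optimiser space
# ---------------------------------------------------------------------------

def _phi_from_params(params: AdditiveParams) -> np.ndarray:
    t = params.as_array()
    return np.array(
        [np.log(t[0]), t[1], np.log(t[2]), np.log(t[3]), np.log(t[4]), t[5], t[6], t[7]]
    )


def _params_from_phi(phi: np.ndarray) -> AdditiveParams:
    return AdditiveParams(
        a=float(np.exp(phi[0])),
        b=float(phi[1]),
        r1=float(np.exp(phi[2])),
        r2=float(np.exp(phi[3])),
        r3=float(np.exp(phi[4])),
        k1=float(phi[5]),
        k2=float(phi[6]),
        k3=float(phi[7]),
    )


def _system_eval(phi: np.ndarray, x: np.ndarray, with_jac: bool):
    """Predicted (n, 4) components and optionally the (n, 4, 8) Jacobian.

    Differentiation is with respect to phi = (log a, b, log r, k), which
    turns the coefficient partials into clean multiples of the
    predictions themselves.
    """
    loga, b = phi[0], phi[1]
    logr = phi[2:5]
    k = phi[5:8]
    lx = np.log(x)
    t = np.exp(logr[None, :] + k[None, :] * lx[:, None])  # r_j x^{k_j}, (n, 3)
    denom = 1.0 + t.sum(axis=1)  # (n,)
    total = np.exp(loga + b * lx)  # a x^b
    shares = np.concatenate([np.ones((x.size, 1)), t], axis=1) / denom[:, None]
    F = shares * total[:, None]  # (n, 4)
    if not with_jac:
        return F, None
    J = np.empty((x.size, 4, 8))
    J[:, :, 0] = F  # d/d log a
    J[:, :, 1] = F * lx[:, None]  # d/d b
    ts = t / denom[:, None]  # t_j / S
    for j in range(3):
        sel = np.zeros(4)
        sel[j + 1] = 1.0
        factor = sel[None, :] - ts[:, j][:, None]  # (n, 4)
        J[:, :, 2 + j] = F * factor  # d/d log r_j
        J[:, :, 5 + j] = F * lx[:, None] * factor  # d/d k_j
    return F, J


def _safe_cholesky(sigma: np.ndarray) -> np.ndarray:
    """Lower Cholesky of Σ, ridge-regularising if (near-)singular.

    A degenerate Σ (e.g. from an exact fit) is replaced by the identity
    — GLS estimates are invariant to an overall scaling of Σ, so this
    only anchors the scale.
    """
    tr = float(np.trace(sigma))
    if not np.isfinite(tr) or tr <= 0 or tr < 4e-25:
        logger.warning("degenerate residual covariance; using identity weighting")
        return np.eye(4)
    ridge = 0.0
    for _ in range(12):
        try:
            return linalg.cholesky(sigma + ridge * np.eye(4), lower=True)
        except linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-12 * tr / 4.0)
            logger.warning("singular residual covariance; ridge-regularising with %g", ridge)
    raise FitError("could not factorise the residual covariance")


def _gls_step(phi0, x, Y, W, L, xtol):
    """One generalized least-squares minimisation at fixed Σ = L L'."""
    Linv_T = linalg.solve_triangular(L, np.eye(4), lower=True).T  # E @ Linv_T whitens rows

    def resid(phi):
        F, _ = _system_eval(phi, x, with_jac=False)
        return (((Y - F) / W) @ Linv_T).ravel()

    def jac(phi):
        _, Jf = _system_eval(phi, x, with_jac=True)
        # d resid / d phi_p = (-Jf[:, :, p] / W) @ Linv_T
        out = np.empty((x.size * 4, 8))
        for p in range(8):
            out[:, p] = ((-Jf[:, :, p] / W) @ Linv_T).ravel()
        return out

    res = optimize.least_squares(resid, phi0, jac=jac, method="lm", xtol=xtol, ftol=xtol, gtol=xtol)
    return res


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def start_values(x: np.ndarray, Y: np.ndarray) -> AdditiveParams:
    """Initial system parameters from per-equation log–log regressions.

    Each component and the total get ordinary least squares of
    log(response) on log(x); the per-component power laws are then
    reparameterised into the compatible-system form.  Rows with
    non-positive responses are excluded from that component's
    regression (with a logged warning).
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 4:
        raise ValueError("Y must be (n, 4): stem, branch, foliage, root")
    lx = np.log(x)

    def loglog(y, name):
        mask = y > 0
        if not mask.all():
            logger.warning("start_values: excluding %d non-positive %s responses", (~mask).sum(), name)
        if mask.sum() < 3:
            raise FitError(f"too few positive {name} responses for start values")
        slope, intercept = np.polyfit(lx[mask], np.log(y[mask]), 1)
        return float(np.exp(intercept)), float(slope)

    pairs = [loglog(Y[:, j], COMPONENTS[j]) for j in range(4)]
    a0, b0 = loglog(Y.sum(axis=1), "total")
    comp = ComponentAllometries(
        a1=pairs[0][0], b1=pairs[0][1],
        a2=pairs[1][0], b2=pairs[1][1],
        a3=pairs[2][0], b3=pairs[2][1],
        a4=pairs[3][0], b4=pairs[3][1],
        a0=a0, b0=b0,
    )
    return reparameterize(comp)


def estimate_weight_exponents(x: np.ndarray, resid: np.ndarray) -> WeightSpec:
    """Variance-power exponents from unweighted residuals.

    For each equation, regress log(resid^2) on log(x); the slope is the
    exponent p of the error-variance model var ∝ x^p.  Equations with
    (numerically) zero residuals get p = 0.
    """
    x = np.asarray(x, dtype=float)
    resid = np.asarray(resid, dtype=float)
    lx = np.log(x)
    ps = []
    for j in range(4):
        e2 = resid[:, j] ** 2
        mask = e2 > np.finfo(float).tiny
        if mask.sum() < 3:
            logger.info("estimate_weight_exponents: %s residuals ~0; p set to 0", COMPONENTS[j])
            ps.append(0.0)
            continue
        slope, _ = np.polyfit(lx[mask], np.log(e2[mask]), 1)
        ps.append(float(slope))
    return WeightSpec(*ps)


def fit_nsur(
    x: np.ndarray,
    Y: np.ndarray,
    weights: WeightSpec,
    start: AdditiveParams,
    tol: float = 1e-8,
    max_iter: int = 200,
    two_step: bool = False,
    sigma0: np.ndarray | None = None,
    jitter_seed: int = 0,
) -> dict:
    """Iterated FGLS estimation of the compatible system (array interface).

    Returns a dict with keys params, sigma, param_cov, n_iter,
    converged, resid, fitted, weights, jitter_used.  ``two_step`` stops
    after one Σ re-estimation (classic two-step FGLS).  ``sigma0`` warm
    starts the covariance (identity otherwise).
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = x.size
    if n < 3:
        raise FitError(f"need at least 3 trees to identify 8 parameters; got {n}")
    if Y.shape != (n, 4):
        raise ValueError("Y must be (n, 4)")
    W = weights.sd_weights(x)
    phi = _phi_from_params(start)
    sigma = np.eye(4) if sigma0 is None else np.array(sigma0, dtype=float)
    converged = False
    n_iter = 0
    jitter_used = False
    rng = np.random.default_rng(jitter_seed)
    inner_tol = min(tol, 1e-10)
    for n_iter in range(1, max_iter + 1):
        L = _safe_cholesky(sigma)
        res = _gls_step(phi, x, Y, W, L, inner_tol)
        if not np.all(np.isfinite(res.x)):
            # rare: restart from a jittered start point
            jitter_used = True
            logger.warning("fit_nsur: non-finite step; jitter restart")
            res = _gls_step(phi + rng.normal(0, 0.05, 8), x, Y, W, L, inner_tol)
            if not np.all(np.isfinite(res.x)):
                raise FitError("optimiser diverged even after jitter restart")
        theta_old = _params_from_phi(phi).as_array()
        phi = res.x
        theta_new = _params_from_phi(phi).as_array()
        F, _ = _system_eval(phi, x, with_jac=False)
        E = (Y - F) / W
        sigma_new = E.T @ E / n
        delta = np.max(np.abs(theta_new - theta_old) / np.maximum(np.abs(theta_old), 1e-12))
        sigma = sigma_new
        if delta < tol and n_iter > 1:
            converged = True
            break
        if two_step and n_iter >= 2:
            converged = delta < tol
            break
    if not converged and not two_step:
        logger.warning("fit_nsur: no convergence in %d outer iterations (delta=%g)", n_iter, delta)
    # covariance at the final estimate, under the final Sigma
    L = _safe_cholesky(sigma)
    Linv_T = linalg.solve_triangular(L, np.eye(4), lower=True).T
    _, Jf = _system_eval(phi, x, with_jac=True)
    Jw = np.empty((n * 4, 8))
    for p in range(8):
        Jw[:, p] = ((Jf[:, :, p] / W) @ Linv_T).ravel()
    JtJ = Jw.T @ Jw
    try:
        cov_phi = linalg.inv(JtJ)
    except linalg.LinAlgError:
        cov_phi = linalg.pinv(JtJ)
    params = _params_from_phi(phi)
    th = params.as_array()
    G = np.diag([th[0], 1.0, th[2], th[3], th[4], 1.0, 1.0, 1.0])  # dtheta/dphi
    param_cov = G @ cov_phi @ G.T
    F, _ = _system_eval(phi, x, with_jac=False)
    return {
        "params": params,
        "sigma": sigma,
        "param_cov": param_cov,
        "n_iter": n_iter,
        "converged": converged,
        "resid": Y - F,
        "fitted": F,
        "weights": weights,
        "jitter_used": jitter_used,
    }


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class CompatibleSystemModel:
    """A compatible additive allometric system bound to a tree table.

    Parameters
    ----------
    data : DataFrame
        Canonical tree table (see :mod:`allocarbon.data`).
    spec : ModelSpec or str
        Which system: "BM1", "BM2", "CM3" or "CM4" (or a ModelSpec).
    weights : WeightSpec, "fixed", "estimate" or "unit"
        Heteroscedasticity weighting.  "fixed" (default) uses the
        published Korean pine variance-power exponents for the chosen
        system; "estimate" derives them from an unweighted fit;
        "unit" disables weighting.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | str, weights="fixed"):
        self.data = validate_tree_table(data.reset_index(drop=True))
        self.spec = ModelSpec.from_label(spec) if isinstance(spec, str) else spec
        self.x = np.asarray(
            self.spec.predictor_values(self.data["D_cm"].to_numpy(), self.data["H_m"].to_numpy()),
            dtype=float,
        )
        self.endog = response_matrix(self.data, self.spec.response)
        self.weight_mode = weights
        self.nobs = len(self.data)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec="BM1", weights="fixed"):
        return cls(data, spec, weights)

    def start_values(self) -> AdditiveParams:
        return start_values(self.x, self.endog)

    def _resolve_weights(self, start: AdditiveParams, tol, max_iter) -> WeightSpec:
        w = self.weight_mode
        if isinstance(w, WeightSpec):
            return w
        if w == "unit":
            return WeightSpec.unit()
        if w == "fixed":
            return KOREAN_PINE_VARIANCE_EXPONENTS[self.spec.label]
        if w == "estimate":
            prelim = fit_nsur(
                self.x, self.endog, WeightSpec.unit(), start, tol=tol, max_iter=max_iter
            )
            return estimate_weight_exponents(self.x, prelim["resid"])
        raise ValueError(f"unknown weights mode {w!r}")

    def fit(
        self,
        start: AdditiveParams | None = None,
        tol: float = 1e-8,
        max_iter: int = 200,
        two_step: bool = False,
        sigma0: np.ndarray | None = None,
    ) -> "SystemResults":
        if start is None:
            start = self.start_values()
        weights = self._resolve_weights(start, tol, max_iter)
        raw = fit_nsur(
            self.x, self.endog, weights, start,
            tol=tol, max_iter=max_iter, two_step=two_step, sigma0=sigma0,
        )
        return SystemResults(self, raw, tol=tol)


class SystemResults:
    """A converged (or diagnosed) NSUR fit of a compatible system.

    Attributes
    ----------
    params : AdditiveParams
    params_array : ndarray, shape (8,)
    bse : ndarray — approximate standard errors (delta method from the
        GLS information matrix)
    sigma : ndarray (4, 4) — cross-equation covariance of weighted residuals
    weight_spec : WeightSpec
    converged : bool
    resid, fittedvalues : (n, 4) arrays in component order
    """

    def __init__(self, model: CompatibleSystemModel, raw: dict, tol: float):
        self.model = model
        self.params: AdditiveParams = raw["params"]
        self.params_array = self.params.as_array()
        self.sigma = raw["sigma"]
        self.param_cov = raw["param_cov"]
        self.bse = np.sqrt(np.maximum(np.diag(self.param_cov), 0.0))
        self.weight_spec: WeightSpec = raw["weights"]
        self.n_iter: int = raw["n_iter"]
        self.converged: bool = raw["converged"]
        self.resid = raw["resid"]
        self.fittedvalues = raw["fitted"]
        self.jitter_used: bool = raw["jitter_used"]
        self.tol = tol
        self.nobs = model.nobs

    def cov_params(self) -> np.ndarray:
        return self.param_cov

    def predict(self, D, H=None):
        """Component predictions (n, 4) at new D (cm) / H (m)."""
        from .allometry import predict_components

        x = self.model.spec.predictor_values(D, H)
        return predict_components(self.params, x)

    def predict_frame(self, D, H=None) -> pd.DataFrame:
        arr = np.atleast_2d(self.predict(np.atleast_1d(np.asarray(D, float)),
                                         None if H is None else np.atleast_1d(np.asarray(H, float))))
        df = pd.DataFrame(arr, columns=list(COMPONENTS))
        df["total"] = df.sum(axis=1)
        return df

    def jackknife(self, **kwargs):
        """Leave-one-out refits; see :func:`allocarbon.validation.jackknife_fit`."""
        from .validation import jackknife_fit

        return jackknife_fit(self.model, full_fit=self, **kwargs)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Compatible additive system {spec.label} "
            f"({spec.response.value}, predictor {spec.predictor.value})",
            f"n = {self.nobs} trees, iterated FGLS, "
            f"{'converged' if self.converged else 'NOT converged'} in {self.n_iter} outer iterations",
            f"variance-power weights (stem, branch, foliage, root): "
            + ", ".join(f"{p:g}" for p in self.weight_spec.as_array()),
            "",
            f"{'param':>6} {'estimate':>12} {'std err':>12}",
        ]
        for name, est, se in zip(AdditiveParams.NAMES, self.params_array, self.bse):
            lines.append(f"{name:>6} {est:12.4f} {se:12.4f}")
        corr = self.sigma / np.sqrt(np.outer(np.diag(self.sigma), np.diag(self.sigma)))
        lines.append("")
        lines.append("weighted-residual cross-equation correlations:")
        for i, c in enumerate(COMPONENTS):
            lines.append(
                f"{c:>8} " + " ".join(f"{corr[i, j]:6.2f}" for j in range(4))
            )
        return "\n".join(lines)
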