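"""Compatible additive allometric systems for tree component biomass and carbon.

A single-predictor allometry ``Y = a X^b`` relates a tree dimension
(diameter at breast height D, or the combined form D^2 H) to a mass pool.
A *compatible* (additive) system reparameterises the four component
equations (stem, branch, foliage, root) so that their predictions sum
exactly to the total allometry ``a X^b``:

    Y_stem    = a X^b                 / S(X)
    Y_branch  = a r1 X^(b + k1)       / S(X)
    Y_foliage = a r2 X^(b + k2)       / S(X)
    Y_root    = a r3 X^(b + k3)       / S(X)

with ``S(X) = 1 + r1 X^k1 + r2 X^k2 + r3 X^k3``.  Here ``(a, b)`` is the
total-tree allometry, ``r_j = a_{j+1}/a_1`` are component/stem coefficient
ratios and ``k_j = b_{j+1} - b_1`` exponent differences of the underlying
per-component allometries.

Units: D in cm, H in m, biomass in kg, carbon in kg C.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COMPONENTS",
    "PredictorForm",
    "Response",
    "ModelSpec",
    "MODEL_SPECS",
    "AdditiveParams",
    "ComponentAllometries",
    "ComponentVector",
    "predictor_value",
    "predict_components",
    "predict_components_expanded",
    "reparameterize",
    "expand_params",
]

#: Component order used everywhere in the package.
COMPONENTS = ("stem", "branch", "foliage", "root")


class PredictorForm(str, enum.Enum):
    """Predictor variable of the allometry: D (cm) or D^2 H (cm^2 m)."""

    D = "D"
    D2H = "D2H"


class Response(str, enum.Enum):
    """What the system predicts: oven-dry biomass (kg) or carbon stock (kg C)."""

    BIOMASS = "biomass"
    CARBON = "carbon"


def predictor_value(form: PredictorForm, D, H=None):
    """Evaluate the predictor X from diameter D (cm) and height H (m).

    Under the ``D`` form H is ignored; under ``D2H`` it is required.
    Accepts scalars or arrays; raises ``ValueError`` on non-positive inputs.
    """
    form = PredictorForm(form)
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0) or not np.all(np.isfinite(D)):
        raise ValueError("D must be positive and finite (cm)")
    if form is PredictorForm.D:
        return D if D.ndim else float(D)
    if H is None:
        raise ValueError("H (m) is required for the D2H predictor form")
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0) or not np.all(np.isfinite(H)):
        raise ValueError("H must be positive and finite (m)")
    x = D * D * H
    return x if x.ndim else float(x)


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one compatible system: response × predictor form.

    The four canonical systems are labelled BM1 (biomass, D),
    BM2 (biomass, D^2 H), CM3 (carbon, D) and CM4 (carbon, D^2 H).
    """

    response: Response
    predictor: PredictorForm
    label: str = field(default="", compare=False)

    _LABELS = {
        (Response.BIOMASS, PredictorForm.D): "BM1",
        (Response.BIOMASS, PredictorForm.D2H): "BM2",
        (Response.CARBON, PredictorForm.D): "CM3",
        (Response.CARBON, PredictorForm.D2H): "CM4",
    }

    def __post_init__(self):
        object.__setattr__(self, "response", Response(self.response))
        object.__setattr__(self, "predictor", PredictorForm(self.predictor))
        canonical = self._LABELS[(self.response, self.predictor)]
        if self.label and self.label != canonical:
            raise ValueError(
                f"label {self.label!r} inconsistent with "
                f"({self.response.value}, {self.predictor.value}); expected {canonical}"
            )
        object.__setattr__(self, "label", canonical)

    @classmethod
    def from_label(cls, label: str) -> "ModelSpec":
        for (resp, pred), lab in cls._LABELS.items():
            if lab == label.upper():
                return cls(resp, pred)
        raise ValueError(f"unknown model label {label!r}; expected one of BM1, BM2, CM3, CM4")

    def predictor_values(self, D, H=None):
        return predictor_value(self.predictor, D, H)


MODEL_SPECS = {lab: ModelSpec.from_label(lab) for lab in ("BM1", "BM2", "CM3", "CM4")}


@dataclass(frozen=True)
class AdditiveParams:
    """Parameters of one compatible additive system.

    ``a`` and ``b`` are the total-tree allometry coefficient and exponent;
    ``r1..r3`` are branch/foliage/root-to-stem coefficient ratios and
    ``k1..k3`` the corresponding exponent differences.
    """

    a: float
    b: float
    r1: float
    r2: float
    r3: float
    k1: float
    k2: float
    k3: float

    NAMES = ("a", "b", "r1", "r2", "r3", "k1", "k2", "k3")

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("all parameters must be finite")
        if self.a <= 0:
            raise ValueError("total coefficient a must be positive")
        if min(self.r1, self.r2, self.r3) <= 0:
            raise ValueError("ratios r1, r2, r3 must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a, self.b, self.r1, self.r2, self.r3, self.k1, self.k2, self.k3],
            dtype=float,
        )

    @classmethod
    def from_array(cls, arr) -> "AdditiveParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError("expected 8 parameters (a, b, r1..r3, k1..k3)")
        return cls(*arr)


@dataclass(frozen=True)
class ComponentAllometries:
    """Per-component power laws ``Y_j = a_j X^{b_j}`` plus the total pair.

    Index 1..4 = stem, branch, foliage, root; (a0, b0) is the total.
    """

    a1: float
    b1: float
    a2: float
    b2: float
    a3: float
    b3: float
    a4: float
    b4: float
    a0: float
    b0: float

    def __post_init__(self):
        if min(self.a1, self.a2, self.a3, self.a4, self.a0) <= 0:
            raise ValueError("all allometric coefficients must be positive")


@dataclass(frozen=True)
class ComponentVector:
    """Masses per component with the total as their exact sum (kg or kg C)."""

    stem: float
    branch: float
    foliage: float
    root: float

    @property
    def total(self) -> float:
        return self.stem + self.branch + self.foliage + self.root

    def as_array(self) -> np.ndarray:
        return np.array([self.stem, self.branch, self.foliage, self.root], dtype=float)


def reparameterize(comp: ComponentAllometries) -> AdditiveParams:
    """Convert per-component allometries to compatible-system parameters.

    ``r_j = a_{j+1}/a_1``, ``k_j = b_{j+1} - b_1``; the total pair
    ``(a0, b0)`` becomes ``(a, b)``.
    """
    return AdditiveParams(
        a=comp.a0,
        b=comp.b0,
        r1=comp.a2 / comp.a1,
        r2=comp.a3 / comp.a1,
        r3=comp.a4 / comp.a1,
        k1=comp.b2 - comp.b1,
        k2=comp.b3 - comp.b1,
        k3=comp.b4 - comp.b1,
    )


def expand_params(params: AdditiveParams, a1: float = 1.0, b1: float = 0.0) -> ComponentAllometries:
    """Rebuild per-component allometries from system parameters.

    The stem pair ``(a1, b1)`` is not identified by ``(r, k)`` alone
    (only ratios and differences are); any positive choice yields the
    same compatible-system predictions.
    """
    if a1 <= 0:
        raise ValueError("a1 must be positive")
    return ComponentAllometries(
        a1=a1,
        b1=b1,
        a2=a1 * params.r1,
        b2=b1 + params.k1,
        a3=a1 * params.r2,
        b3=b1 + params.k2,
        a4=a1 * params.r3,
        b4=b1 + params.k3,
        a0=params.a,
        b0=params.b,
    )


def _check_X(X):
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0) or not np.all(np.isfinite(X)):
        raise ValueError("predictor X must be positive and finite")
    return X


def predict_components(params: AdditiveParams, X):
    """Evaluate the compatible system at predictor value(s) X.

    Returns a ``ComponentVector`` for scalar X, or an (n, 4) array
    (columns stem, branch, foliage, root) for array X.  The component
    sum equals ``a X^b`` exactly by construction.
    """
    X = _check_X(X)
    scalar = X.ndim == 0
    x = np.atleast_1d(X)
    total = params.a * x ** params.b
    t1 = params.r1 * x ** params.k1
    t2 = params.r2 * x ** params.k2
    t3 = params.r3 * x ** params.k3
    denom = 1.0 + t1 + t2 + t3
    shares = np.column_stack([np.ones_like(x), t1, t2, t3]) / denom[:, None]
    out = shares * total[:, None]
    if scalar:
        return ComponentVector(*out[0])
    return out


def predict_components_expanded(comp: ComponentAllometries, X):
    """Evaluate the system in its derivation form (unsimplified shares).

    Each component's share of the total ``a0 X^{b0}`` is
    ``a_j X^{b_j} / sum_m a_m X^{b_m}``.  Algebraically identical to
    :func:`predict_components` after :func:`reparameterize`; kept as an
    independent route for cross-checking.
    """
    X = _check_X(X)
    scalar = X.ndim == 0
    x = np.atleast_1d(X)
    parts = np.column_stack(
        [
            comp.a1 * x ** comp.b1,
            comp.a2 * x ** comp.b2,
            comp.a3 * x ** comp.b3,
            comp.a4 * x ** comp.b4,
        ]
    )
    total = comp.a0 * x ** comp.b0
    out = parts / parts.sum(axis=1)[:, None] * total[:, None]
    if scalar:
        return ComponentVector(*out[0])
    return out
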