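"""Parametric age-specific mortality laws.

Implements the hazard families routinely used for wildlife survival
analysis -- Exponential, Gompertz, Weibull and Logistic baselines, each
optionally extended with a Makeham (age-independent) term or a full
bathtub (Siler-type) shape with a declining juvenile component::

    mu(x) = exp(a0 - a1*x) + c + mu_baseline(x)

All ages are continuous years.  Survivorship uses closed-form cumulative
hazards (every law here integrates analytically); life expectancy and
life-span quantiles are obtained by quadrature and root finding on the
closed forms.  Discretisation to yearly life tables lives in
:mod:`postrepro.lifetable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "Model",
    "Shape",
    "MortalityParams",
    "TEN_LAWS",
    "hazard",
    "cumulative_hazard",
    "survivorship",
    "density",
    "remaining_expectancy",
    "lifespan_quantile",
    "sample_ages",
    "AGE_CAP",
]

#: Age (years) beyond which survivorship mass is treated as negligible.
#: For any plausible parameters of a long-lived mammal S(AGE_CAP) < 1e-12.
AGE_CAP = 150.0


class Model(str, Enum):
    EXPONENTIAL = "exponential"
    GOMPERTZ = "gompertz"
    WEIBULL = "weibull"
    LOGISTIC = "logistic"


class Shape(str, Enum):
    SIMPLE = "simple"
    MAKEHAM = "makeham"
    BATHTUB = "bathtub"


#: The ten model/shape combinations fitted in the analysis: a constant
#: hazard plus the three age-dependent baselines under each shape.
TEN_LAWS: tuple[tuple[Model, Shape], ...] = (
    (Model.EXPONENTIAL, Shape.SIMPLE),
    (Model.GOMPERTZ, Shape.SIMPLE),
    (Model.GOMPERTZ, Shape.MAKEHAM),
    (Model.GOMPERTZ, Shape.BATHTUB),
    (Model.WEIBULL, Shape.SIMPLE),
    (Model.WEIBULL, Shape.MAKEHAM),
    (Model.WEIBULL, Shape.BATHTUB),
    (Model.LOGISTIC, Shape.SIMPLE),
    (Model.LOGISTIC, Shape.MAKEHAM),
    (Model.LOGISTIC, Shape.BATHTUB),
)


@dataclass(frozen=True)
class MortalityParams:
    """Parameters of one mortality law.

    ``a0``/``a1`` control the juvenile decline (bathtub shape only),
    ``c`` is the age-independent hazard (Makeham/bathtub, and the whole
    hazard for the Exponential law), and ``b0``/``b1`` parameterise the
    senescent baseline.  For Gompertz and Logistic ``b0`` is on log
    scale (hazard ``exp(b0 + b1*x)``); for Weibull ``b0`` is the shape
    and ``b1`` the rate of ``mu(x) = b0*b1*(b1*x)**(b0-1)``.
    """

    model: Model
    shape: Shape = Shape.SIMPLE
    a0: Optional[float] = None
    a1: Optional[float] = None
    c: Optional[float] = None
    b0: Optional[float] = None
    b1: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))
        object.__setattr__(self, "shape", Shape(self.shape))
        self._validate()

    def _validate(self) -> None:
        m, s = self.model, self.shape
        if m is Model.EXPONENTIAL:
            if s is not Shape.SIMPLE:
                raise ValueError(
                    "the constant-hazard law has no Makeham/bathtub variant"
                )
            if self.c is None or self.c < 0:
                raise ValueError("exponential law needs c >= 0")
            return
        if self.b0 is None or self.b1 is None:
            raise ValueError(f"{m.value} law needs b0 and b1")
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0")
        if m is Model.WEIBULL and (self.b0 <= 0 or self.b1 <= 0):
            raise ValueError("Weibull needs shape b0 > 0 and rate b1 > 0")
        if s in (Shape.MAKEHAM, Shape.BATHTUB):
            if self.c is None or self.c < 0:
                raise ValueError(f"{s.value} shape needs c >= 0")
        if s is Shape.BATHTUB:
            if self.a0 is None or self.a1 is None:
                raise ValueError("bathtub shape needs a0 and a1")
            if self.a1 < 0:
                raise ValueError("a1 must be >= 0")

    @property
    def active_names(self) -> tuple[str, ...]:
        """Names of the parameters this model/shape actually uses."""
        return active_param_names(self.model, self.shape)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.active_names], float)

    @classmethod
    def from_array(cls, model: Model, shape: Shape, values) -> "MortalityParams":
        names = active_param_names(model, shape)
        return cls(model=model, shape=shape, **dict(zip(names, map(float, values))))


def active_param_names(model: Model, shape: Shape) -> tuple[str, ...]:
    model, shape = Model(model), Shape(shape)
    if model is Model.EXPONENTIAL:
        return ("c",)
    base = ("b0", "b1")
    if shape is Shape.SIMPLE:
        return base
    if shape is Shape.MAKEHAM:
        return ("c",) + base
    return ("a0", "a1", "c") + base


def _check_age(age) -> np.ndarray:
    x = np.asarray(age, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be >= 0")
    return x


def _baseline_hazard(p: MortalityParams, x: np.ndarray) -> np.ndarray:
    if p.model is Model.EXPONENTIAL:
        return np.full_like(x, p.c)
    if p.model is Model.GOMPERTZ:
        return np.exp(p.b0 + p.b1 * x)
    if p.model is Model.WEIBULL:
        with np.errstate(divide="ignore"):
            return p.b0 * p.b1 * np.power(p.b1 * x, p.b0 - 1.0)
    # logistic: Gompertz numerator with a saturating denominator; the
    # hazard rises like exp(b0 + b1*x) and plateaus at b1.
    ebx = np.exp(p.b1 * x)
    return np.exp(p.b0) * ebx / (1.0 + math.exp(p.b0) * (ebx - 1.0) / p.b1)


def _baseline_cumhaz(p: MortalityParams, x: np.ndarray) -> np.ndarray:
    if p.model is Model.EXPONENTIAL:
        return p.c * x
    if p.model is Model.GOMPERTZ:
        if p.b1 == 0:
            return math.exp(p.b0) * x
        return math.exp(p.b0) / p.b1 * np.expm1(p.b1 * x)
    if p.model is Model.WEIBULL:
        return np.power(p.b1 * x, p.b0)
    if p.b1 == 0:
        return math.exp(p.b0) * x
    return np.log1p(math.exp(p.b0) * np.expm1(p.b1 * x) / p.b1)


def hazard(params: MortalityParams, age) -> np.ndarray:
    """Instantaneous mortality rate mu(age) in 1/year."""
    x = _check_age(age)
    h = _baseline_hazard(params, x)
    if params.shape is Shape.MAKEHAM:
        h = h + params.c
    elif params.shape is Shape.BATHTUB:
        h = h + params.c + np.exp(params.a0 - params.a1 * x)
    return h


def cumulative_hazard(params: MortalityParams, age) -> np.ndarray:
    """Integrated hazard H(age) = int_0^age mu(t) dt, in closed form."""
    x = _check_age(age)
    H = _baseline_cumhaz(params, x)
    if params.shape is Shape.MAKEHAM:
        H = H + params.c * x
    elif params.shape is Shape.BATHTUB:
        if params.a1 == 0:
            infant = math.exp(params.a0) * x
        else:
            infant = math.exp(params.a0) / params.a1 * (-np.expm1(-params.a1 * x))
        H = H + params.c * x + infant
    return H


def survivorship(params: MortalityParams, age) -> np.ndarray:
    """Probability S(age) of surviving from birth to ``age``."""
    return np.exp(-cumulative_hazard(params, age))


def density(params: MortalityParams, age) -> np.ndarray:
    """Age-at-death density f(age) = mu(age) * S(age)."""
    return hazard(params, age) * survivorship(params, age)


def remaining_expectancy(params: MortalityParams, age: float = 0.0) -> float:
    """Expected remaining years of life at ``age``.

    e_x = int_age^inf S(t) dt / S(age), with the integral truncated at
    :data:`AGE_CAP` where survivorship mass is negligible.
    """
    x = float(_check_age(age))
    s_x = float(survivorship(params, x))
    if s_x <= 0.0 or not np.isfinite(s_x):
        raise ValueError(f"survivorship is zero at age {x}; e_x undefined")
    val, _ = integrate.quad(
        lambda t: float(np.exp(-(cumulative_hazard(params, t)
                                 - cumulative_hazard(params, x)))),
        x, AGE_CAP, limit=200,
    )
    return float(val)


def lifespan_quantile(params: MortalityParams, q: float) -> float:
    """Age by which a fraction ``q`` of a cohort has died (S(x) = 1 - q)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    target = -math.log1p(-q)  # H(x) at the quantile

    def g(x: float) -> float:
        return float(cumulative_hazard(params, x)) - target

    hi = AGE_CAP
    if g(hi) < 0:  # essentially immortal within the cap; report the cap
        return hi
    return float(optimize.brentq(g, 0.0, hi, xtol=1e-10))


def array_hazard(model: Model, shape: Shape, P: dict, x: np.ndarray) -> np.ndarray:
    """Hazard with array-valued parameters (broadcast against ``x``).

    ``P`` maps active parameter names to arrays; used by the MCMC
    machinery to evaluate many parameter draws at once.
    """
    if model is Model.EXPONENTIAL:
        h = np.broadcast_to(P["c"], np.broadcast_shapes(np.shape(P["c"]), x.shape)).copy()
        return h
    b0, b1 = P["b0"], P["b1"]
    if model is Model.GOMPERTZ:
        h = np.exp(b0 + b1 * x)
    elif model is Model.WEIBULL:
        with np.errstate(divide="ignore", invalid="ignore"):
            h = b0 * b1 * np.power(b1 * x, b0 - 1.0)
    else:  # logistic
        ebx = np.exp(b1 * x)
        h = np.exp(b0) * ebx / (1.0 + np.exp(b0) * (ebx - 1.0) / b1)
    if shape is Shape.MAKEHAM:
        h = h + P["c"]
    elif shape is Shape.BATHTUB:
        h = h + P["c"] + np.exp(P["a0"] - P["a1"] * x)
    return h


def array_cumhaz(model: Model, shape: Shape, P: dict, x: np.ndarray) -> np.ndarray:
    """Cumulative hazard with array-valued parameters (see array_hazard)."""
    if model is Model.EXPONENTIAL:
        return P["c"] * x
    b0, b1 = P["b0"], P["b1"]
    if model is Model.GOMPERTZ:
        H = np.exp(b0) / b1 * np.expm1(b1 * x)
    elif model is Model.WEIBULL:
        H = np.power(b1 * x, b0)
    else:
        H = np.log1p(np.exp(b0) * np.expm1(b1 * x) / b1)
    if shape is Shape.MAKEHAM:
        H = H + P["c"] * x
    elif shape is Shape.BATHTUB:
        H = H + P["c"] * x - np.exp(P["a0"]) / P["a1"] * np.expm1(-P["a1"] * x)
    return H


def sample_ages(
    params: MortalityParams,
    n: int,
    rng: np.random.Generator,
    min_age: float = 0.0,
) -> np.ndarray:
    """Draw ``n`` ages at death by inverse-CDF sampling.

    With ``min_age`` > 0 the draws are conditional on survival to that
    age (used for left-truncated founders).  Inversion of the cumulative
    hazard uses vectorised bisection on [min_age, AGE_CAP].
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    u = rng.uniform(size=n)
    base = float(cumulative_hazard(params, min_age))
    target = base - np.log1p(-u)  # H(x) = H(min_age) - log(1 - u)
    lo = np.full(n, float(min_age))
    hi = np.full(n, AGE_CAP)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = cumulative_hazard(params, mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)
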