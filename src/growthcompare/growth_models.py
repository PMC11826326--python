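"""Ten classical nonlinear growth functions as pure mathematical objects.

The registry covers the asymptotic and sigmoidal curves routinely used to
describe age-body-weight trajectories in poultry: Brody, negative
exponential, logistic, Gompertz, von Bertalanffy, Richards, Schumacher,
Morgan, Lomolino and Weibull.  Each model exposes

* ``evaluate``      -- body weight (g) at a given age (days),
* ``agr``           -- the analytic first derivative with respect to age,
                       i.e. the absolute growth rate (g/day),
* ``inflection_time`` -- the age of maximal growth rate, closed form where
                       one exists and a numeric maximiser otherwise,
* ``asymptote``     -- the mature-weight limit as age goes to infinity,
* ``initial_guess`` -- deterministic heuristic start values for fitting.

Parameter conventions follow the standard growth-curve literature:
``a`` is the asymptotic (mature) weight, ``b`` an integration constant
tied to the weight at the time origin, ``k`` the maturation rate, ``m``
the Richards shape parameter and ``ip`` the Weibull inflection age.
No positivity is imposed on ``a``, ``b`` or ``k``: published fits of the
Brody and negative exponential curves to duck data sit in sign-flipped
regions (a < 0, k < 0), and the fitting layer must be able to reach them.

Two of the curves are ambiguous in parts of the applied literature.  The
Schumacher and Morgan forms used here by default are the "derivative-like"
humps  a*b^2*k*(t+b)^(-2)*exp(b*k*t/(t+b))  and
a*b^k*k*t^(k-1)/(t^k+b^k)^2 , which are algebraically the first
derivatives of the sigmoids  a*exp(b*k*t/(t+b))  and the Hill curve
a*t^k/(t^k+b^k).  Both readings are available through the ``variant``
switch of :func:`get_model`; ``"printed"`` (the hump forms) is the
default, ``"sigmoid"`` selects the antiderivative sigmoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DomainError",
    "UnknownModelError",
    "GrowthModelSpec",
    "ParameterSet",
    "MODEL_NAMES",
    "get_model",
    "list_models",
    "make_params",
    "evaluate",
    "agr",
    "inflection_time",
    "asymptote",
    "initial_guess",
]

_EXP_MAX = 700.0  # exp argument cap; avoids overflow during optimizer excursions


class DomainError(ValueError):
    """Age outside a model's domain (e.g. t = 0 for Morgan/Lomolino)."""


class UnknownModelError(KeyError):
    """Model name not present in the registry."""


def _exp(x):
    return np.exp(np.minimum(x, _EXP_MAX))


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    """Named parameter values for one growth model.

    Exactly the parameters the model declares must be present.  For the
    Weibull curve the inflection-at-``ip`` identity requires ``k > 1``
    and ``ip > 0``; both are enforced at construction.
    """

    model: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        spec = get_model(self.model)
        object.__setattr__(self, "values", dict(self.values))
        expected = set(spec.parameter_names)
        got = set(self.values)
        if got != expected:
            raise ValueError(
                f"model {spec.name!r} needs parameters {sorted(expected)}, "
                f"got {sorted(got)}"
            )
        for name, v in self.values.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"parameter {name!r} is not finite: {v}")
        if spec.name == "weibull":
            if self.values["k"] <= 1:
                raise ValueError("weibull requires k > 1 (inflection at ip)")
            if self.values["ip"] <= 0:
                raise ValueError("weibull requires ip > 0")

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    def as_array(self) -> np.ndarray:
        """Parameter values in the model's declared order."""
        spec = get_model(self.model)
        return np.array([self.values[n] for n in spec.parameter_names], float)

    @classmethod
    def from_array(cls, model: str, x: Sequence[float]) -> "ParameterSet":
        spec = get_model(model)
        if len(x) != spec.p:
            raise ValueError(f"expected {spec.p} values for {model!r}, got {len(x)}")
        return cls(spec.name, dict(zip(spec.parameter_names, map(float, x))))


def make_params(model: str, **values: float) -> ParameterSet:
    """Convenience constructor: ``make_params("gompertz", a=..., b=..., k=...)``."""
    return ParameterSet(model, values)


# ---------------------------------------------------------------------------
# model spec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthModelSpec:
    """A named growth function with its calculus metadata."""

    name: str
    parameter_names: tuple[str, ...]
    has_closed_form_inflection: bool
    has_finite_asymptote: bool
    excludes_zero_age: bool = False
    variant: str = "printed"
    _evaluate: Callable = field(repr=False, default=None)
    _derivative: Callable = field(repr=False, default=None)
    _inflection: Callable = field(repr=False, default=None)
    _asymptote: Callable = field(repr=False, default=None)
    _guess: Callable = field(repr=False, default=None)

    @property
    def p(self) -> int:
        return len(self.parameter_names)


def _as_params_dict(spec: GrowthModelSpec, params) -> dict:
    if isinstance(params, ParameterSet):
        if params.model != spec.name:
            raise ValueError(
                f"parameter set is for {params.model!r}, not {spec.name!r}"
            )
        return dict(params.values)
    d = dict(params)
    missing = set(spec.parameter_names) - set(d)
    if missing:
        raise ValueError(f"missing parameter(s) {sorted(missing)} for {spec.name!r}")
    return d


def _check_domain(spec: GrowthModelSpec, t: np.ndarray) -> None:
    if np.any(t < 0):
        raise DomainError(f"{spec.name}: age must be >= 0")
    if spec.excludes_zero_age and np.any(t <= 0):
        raise DomainError(f"{spec.name}: age must be > 0 (singular at t = 0)")


# ---------------------------------------------------------------------------
# functional forms and analytic first derivatives
# ---------------------------------------------------------------------------
# Each pair of functions takes (t: ndarray, q: dict) and is fully vectorised.
# Invalid parameter regions (negative bases under fractional powers etc.)
# yield NaN/inf, which the fitting layer converts into a finite penalty.


def _brody(t, q):
    return q["a"] * (1.0 - q["b"] * _exp(-q["k"] * t))


def _brody_d(t, q):
    return q["a"] * q["b"] * q["k"] * _exp(-q["k"] * t)


def _negexp(t, q):
    return q["a"] * (1.0 - _exp(-q["k"] * t))


def _negexp_d(t, q):
    return q["a"] * q["k"] * _exp(-q["k"] * t)


def _logistic(t, q):
    return q["a"] / (1.0 + q["b"] * _exp(-q["k"] * t))


def _logistic_d(t, q):
    e = q["b"] * _exp(-q["k"] * t)
    return q["a"] * q["k"] * e / (1.0 + e) ** 2


def _gompertz(t, q):
    return q["a"] * _exp(-q["b"] * _exp(-q["k"] * t))


def _gompertz_d(t, q):
    e = _exp(-q["k"] * t)
    return q["a"] * q["b"] * q["k"] * e * _exp(-q["b"] * e)


def _vonbert(t, q):
    u = 1.0 - q["b"] * _exp(-q["k"] * t)
    return q["a"] * u**3


def _vonbert_d(t, q):
    e = _exp(-q["k"] * t)
    return 3.0 * q["a"] * q["b"] * q["k"] * e * (1.0 - q["b"] * e) ** 2


def _richards(t, q):
    u = 1.0 - q["b"] * _exp(-q["k"] * t)
    with np.errstate(invalid="ignore", divide="ignore"):
        return q["a"] * np.power(u, -1.0 / q["m"])


def _richards_d(t, q):
    e = _exp(-q["k"] * t)
    u = 1.0 - q["b"] * e
    with np.errstate(invalid="ignore", divide="ignore"):
        return -(q["a"] * q["b"] * q["k"] / q["m"]) * e * np.power(u, -1.0 / q["m"] - 1.0)


def _schumacher(t, q):
    a, b, k = q["a"], q["b"], q["k"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return a * b * b * k * (t + b) ** (-2.0) * _exp(b * k * t / (t + b))


def _schumacher_d(t, q):
    b, k = q["b"], q["k"]
    y = _schumacher(t, q)
    with np.errstate(invalid="ignore", divide="ignore"):
        return y * (b * b * k / (t + b) ** 2 - 2.0 / (t + b))


def _schumacher_sig(t, q):
    with np.errstate(invalid="ignore", divide="ignore"):
        return q["a"] * _exp(q["b"] * q["k"] * t / (t + q["b"]))


def _schumacher_sig_d(t, q):
    b, k = q["b"], q["k"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return _schumacher_sig(t, q) * b * b * k / (t + b) ** 2


def _morgan(t, q):
    a, b, k = q["a"], q["b"], q["k"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return a * b**k * k * t ** (k - 1.0) / (t**k + b**k) ** 2


def _morgan_d(t, q):
    b, k = q["b"], q["k"]
    y = _morgan(t, q)
    with np.errstate(invalid="ignore", divide="ignore"):
        return y * ((k - 1.0) / t - 2.0 * k * t ** (k - 1.0) / (t**k + b**k))


def _morgan_sig(t, q):
    a, b, k = q["a"], q["b"], q["k"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return a * t**k / (t**k + b**k)


def _morgan_sig_d(t, q):
    a, b, k = q["a"], q["b"], q["k"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return a * k * t ** (k - 1.0) * b**k / (t**k + b**k) ** 2


_LN10 = math.log(10.0)


def _lomolino(t, q):
    a, b, k = q["a"], q["b"], q["k"]
    with np.errstate(invalid="ignore", divide="ignore"):
        big = np.power(b, np.log10(k / t))
        return a / (1.0 + big)


def _lomolino_d(t, q):
    a, b, k = q["a"], q["b"], q["k"]
    with np.errstate(invalid="ignore", divide="ignore"):
        big = np.power(b, np.log10(k / t))
        return a * big * np.log(b) / (t * _LN10 * (1.0 + big) ** 2)


def _weibull(t, q):
    a, b, k, ip = q["a"], q["b"], q["k"], q["ip"]
    c = (k - 1.0) / k
    with np.errstate(invalid="ignore", divide="ignore"):
        return a - (a - b) * _exp(-c * (t / ip) ** k)


def _weibull_d(t, q):
    a, b, k, ip = q["a"], q["b"], q["k"], q["ip"]
    c = (k - 1.0) / k
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (t / ip) ** k
        return (a - b) * c * (k / ip) * (t / ip) ** (k - 1.0) * _exp(-c * z)


# ---------------------------------------------------------------------------
# closed-form inflection times (None -> caller falls back to numeric search)
# ---------------------------------------------------------------------------


def _infl_log_bk(q):
    if q["b"] > 0 and q["k"] != 0:
        t = math.log(q["b"]) / q["k"]
        return t if t > 0 else None
    return None


def _infl_vonbert(q):
    if q["b"] > 0 and q["k"] != 0:
        t = math.log(3.0 * q["b"]) / q["k"]
        return t if t > 0 else None
    return None


def _infl_weibull(q):
    # d/dt log y' = (k-1)/t - (k-1) t^(k-1)/ip^k  vanishes exactly at t = ip
    return q["ip"] if q["k"] > 1 else None


# ---------------------------------------------------------------------------
# asymptotes (limit of evaluate as t -> infinity; None if divergent)
# ---------------------------------------------------------------------------


def _asym_saturating(q):
    # brody / negative exponential: a(1 - b e^{-kt}) family
    k = q["k"]
    if k > 0:
        return q["a"]
    if k == 0:
        return q["a"] * (1.0 - q.get("b", 1.0))
    return None


def _asym_a_if_k_pos(q):
    return q["a"] if q["k"] > 0 else None


def _asym_lomolino(q):
    if q["b"] > 1:
        return q["a"]
    if q["b"] == 1:
        return q["a"] / 2.0
    return 0.0  # b in (0, 1): b^(log10(k/t)) diverges, y -> 0


def _asym_zero(q):
    return 0.0  # hump-shaped derivative forms decay to zero


def _asym_weibull(q):
    return q["a"]


def _asym_schumacher_sig(q):
    return q["a"] * math.exp(min(q["b"] * q["k"], _EXP_MAX))


def _asym_morgan_sig(q):
    return q["a"] if q["k"] > 0 else None


# ---------------------------------------------------------------------------
# initial-guess heuristics (deterministic in the data)
# ---------------------------------------------------------------------------


def _safe_log_ratio(z1: float, z2: float, dt: float, default: float) -> float:
    """Slope of ln z between two points, with a fallback for bad values."""
    if z1 > 0 and z2 > 0 and dt > 0:
        return (math.log(z1) - math.log(z2)) / dt
    return default


def _guess_a(w: np.ndarray) -> float:
    m = float(np.max(w))
    return 1.2 * m if m > 0 else 1.0


def _guess_brody(t, w):
    a = _guess_a(w)
    z = np.clip(1.0 - w / a, 1e-6, None)
    k = _safe_log_ratio(z[0], z[-1], t[-1] - t[0], 0.05)
    k = float(np.clip(k, 1e-4, 2.0))
    b = float(np.clip(z[0] * math.exp(k * t[0]), 1e-3, 1e3))
    return {"a": a, "b": b, "k": k}


def _guess_negexp(t, w):
    a = _guess_a(w)
    z = np.clip(1.0 - w / a, 1e-6, None)
    k = _safe_log_ratio(z[0], z[-1], t[-1] - t[0], 0.05)
    return {"a": a, "k": float(np.clip(k, 1e-4, 2.0))}


def _guess_logistic(t, w):
    a = _guess_a(w)
    z = np.clip(a / np.clip(w, 1e-9, None) - 1.0, 1e-6, None)
    k = _safe_log_ratio(z[0], z[-1], t[-1] - t[0], 0.1)
    k = float(np.clip(k, 1e-3, 2.0))
    b = float(np.clip(z[0] * math.exp(k * t[0]), 1e-2, 1e4))
    return {"a": a, "b": b, "k": k}


def _guess_gompertz(t, w):
    a = _guess_a(w)
    z = np.log(np.clip(a / np.clip(w, 1e-9, None), 1.0 + 1e-9, None))
    k = _safe_log_ratio(z[0], z[-1], t[-1] - t[0], 0.08)
    k = float(np.clip(k, 1e-3, 2.0))
    b = float(np.clip(z[0] * math.exp(k * t[0]), 1e-2, 1e3))
    return {"a": a, "b": b, "k": k}


def _guess_vonbert(t, w):
    a = _guess_a(w)
    z = np.clip(1.0 - np.cbrt(np.clip(w, 0.0, None) / a), 1e-6, None)
    k = _safe_log_ratio(z[0], z[-1], t[-1] - t[0], 0.05)
    k = float(np.clip(k, 1e-4, 2.0))
    b = float(np.clip(z[0] * math.exp(k * t[0]), 1e-3, 1e2))
    return {"a": a, "b": b, "k": k}


def _guess_richards(t, w):
    g = _guess_gompertz(t, w)
    # negative b with exponent -1/m gives an increasing curve rising to a
    return {"a": g["a"], "b": -1.0, "k": g["k"], "m": 0.3}


def _guess_schumacher(t, w):
    b = float(max(t[-1] / 2.0, 1.0))
    k = 0.5
    tn, wn = float(t[-1]), float(max(w[-1], 1e-6))
    a = wn * (tn + b) ** 2 * math.exp(-b * k * tn / (tn + b)) / (b * b * k)
    return {"a": a, "b": b, "k": k}


def _guess_morgan(t, w):
    b = float(max(t[-1], 1.0))
    k = 2.5
    i = int(np.argmax(w))
    ti, wi = float(max(t[i], 1e-6)), float(max(w[i], 1e-6))
    a = wi * (ti**k + b**k) ** 2 / (b**k * k * ti ** (k - 1.0))
    return {"a": a, "b": b, "k": k}


def _guess_lomolino(t, w):
    a = _guess_a(w)
    # k is the age at half-asymptote for this form
    half = a / 2.0
    above = np.nonzero(w >= half)[0]
    k = float(t[above[0]]) if above.size else float(t[-1])
    k = max(k, float(t[0]) * 1.01 if t[0] > 0 else 1.0)
    l1 = math.log10(k / t[0]) if t[0] > 0 else 1.0
    w1 = float(max(w[0], 1e-6))
    if abs(l1) > 1e-6 and a / w1 > 1:
        b = (a / w1 - 1.0) ** (1.0 / l1)
        b = float(np.clip(b, 1.01, 1e4))
    else:
        b = 50.0
    return {"a": a, "b": b, "k": k}


def _guess_weibull(t, w):
    a = _guess_a(w)
    b = float(w[0])  # curve value at t = 0 equals b
    diffs = np.diff(w) / np.diff(t)
    i = int(np.argmax(diffs))
    ip = float((t[i] + t[i + 1]) / 2.0)
    return {"a": a, "b": b, "k": 2.0, "ip": max(ip, 1.0)}


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def _spec(name, pnames, evalf, derivf, inflf, asymf, guessf, *, closed_infl,
          finite_asym, excl_zero=False, variant="printed"):
    return GrowthModelSpec(
        name=name,
        parameter_names=tuple(pnames),
        has_closed_form_inflection=closed_infl,
        has_finite_asymptote=finite_asym,
        excludes_zero_age=excl_zero,
        variant=variant,
        _evaluate=evalf,
        _derivative=derivf,
        _inflection=inflf,
        _asymptote=asymf,
        _guess=guessf,
    )


_REGISTRY: dict[str, GrowthModelSpec] = {
    s.name: s
    for s in [
        _spec("brody", ("a", "b", "k"), _brody, _brody_d, None,
              _asym_saturating, _guess_brody, closed_infl=False, finite_asym=True),
        _spec("negative_exponential", ("a", "k"), _negexp, _negexp_d, None,
              _asym_saturating, _guess_negexp, closed_infl=False, finite_asym=True),
        _spec("logistic", ("a", "b", "k"), _logistic, _logistic_d, _infl_log_bk,
              _asym_a_if_k_pos, _guess_logistic, closed_infl=True, finite_asym=True),
        _spec("gompertz", ("a", "b", "k"), _gompertz, _gompertz_d, _infl_log_bk,
              _asym_a_if_k_pos, _guess_gompertz, closed_infl=True, finite_asym=True),
        _spec("von_bertalanffy", ("a", "b", "k"), _vonbert, _vonbert_d, _infl_vonbert,
              _asym_a_if_k_pos, _guess_vonbert, closed_infl=True, finite_asym=True),
        _spec("richards", ("a", "b", "k", "m"), _richards, _richards_d, None,
              _asym_a_if_k_pos, _guess_richards, closed_infl=False, finite_asym=True),
        _spec("schumacher", ("a", "b", "k"), _schumacher, _schumacher_d, None,
              _asym_zero, _guess_schumacher, closed_infl=False, finite_asym=True),
        _spec("morgan", ("a", "b", "k"), _morgan, _morgan_d, None,
              _asym_zero, _guess_morgan, closed_infl=False, finite_asym=True,
              excl_zero=True),
        _spec("lomolino", ("a", "b", "k"), _lomolino, _lomolino_d, None,
              _asym_lomolino, _guess_lomolino, closed_infl=False, finite_asym=True,
              excl_zero=True),
        _spec("weibull", ("a", "b", "k", "ip"), _weibull, _weibull_d, _infl_weibull,
              _asym_weibull, _guess_weibull, closed_infl=True, finite_asym=True),
    ]
}

MODEL_NAMES: tuple[str, ...] = tuple(_REGISTRY)

_VARIANTS: dict[tuple[str, str], GrowthModelSpec] = {
    ("schumacher", "sigmoid"): _spec(
        "schumacher", ("a", "b", "k"), _schumacher_sig, _schumacher_sig_d, None,
        _asym_schumacher_sig, _guess_schumacher, closed_infl=False,
        finite_asym=True, variant="sigmoid"),
    ("morgan", "sigmoid"): _spec(
        "morgan", ("a", "b", "k"), _morgan_sig, _morgan_sig_d, None,
        _asym_morgan_sig, _guess_morgan, closed_infl=False, finite_asym=True,
        excl_zero=True, variant="sigmoid"),
}


def get_model(model, variant: str | None = None) -> GrowthModelSpec:
    """Resolve a model name (or pass a spec through) to a :class:`GrowthModelSpec`.

    ``variant="sigmoid"`` selects the antiderivative reading of the
    Schumacher and Morgan curves; it is invalid for any other model.
    """
    if isinstance(model, GrowthModelSpec):
        return model
    name = str(model)
    if name not in _REGISTRY:
        raise UnknownModelError(
            f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
        )
    if variant in (None, "printed"):
        return _REGISTRY[name]
    key = (name, variant)
    if key not in _VARIANTS:
        raise UnknownModelError(f"no variant {variant!r} for model {name!r}")
    return _VARIANTS[key]


def list_models() -> list[str]:
    return list(MODEL_NAMES)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def evaluate(model, params, age):
    """Body weight (g) at ``age`` (days). Vectorised over ``age``."""
    spec = get_model(model)
    q = _as_params_dict(spec, params)
    t = np.asarray(age, dtype=float)
    _check_domain(spec, t)
    out = spec._evaluate(t, q)
    return float(out) if np.isscalar(age) or t.ndim == 0 else out


def agr(model, params, age):
    """Absolute growth rate (g/day): analytic d(weight)/d(age)."""
    spec = get_model(model)
    q = _as_params_dict(spec, params)
    t = np.asarray(age, dtype=float)
    _check_domain(spec, t)
    out = spec._derivative(t, q)
    return float(out) if np.isscalar(age) or t.ndim == 0 else out


def _numeric_inflection(spec, q, lo=0.01, hi=500.0):
    ts = np.linspace(lo, hi, 4001)
    with np.errstate(all="ignore"):
        vals = spec._derivative(ts, q)
    vals = np.where(np.isfinite(vals), vals, -np.inf)
    i = int(np.argmax(vals))
    if not np.isfinite(vals[i]) or i == 0 or i == len(ts) - 1:
        return None  # AGR is monotone on the bracket: no interior inflection
    res = minimize_scalar(
        lambda x: -spec._derivative(np.asarray(x, float), q),
        bounds=(ts[i - 1], ts[i + 1]),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def inflection_time(model, params):
    """Age (days) of maximal growth rate, or ``None`` if the AGR is monotone.

    Closed forms: gompertz and logistic ln(b)/k, von Bertalanffy ln(3b)/k,
    Weibull exactly its ``ip`` parameter.  Brody and the negative
    exponential have no interior inflection.  The remaining models (and
    closed-form models whose parameters leave the closed form undefined)
    use a bounded numeric maximiser of the AGR.
    """
    spec = get_model(model)
    q = _as_params_dict(spec, params)
    if spec.variant == "printed" and spec.name in ("brody", "negative_exponential"):
        return None
    if spec._inflection is not None:
        t = spec._inflection(q)
        if t is not None:
            return float(t)
    return _numeric_inflection(spec, q)


def asymptote(model, params):
    """Mature-weight limit as age -> infinity, or ``None`` when divergent."""
    spec = get_model(model)
    q = _as_params_dict(spec, params)
    v = spec._asymptote(q)
    return None if v is None else float(v)


def initial_guess(dataset, model) -> ParameterSet:
    """Deterministic heuristic start values for nonlinear fitting.

    ``dataset`` is anything exposing ``ages`` and ``weights`` arrays (or a
    pair of sequences).  Requires at least p + 1 observations.
    """
    spec = get_model(model)
    if hasattr(dataset, "ages"):
        t = np.asarray(dataset.ages, float)
        w = np.asarray(dataset.weights, float)
    else:
        t, w = (np.asarray(x, float) for x in dataset)
    if len(t) < spec.p + 1:
        raise ValueError(
            f"need at least {spec.p + 1} observations to start {spec.name!r}, "
            f"got {len(t)}"
        )
    return ParameterSet(spec.name, spec._guess(t, w))
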