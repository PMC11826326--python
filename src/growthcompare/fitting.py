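"""Nonlinear least-squares estimation of growth-curve parameters.

One weight per age per group is the canonical input (breed-mean
trajectories measured at a handful of ages), so every fit here is a small
dense problem: n of order 10, p of 2-4.  Estimation is damped least
squares (Levenberg-Marquardt) with a deterministic heuristic start plus
seeded multiplicative log-normal restarts; the lowest-RSS solution wins.
Multi-start matters because several published optima for the Brody and
negative-exponential curves sit in sign-flipped (a < 0, k < 0) parameter
regions that a naive saturating-curve start never reaches.

Asymptotic standard errors come from the Jacobian at the optimum,
``RSS/(n-p) * inv(J'J)``, and are reported as unavailable when J'J is
numerically singular.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .growth_models import (
    GrowthModelSpec,
    ParameterSet,
    get_model,
)

__all__ = ["GrowthDataset", "FitConfig", "FitResult", "fit", "predict_curve"]

_PENALTY = 1e8  # stands in for non-finite residuals during optimisation


@dataclass(frozen=True)
class GrowthDataset:
    """Ordered (age, weight) observations for one group.

    Ages are strictly increasing and non-negative; at least three
    observations are required.  Weights must be finite but may be
    negative (some published curves predict negative early weights).
    """

    group: str
    ages: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.ages, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if t.ndim != 1 or w.ndim != 1 or len(t) != len(w):
            raise ValueError("ages and weights must be 1-D and equally long")
        if len(t) < 3:
            raise ValueError("need at least 3 observations")
        if np.any(t < 0):
            raise ValueError("ages must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("ages must be strictly increasing (no duplicates)")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "ages", t)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.ages)

    @classmethod
    def from_observations(cls, group: str, observations: Sequence[tuple]) -> "GrowthDataset":
        obs = sorted((float(a), float(w)) for a, w in observations)
        ages = np.array([a for a, _ in obs])
        weights = np.array([w for _, w in obs])
        return cls(group, ages, weights)


@dataclass(frozen=True)
class FitConfig:
    """Solver settings for :func:`fit`.

    Tolerances are tight (1e-10) because the problems are tiny; 16
    restarts with log-normal jitter (sd 0.5 on the log scale, sign
    preserved) is enough to find sign-flipped optima reliably.
    """

    max_iter: int = 400
    ftol: float = 1e-10
    xtol: float = 1e-10
    restarts: int = 16
    seed: int = 20250214
    jitter_sd: float = 0.5
    bounds: Mapping[str, tuple] | None = None  # model name -> (lower, upper) arrays
    variants: Mapping[str, str] = field(default_factory=dict)  # model -> variant

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.ftol <= 0 or self.xtol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class FitResult:
    """Best solution for one model on one dataset."""

    model: str
    group: str
    params: ParameterSet
    stderr: dict | None  # parameter name -> SE, or None when J'J singular
    rss: float
    n: int
    p: int
    converged: bool
    best_restart: int
    residuals: np.ndarray  # observed - predicted, in age order

    @property
    def rmse_df(self) -> float:
        """sqrt(RSS / (n - p)); the degrees-of-freedom RMSE."""
        return math.sqrt(self.rss / (self.n - self.p))


def _initial_guess_from(dataset, spec):
    from .growth_models import initial_guess

    return initial_guess(dataset, spec).as_array()


def _accelerating(t: np.ndarray, w: np.ndarray) -> bool:
    """True when the last-interval slope exceeds the first-interval slope."""
    s_first = (w[1] - w[0]) / (t[1] - t[0])
    s_last = (w[-1] - w[-2]) / (t[-1] - t[-2])
    return s_last > s_first


def _exponential_branch_start(spec: GrowthModelSpec, t, w):
    """Start in the (a < 0, k < 0) exponential-growth regime.

    Published Brody / negative-exponential fits to still-accelerating
    weight data live here: y = a - a*b*e^{|k|t} with a < 0 grows without
    bound, which is what convex-to-the-end data ask for.
    """
    pos = np.nonzero(w > 0)[0]
    if len(pos) < 2:
        return None
    j1, j2 = pos[-2], pos[-1]
    k = -(math.log(w[j2]) - math.log(w[j1])) / (t[j2] - t[j1])
    if k >= 0:
        k = -0.005
    a = -3.0 * float(np.max(w))
    if spec.name == "negative_exponential":
        return np.array([a, k])
    b = (1.0 - w[j2] / a) * math.exp(k * t[j2])
    return np.array([a, b, k])


def _residual_fn(spec, t, w):
    kpos = spec.name == "weibull" and "k" in spec.parameter_names

    def resid(x):
        q = dict(zip(spec.parameter_names, x))
        if kpos and q["k"] <= 1.0:  # keep the inflection-at-ip identity valid
            return np.full_like(w, _PENALTY)
        with np.errstate(all="ignore"):
            pred = spec._evaluate(t, q)
        r = pred - w
        bad = ~np.isfinite(r)
        if bad.any():
            r = np.where(bad, _PENALTY, r)
        return r

    return resid


def _standard_errors(jac, rss, n, p, names):
    try:
        jtj = jac.T @ jac
        if not np.all(np.isfinite(jtj)) or np.linalg.cond(jtj) > 1e12:
            return None
        cov = rss / (n - p) * np.linalg.inv(jtj)
        diag = np.diag(cov)
        if np.any(diag < 0):
            return None
        return dict(zip(names, np.sqrt(diag)))
    except np.linalg.LinAlgError:
        return None


def fit(dataset: GrowthDataset, model, config: FitConfig | None = None) -> FitResult:
    """Fit one growth model to a dataset by multi-start least squares.

    Returns the lowest-RSS solution over the heuristic start, an optional
    deterministic exponential-branch start (Brody/negative exponential on
    still-accelerating data), and seeded log-normal perturbations of
    those.  Never raises on numerical failure: if no restart converges,
    the best attempt is returned with ``converged=False``.
    """
    config = config or FitConfig()
    spec = get_model(model, config.variants.get(str(getattr(model, "name", model))))
    t, w = dataset.ages, dataset.weights
    n, p = dataset.n, spec.p
    if n <= p:
        raise ValueError(f"need n > p observations ({n} <= {p}) to fit {spec.name!r}")
    if spec.excludes_zero_age and np.any(t <= 0):
        raise ValueError(f"{spec.name!r} is undefined at age 0; drop the t=0 row")

    base_starts = [_initial_guess_from(dataset, spec)]
    if spec.name in ("brody", "negative_exponential") and _accelerating(t, w):
        alt = _exponential_branch_start(spec, t, w)
        if alt is not None:
            base_starts.append(alt)

    resid = _residual_fn(spec, t, w)
    if config.bounds and spec.name in config.bounds:
        lo, hi = config.bounds[spec.name]
        method, bounds = "trf", (np.asarray(lo, float), np.asarray(hi, float))
    else:
        method, bounds = "lm", (-np.inf, np.inf)

    rng = np.random.default_rng(config.seed)
    best = None
    for i in range(config.restarts):
        base = base_starts[i % len(base_starts)]
        if i < len(base_starts):
            x0 = base.copy()
        else:
            x0 = base * np.exp(rng.normal(0.0, config.jitter_sd, size=p))
        if method == "trf":
            x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = least_squares(
                    resid, x0, method=method, bounds=bounds if method == "trf" else (-np.inf, np.inf),
                    ftol=config.ftol, xtol=config.xtol, gtol=1e-12,
                    max_nfev=config.max_iter * (p + 1),
                )
        except (ValueError, np.linalg.LinAlgError):
            continue
        r = resid(res.x)
        if np.any(np.abs(r) >= _PENALTY):
            continue
        rss = float(np.dot(r, r))
        ok = bool(res.status > 0)
        if best is None or rss < best[0] - 1e-15 * max(best[0], 1.0):
            best = (rss, res, ok, i)

    if best is None:
        # every attempt blew up; report the heuristic start, unconverged
        x = base_starts[0]
        params = ParameterSet.from_array(spec.name, x)
        r = resid(x)
        r = np.where(np.isfinite(r), r, np.nan)
        return FitResult(spec.name, dataset.group, params, None,
                         float(np.nansum(r * r)), n, p, False, -1, -r)

    rss, res, ok, idx = best
    params = ParameterSet.from_array(spec.name, res.x)
    r = resid(res.x)  # predicted - observed
    stderr = _standard_errors(res.jac, rss, n, p, spec.parameter_names)
    return FitResult(
        model=spec.name,
        group=dataset.group,
        params=params,
        stderr=stderr,
        rss=rss,
        n=n,
        p=p,
        converged=ok,
        best_restart=idx,
        residuals=-r,  # observed - predicted, age order
    )


def predict_curve(fit_result: FitResult, ages) -> list[tuple[float, float]]:
    """Evaluate the fitted curve at the given ages; order preserved."""
    from .growth_models import evaluate

    ages = list(ages)
    if not ages:
        return []
    pred = evaluate(fit_result.model, fit_result.params, np.asarray(ages, float))
    return [(float(a), float(y)) for a, y in zip(ages, np.atleast_1d(pred))]
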