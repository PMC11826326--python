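"""Synthetic age-weight datasets with the structure the analysis assumes.

The study design being emulated is a breed-mean growth trajectory: one
weight per age at 1, 7, 14, 21, 28, 35, 42 and 49 days.  Datasets are
drawn as ``weight(age) = curve(age) + noise`` from any registry model;
the default generator is the Gompertz curve with the published Danish
Pekin parameters, so fixtures numerically resemble real meat-duck data.
Noise is additive Gaussian (default sd 20 g) or proportional
(coefficient of variation), seeded and reproducible.

``recovery_experiment`` wraps the standard simulate-refit loop: estimator
bias/RMSE for the generating model's parameters and, optionally, how
often the RSS-form AIC picks the generating model out of a candidate
set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fitting import FitConfig, FitResult, GrowthDataset, fit
from .growth_models import ParameterSet, evaluate, get_model, make_params
from .model_selection import aic
from .presets import OBSERVATION_AGES, preset_params

__all__ = ["SimConfig", "simulate_dataset", "recovery_experiment", "RecoverySummary"]


def _default_params() -> ParameterSet:
    return preset_params("danish", "gompertz")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for :func:`simulate_dataset`.

    ``sd`` is the additive Gaussian noise standard deviation in grams;
    set ``cv`` (e.g. 0.05) to use proportional noise instead, in which
    case ``sd`` is ignored.  ``clip_negative`` replaces negative draws by
    0.1 g with a warning — disable when simulating from curves that are
    legitimately negative early (sign-flipped Brody fits).
    """

    model: str = "gompertz"
    params: ParameterSet = field(default_factory=_default_params)
    ages: tuple = OBSERVATION_AGES
    sd: float = 20.0
    cv: float | None = None
    replicates: int = 1
    seed: int = 20250214
    clip_negative: bool = True
    group: str = "sim"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.cv is not None and self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        ages = tuple(float(a) for a in self.ages)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")
        if self.params.model != get_model(self.model).name:
            raise ValueError(
                f"params are for {self.params.model!r}, not {self.model!r}"
            )


def simulate_dataset(config: SimConfig) -> list[GrowthDataset]:
    """Draw ``config.replicates`` datasets; deterministic given the seed."""
    ages = np.asarray(config.ages, dtype=float)
    mean = np.asarray(evaluate(config.model, config.params, ages), dtype=float)
    rng = np.random.default_rng(config.seed)
    out = []
    clipped = 0
    for r in range(config.replicates):
        if config.cv is not None:
            noise = rng.normal(0.0, 1.0, size=len(ages)) * config.cv * np.abs(mean)
        else:
            noise = rng.normal(0.0, config.sd, size=len(ages))
        w = mean + noise
        if config.clip_negative:
            neg = w < 0
            clipped += int(neg.sum())
            w = np.where(neg, 0.1, w)
        label = config.group if config.replicates == 1 else f"{config.group}_{r:03d}"
        out.append(GrowthDataset(label, ages, w))
    if clipped:
        warnings.warn(f"clipped {clipped} negative simulated weight(s) to 0.1 g")
    return out


@dataclass(frozen=True)
class RecoverySummary:
    """Simulate-refit summary over replicates."""

    model: str
    replicates: int
    true_params: ParameterSet
    bias: dict            # parameter -> mean(estimate - true)
    relative_rmse: dict   # parameter -> rmse(estimate)/|true|
    median_abs_rel_error: dict  # parameter -> median |est/true - 1|
    selection_frequency: float | None  # generating model ranked first by AIC
    n_failed: int


def recovery_experiment(
    sim: SimConfig,
    fitcfg: FitConfig | None = None,
    candidates: Sequence[str] | None = None,
) -> RecoverySummary:
    """Fit the generating model (and optional candidates) to each replicate.

    Fit failures are counted, never raised.  Selection frequency is the
    fraction of replicates in which the RSS-form AIC ranks the generating
    model strictly first among ``candidates`` (which should include it).
    """
    if sim.replicates < 2:
        raise ValueError("recovery_experiment needs replicates >= 2")
    fitcfg = fitcfg or FitConfig()
    spec = get_model(sim.model)
    true = sim.params
    datasets = simulate_dataset(sim)

    estimates: list[ParameterSet] = []
    wins = 0
    comparisons = 0
    failed = 0
    for ds in datasets:
        try:
            res = fit(ds, spec, fitcfg)
        except (ValueError, FloatingPointError):
            failed += 1
            continue
        if not res.converged:
            failed += 1
        estimates.append(res.params)
        if candidates:
            aics = {}
            for name in candidates:
                r = res if name == spec.name else None
                if r is None:
                    try:
                        r = fit(ds, name, fitcfg)
                    except (ValueError, FloatingPointError):
                        continue
                if r.rss > 0:
                    aics[name] = aic(r.rss, r.n, r.p)
                else:
                    aics[name] = -math.inf
            if aics:
                comparisons += 1
                best = min(aics, key=aics.get)
                if best == spec.name:
                    wins += 1

    bias = {}
    rel_rmse = {}
    med_abs = {}
    for name in spec.parameter_names:
        tv = true[name]
        ests = np.array([e[name] for e in estimates]) if estimates else np.array([])
        if ests.size:
            bias[name] = float(np.mean(ests - tv))
            rel_rmse[name] = float(np.sqrt(np.mean((ests - tv) ** 2)) / abs(tv))
            med_abs[name] = float(np.median(np.abs(ests / tv - 1.0)))
        else:
            bias[name] = rel_rmse[name] = med_abs[name] = math.nan

    return RecoverySummary(
        model=spec.name,
        replicates=sim.replicates,
        true_params=true,
        bias=bias,
        relative_rmse=rel_rmse,
        median_abs_rel_error=med_abs,
        selection_frequency=(wins / comparisons) if candidates and comparisons else None,
        n_failed=failed,
    )
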