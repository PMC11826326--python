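"""Goodness-of-fit statistics and model ranking for growth-curve fits.

The statistic suite is the one conventional in comparative growth-curve
studies on small per-age-mean datasets:

* adjusted R^2            1 - ((n-1)/(n-p)) (1 - R^2),  R^2 = 1 - RSS/TSS
* RMSE                    sqrt(RSS / (n - p))   (a literal n - p - 1
                          denominator is available via ``ddof``)
* Durbin-Watson           sum (e_t - e_{t-1})^2 / sum e_t^2, on residuals
                          in age order; ~2 means no first-order
                          autocorrelation, ->0 positive, ->4 negative
* AIC (RSS form)          n ln(RSS) + 2p
* BIC (RSS form)          n ln(RSS/n) + p ln(n)

Note the deliberate asymmetry between the AIC and BIC conventions (RSS
vs RSS/n inside the log): this is the pairing used in the applied
literature these statistics are compared against, and the two differ
only by the model-independent constant n ln(n), so rankings agree.

Ranking is ascending AIC with deterministic tie-breaks (BIC, then RMSE,
then name); models whose fits failed are ranked last and flagged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult, GrowthDataset

__all__ = [
    "adjusted_r2",
    "rmse",
    "durbin_watson",
    "aic",
    "bic",
    "gof_from_rmse",
    "classify_dw",
    "rank_models",
    "RankedModel",
    "GofReport",
    "compute_gof",
]


def adjusted_r2(rss: float, tss: float, n: int, p: int) -> float:
    """Adjusted coefficient of determination; 1 iff the fit is perfect."""
    if n <= p:
        raise ValueError("requires n > p")
    if tss <= 0:
        raise ValueError("requires tss > 0")
    r2 = 1.0 - rss / tss
    return 1.0 - (n - 1) / (n - p) * (1.0 - r2)


def rmse(rss: float, n: int, p: int, *, ddof: str = "n-p") -> float:
    """Root mean square error of a fit, sqrt(RSS / df).

    ``ddof="n-p"`` (default) is the convention that published AIC/BIC
    tables in this literature are internally consistent with;
    ``ddof="n-p-1"`` gives the occasionally-printed literal formula.
    """
    df = {"n-p": n - p, "n-p-1": n - p - 1}[ddof]
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    return math.sqrt(rss / df)


def durbin_watson(residuals) -> float:
    """First-order residual autocorrelation statistic, in [0, 4].

    Residuals must be in age (time) order and not all zero.
    """
    e = np.asarray(list(residuals), dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(np.dot(e, e))
    if denom == 0.0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    num = float(np.sum(np.diff(e) ** 2))
    return num / denom


def classify_dw(dw: float) -> str:
    """Descriptive autocorrelation band: 'positive', 'none' or 'negative'.

    Bands: dw <= 1.5 positive, dw > 2.5 negative, otherwise none.
    """
    if dw <= 1.5:
        return "positive"
    if dw > 2.5:
        return "negative"
    return "none"


def aic(rss: float, n: int, p: int) -> float:
    """RSS-form Akaike information criterion, n ln(RSS) + 2p."""
    if rss <= 0:
        raise ValueError("requires rss > 0")
    return n * math.log(rss) + 2 * p


def bic(rss: float, n: int, p: int) -> float:
    """RSS-form Bayesian information criterion, n ln(RSS/n) + p ln(n)."""
    if rss <= 0:
        raise ValueError("requires rss > 0")
    if n < 1:
        raise ValueError("requires n >= 1")
    return n * math.log(rss / n) + p * math.log(n)


def gof_from_rmse(rmse_value: float, n: int, p: int, *, ddof: str = "n-p"):
    """Invert a reported RMSE back to (rss, aic, bic).

    Useful for regenerating information-criterion tables from published
    RMSE cells when the raw data are unavailable.
    """
    if rmse_value <= 0:
        raise ValueError("requires rmse > 0")
    df = {"n-p": n - p, "n-p-1": n - p - 1}[ddof]
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    rss = rmse_value**2 * df
    return rss, aic(rss, n, p), bic(rss, n, p)


class RankedModel(NamedTuple):
    name: str
    failed: bool
    tied: bool


def rank_models(stats: Mapping[str, Mapping[str, float]]) -> list[RankedModel]:
    """Order models ascending by AIC; ties broken by BIC, RMSE, then name.

    ``stats`` maps model name to a mapping with keys ``aic``, ``bic``,
    ``rmse`` and optionally ``converged``.  Models that failed (non-finite
    statistics or ``converged`` False) are ranked after all successful
    ones and flagged.
    """
    if not stats:
        raise ValueError("no models to rank")

    def key_of(s):
        return (float(s.get("aic", math.inf)),
                float(s.get("bic", math.inf)),
                float(s.get("rmse", math.inf)))

    def failed(s):
        k = key_of(s)
        # NaN or +inf marks a failed fit; -inf (perfect fit) is legitimate
        bad = any(math.isnan(v) or v == math.inf for v in k)
        return bad or not s.get("converged", True)

    entries = sorted(
        stats.items(), key=lambda kv: (failed(kv[1]), *key_of(kv[1]), kv[0])
    )
    keys = [(failed(s), key_of(s)) for _, s in entries]
    out = []
    for i, (name, s) in enumerate(entries):
        tied = (i > 0 and keys[i] == keys[i - 1]) or (
            i + 1 < len(keys) and keys[i] == keys[i + 1]
        )
        out.append(RankedModel(name, failed(s), tied))
    return out


_STAT_ROWS = ("r2_adj", "dw", "rmse", "aic", "bic")


@dataclass(frozen=True)
class GofReport:
    """Goodness-of-fit table (statistics x models) and ranking for one group."""

    group: str
    n: int
    p: dict
    stats: dict  # model -> {r2_adj, dw, rmse, aic, bic, converged}
    ranking: list

    @property
    def best(self) -> str:
        return self.ranking[0].name

    def to_frame(self) -> pd.DataFrame:
        """Statistics-by-model table in conventional report layout."""
        cols = [r.name for r in self.ranking]
        data = {m: [self.stats[m].get(s, math.nan) for s in _STAT_ROWS] for m in cols}
        return pd.DataFrame(data, index=list(_STAT_ROWS))

    def to_json(self) -> str:
        payload = {
            "group": self.group,
            "n": self.n,
            "p": self.p,
            "stats": self.stats,
            "ranking": [r._asdict() for r in self.ranking],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def compute_gof(dataset: GrowthDataset, fits: Iterable[FitResult]) -> GofReport:
    """Assemble the full statistic suite and ranking for a set of fits."""
    fits = list(fits)
    w = dataset.weights
    tss = float(np.sum((w - w.mean()) ** 2))
    stats: dict[str, dict] = {}
    for f in fits:
        entry: dict = {"converged": bool(f.converged)}
        try:
            entry["r2_adj"] = adjusted_r2(f.rss, tss, f.n, f.p)
        except ValueError:
            entry["r2_adj"] = math.nan
        try:
            entry["dw"] = durbin_watson(f.residuals)
            entry["dw_class"] = classify_dw(entry["dw"])
        except ValueError:
            entry["dw"] = math.nan
            entry["dw_class"] = "undefined"
        if f.rss > 0:
            entry["rmse"] = rmse(f.rss, f.n, f.p)
            entry["aic"] = aic(f.rss, f.n, f.p)
            entry["bic"] = bic(f.rss, f.n, f.p)
        else:  # perfect fit: information criteria diverge to -inf
            entry["rmse"] = 0.0
            entry["aic"] = -math.inf
            entry["bic"] = -math.inf
        stats[f.model] = entry
    ranking = rank_models(stats)
    return GofReport(
        group=dataset.group,
        n=dataset.n,
        p={f.model: f.p for f in fits},
        stats=stats,
        ranking=ranking,
    )
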