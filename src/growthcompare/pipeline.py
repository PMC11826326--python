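"""End-to-end workflow: read an age-weight table, fit, report.

Input is a tidy CSV/TSV with header columns ``age_days``, ``weight_g``
and an optional ``group`` column; one dataset per group.  For each group
the run produces

* a parameters table (parameter x model, standard errors in parentheses),
* a goodness-of-fit table (statistics x models, rounded as in
  conventional reports: 4 decimals for adjusted R^2, 2 elsewhere) plus a
  full-precision JSON sidecar,
* a ranking file with a best-model verdict line,
* predicted curves over the observed age range for every model,
* the AGR profile and peak summary for the best model,
* a run log (seed, solver settings, convergence flags, variants).

Re-running with the same config and seed reproduces the TSVs byte for
byte: all floats are written at fixed precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agr_analysis import AgrProfile, agr_profile
from .fitting import FitConfig, FitResult, GrowthDataset, fit, predict_curve
from .growth_models import MODEL_NAMES, get_model
from .model_selection import GofReport, compute_gof

__all__ = ["RunConfig", "ReportBundle", "read_dataset", "run_comparison"]

EXIT_OK = 0
EXIT_INPUT_ERROR = 1
EXIT_PARTIAL = 3


class InputError(ValueError):
    """Malformed input table."""


@dataclass(frozen=True)
class RunConfig:
    """Settings for one comparison run."""

    input: str | Path
    outdir: str | Path
    models: Sequence[str] = MODEL_NAMES
    fit: FitConfig = field(default_factory=FitConfig)
    agr_min: float = 1.0
    agr_max: float = 49.0
    agr_step: float = 0.1

    def __post_init__(self) -> None:
        for m in self.models:
            get_model(m)  # raises UnknownModelError early


def read_dataset(path, fmt: str | None = None) -> list[GrowthDataset]:
    """Read a tidy age-weight table into one dataset per group.

    ``fmt`` is "csv" or "tsv"; inferred from the extension by default.
    Malformed rows are reported with their line numbers.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"
    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # noqa: BLE001 - surface as input error
        raise InputError(f"{path}: cannot parse: {exc}") from exc

    required = {"age_days", "weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing required columns {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = "all"

    bad_lines = []
    for col in ("age_days", "weight_g"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[numeric.isna() & df[col].notna()]:
            bad_lines.append(f"line {idx + 2}: non-numeric {col}={df.at[idx, col]!r}")
        df[col] = numeric
    if df[["age_days", "weight_g"]].isna().any().any():
        for idx in df.index[df[["age_days", "weight_g"]].isna().any(axis=1)]:
            msg = f"line {idx + 2}: missing value"
            if msg not in bad_lines and not any(f"line {idx + 2}:" in b for b in bad_lines):
                bad_lines.append(msg)
    if bad_lines:
        raise InputError(f"{path}: " + "; ".join(bad_lines))

    datasets = []
    for group, sub in df.groupby("group", sort=True):
        dup = sub["age_days"].duplicated(keep=False)
        if dup.any():
            lines = ", ".join(str(i + 2) for i in sub.index[dup])
            raise InputError(
                f"{path}: duplicate age within group {group!r} at line(s) {lines}"
            )
        sub = sub.sort_values("age_days")
        datasets.append(
            GrowthDataset(str(group), sub["age_days"].to_numpy(float),
                          sub["weight_g"].to_numpy(float))
        )
    if not datasets:
        raise InputError(f"{path}: empty input")
    return datasets


@dataclass(frozen=True)
class ReportBundle:
    """Everything one run produced, plus the exit status."""

    groups: list
    fits: dict            # group -> {model: FitResult}
    gof: dict             # group -> GofReport
    agr: dict             # group -> AgrProfile (best model)
    exit_code: int
    outdir: Path


_PARAM_ORDER = ("a", "b", "k", "m", "ip")


def _format_params_table(fits: Mapping[str, FitResult]) -> pd.DataFrame:
    cols = {}
    for name, f in fits.items():
        col = {}
        for pname in _PARAM_ORDER:
            if pname in f.params.values:
                est = f.params[pname]
                se = f.stderr.get(pname) if f.stderr else None
                col[pname] = (f"{est:.6g} ({se:.4g})" if se is not None
                              else f"{est:.6g} (n/a)")
            else:
                col[pname] = "-"
        cols[name] = col
    return pd.DataFrame(cols).reindex(list(_PARAM_ORDER))


def _format_gof_table(report: GofReport, models: Sequence[str]) -> pd.DataFrame:
    rows = {"r2_adj": 4, "dw": 2, "rmse": 2, "aic": 2, "bic": 2}
    data = {}
    for m in models:
        s = report.stats[m]
        col = {}
        for stat, nd in rows.items():
            v = s.get(stat, math.nan)
            col[stat] = f"{v:.{nd}f}" if math.isfinite(v) else str(v)
        data[m] = col
    return pd.DataFrame(data).reindex(list(rows))


def run_comparison(config: RunConfig) -> ReportBundle:
    """Fit all configured models to every group and write the report set."""
    datasets = read_dataset(config.input)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_fits: dict[str, dict[str, FitResult]] = {}
    all_gof: dict[str, GofReport] = {}
    all_agr: dict[str, AgrProfile] = {}
    any_failure = False
    log: dict = {
        "seed": config.fit.seed,
        "restarts": config.fit.restarts,
        "jitter_sd": config.fit.jitter_sd,
        "ftol": config.fit.ftol,
        "xtol": config.fit.xtol,
        "max_iter": config.fit.max_iter,
        "variants": dict(config.fit.variants),
        "models": list(config.models),
        "groups": {},
    }

    for ds in datasets:
        fits: dict[str, FitResult] = {}
        for m in config.models:
            try:
                fits[m] = fit(ds, m, config.fit)
            except ValueError as exc:
                any_failure = True
                log["groups"].setdefault(ds.group, {}).setdefault("errors", {})[m] = str(exc)
        if not fits:
            continue
        report = compute_gof(ds, fits.values())
        all_fits[ds.group] = fits
        all_gof[ds.group] = report
        if any(not f.converged for f in fits.values()):
            any_failure = True

        g = ds.group
        _format_params_table(fits).to_csv(outdir / f"{g}_parameters.tsv", sep="\t")
        _format_gof_table(report, list(fits)).to_csv(outdir / f"{g}_gof.tsv", sep="\t")
        (outdir / f"{g}_gof.json").write_text(report.to_json())

        ranking_lines = [f"best model: {report.best}"]
        for i, r in enumerate(report.ranking, 1):
            flags = "".join(
                [" [failed]" if r.failed else "", " [tied]" if r.tied else ""]
            )
            ranking_lines.append(f"{i}. {r.name}{flags}")
        (outdir / f"{g}_ranking.txt").write_text("\n".join(ranking_lines) + "\n")

        ages = np.arange(math.floor(ds.ages[0]), math.ceil(ds.ages[-1]) + 1, 1.0)
        pred = pd.DataFrame({"age_days": ages})
        for m, f in fits.items():
            pred[m] = [f"{y:.4f}" for _, y in predict_curve(f, ages)]
        pred["age_days"] = [f"{a:.1f}" for a in ages]
        pred.to_csv(outdir / f"{g}_predicted.tsv", sep="\t", index=False)

        best_fit = fits[report.best]
        prof = agr_profile(best_fit, config.agr_min, config.agr_max, config.agr_step)
        prof.to_tsv(outdir / f"{g}_agr_best.tsv")
        (outdir / f"{g}_agr_summary.json").write_text(prof.summary_json())
        all_agr[g] = prof

        log["groups"].setdefault(g, {})["converged"] = {
            m: f.converged for m, f in fits.items()
        }
        log["groups"][g]["best"] = report.best

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    exit_code = EXIT_PARTIAL if any_failure else EXIT_OK
    return ReportBundle(
        groups=[d.group for d in datasets],
        fits=all_fits,
        gof=all_gof,
        agr=all_agr,
        exit_code=exit_code,
        outdir=outdir,
    )
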