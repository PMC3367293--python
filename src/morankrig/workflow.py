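"""End-to-end workflow: correlogram-guided variogram models vs the
traditional half-maximum-distance model, compared by cross-validation and
pollution-status agreement.

For each analyte the workflow

1. screens the raw/log distributions,
2. builds a Moran's I correlogram and extracts the characteristic
   distances d1 (argmax I), d2 (argmax Z(I)), d3 (first zero crossing) and
   d4 (end of the first negative range, when present),
3. fits one exponential variogram per roster entry using that distance as
   the active lag — d5 is the traditional model with active lag half the
   maximum separation — plus the nested d1+d2 two-structure model,
4. leave-one-out cross-validates each model (ME/MAE/RMSE/MSE/RMSSE),
5. compares measured and LOO-predicted concentrations (summary statistics
   and 2x2 pollution-status agreement tables), and
6. ranks the models: ME closest to zero first, RMSSE closest to one as the
   tie-break.

A model whose characteristic distance is unavailable (no negative
correlation range: no d4) is pruned from the roster with a warning.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assessment import agreement_table, single_factor_index, summary_stats
from .kriging import KrigingConfig, CrossValidationReport, loo_cross_validate, predict_grid
from .moran import (
    Correlogram,
    build_correlogram,
    default_threshold_grid,
    extract_characteristic_distances,
)
from .samples import AnalyteConfig, SampleSet, ValidationError
from .variogram import FitError, empirical_variogram, fit_exponential, fit_nested

ROSTER_ALL = ("d1", "d2", "d3", "d4", "d5", "nested")


@dataclass
class WorkflowConfig:
    """Configuration of one workflow run (one or more analytes)."""

    analytes: list[AnalyteConfig]
    roster: tuple[str, ...] = ROSTER_ALL
    correlogram_points: int = 30
    thresholds: np.ndarray | None = None  # explicit correlogram grid
    n_bins: int = 10
    kriging: KrigingConfig = field(default_factory=KrigingConfig)
    d5: float | str = "half_max"  # explicit distance or "half_max"
    grid_cell: float | None = None  # krige a map when set
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.roster:
            raise ValidationError("model roster must be non-empty")
        unknown = set(self.roster) - set(ROSTER_ALL)
        if unknown:
            raise ValidationError(f"unknown roster entries: {sorted(unknown)}")
        if "nested" in self.roster and not {"d1", "d2"} <= set(ROSTER_ALL):
            raise ValidationError("nested model requires d1 and d2 to be derivable")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        analytes = [
            AnalyteConfig(
                name=a["name"],
                critical_value=float(a["critical_value"]),
                background_value=float(a["background_value"]),
                log_transform=bool(a.get("log_transform", True)),
            )
            for a in raw.pop("analytes")
        ]
        kr = raw.pop("kriging", {})
        kwargs = dict(
            analytes=analytes,
            kriging=KrigingConfig(**kr),
            **{k: v for k, v in raw.items() if k in cls.__dataclass_fields__},
        )
        kwargs.update(overrides)
        if "roster" in kwargs and kwargs["roster"] is not None:
            kwargs["roster"] = tuple(kwargs["roster"])
        return cls(**kwargs)


@dataclass
class AnalyteResult:
    """Everything the workflow computed for one analyte."""

    analyte: AnalyteConfig
    screening: "object"
    correlogram: Correlogram
    distances: "object"
    models: dict  # label -> VariogramModel
    cv: dict  # label -> CrossValidationReport
    cv_table: pd.DataFrame
    stats_table: pd.DataFrame
    agreement: dict  # label -> 2x2 DataFrame
    ranking: list[str]
    pruned: list[str]
    grids: dict = field(default_factory=dict)
    error: str | None = None


def rank_models(cv: dict[str, CrossValidationReport]) -> list[str]:
    """Order models by |ME| (closest to zero), then |RMSSE - 1|."""

    def key(label: str):
        m = cv[label].metrics
        rmsse_dev = abs(m.RMSSE - 1.0) if m.RMSSE is not None else np.inf
        return (abs(m.ME), rmsse_dev, label)

    return sorted(cv, key=key)


def _active_lags(distances, samples: SampleSet, roster, d5_setting) -> tuple[dict, list]:
    lags: dict[str, float] = {}
    pruned: list[str] = []
    available = distances.to_dict()
    for label in roster:
        if label == "d5":
            if d5_setting == "half_max":
                lags["d5"] = float(samples.pairwise_distances().max() / 2.0)
            else:
                lags["d5"] = float(d5_setting)
        elif label == "nested":
            continue
        else:
            d = available.get(label)
            if d is None:
                pruned.append(label)
                warnings.warn(
                    f"characteristic distance {label} not available "
                    "(no negative correlation range); model pruned",
                    UserWarning,
                )
            else:
                lags[label] = float(d)
    return lags, pruned


def run_analyte(
    samples: SampleSet, analyte: AnalyteConfig, config: WorkflowConfig
) -> AnalyteResult:
    """Run the full comparison for a single analyte."""
    from .samples import screen_distribution

    screening = screen_distribution(samples, analyte)
    work = samples.working_values(analyte)
    thresholds = (
        config.thresholds
        if config.thresholds is not None
        else default_threshold_grid(samples, config.correlogram_points)
    )
    corr = build_correlogram(work, samples, thresholds, analyte=analyte.name)
    distances = extract_characteristic_distances(corr)
    lags, pruned = _active_lags(distances, samples, config.roster, config.d5)

    models, cv = {}, {}
    evs = {}
    for label, lag in lags.items():
        try:
            evs[label] = empirical_variogram(samples, work, lag, n_bins=config.n_bins)
            models[label] = fit_exponential(evs[label])
        except (ValidationError, FitError) as exc:
            pruned.append(label)
            warnings.warn(f"model {label} pruned: {exc}", UserWarning)
    if "nested" in config.roster:
        if "d1" in lags and "d2" in lags:
            lo, hi = sorted([lags["d1"], lags["d2"]])
            if lo < hi:
                try:
                    models["nested"] = fit_nested(
                        empirical_variogram(samples, work, lo, n_bins=config.n_bins),
                        empirical_variogram(samples, work, hi, n_bins=config.n_bins),
                    )
                except (ValidationError, FitError) as exc:
                    pruned.append("nested")
                    warnings.warn(f"nested model pruned: {exc}", UserWarning)
            else:
                pruned.append("nested")
                warnings.warn("nested model pruned: d1 == d2", UserWarning)
        else:
            pruned.append("nested")

    measured = samples.values[analyte.name]
    stats_rows = [{"model": "measured", **summary_stats(measured).to_dict()}]
    agreement: dict[str, pd.DataFrame] = {}
    measured_status = single_factor_index(measured, analyte)["status"]
    for label, model in models.items():
        cv[label] = loo_cross_validate(
            samples, work, model, config.kriging,
            log_scale=analyte.log_transform, model_label=label, analyte=analyte.name,
        )
        stats_rows.append({"model": label, **summary_stats(cv[label].predicted).to_dict()})
        pred_status = single_factor_index(cv[label].predicted, analyte)["status"]
        agreement[label] = agreement_table(measured_status, pred_status)

    grids = {}
    if config.grid_cell is not None:
        for label, model in models.items():
            grids[label] = predict_grid(
                samples, work, model, config.kriging, cell_size=config.grid_cell
            )

    cv_table = pd.DataFrame([r.to_row() for r in cv.values()])
    return AnalyteResult(
        analyte=analyte,
        screening=screening,
        correlogram=corr,
        distances=distances,
        models=models,
        cv=cv,
        cv_table=cv_table,
        stats_table=pd.DataFrame(stats_rows),
        agreement=agreement,
        ranking=rank_models(cv),
        pruned=pruned,
        grids=grids,
    )


def _config_hash(config: WorkflowConfig) -> str:
    payload = {
        "analytes": [a.__dict__ for a in config.analytes],
        "roster": list(config.roster),
        "correlogram_points": config.correlogram_points,
        "n_bins": config.n_bins,
        "kriging": config.kriging.__dict__,
        "d5": config.d5,
        "grid_cell": config.grid_cell,
        "seed": config.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_workflow(samples: SampleSet, config: WorkflowConfig) -> dict:
    """Run every analyte; a failing analyte is recorded, the rest proceed.

    Returns ``{"results": {analyte: AnalyteResult}, "manifest": dict}`` and,
    when ``config.outdir`` is set, writes CSV/JSON artifacts per analyte
    plus a run manifest.
    """
    results: dict[str, AnalyteResult] = {}
    for analyte in config.analytes:
        try:
            results[analyte.name] = run_analyte(samples, analyte, config)
        except (ValidationError, FitError) as exc:
            results[analyte.name] = AnalyteResult(
                analyte=analyte, screening=None, correlogram=None, distances=None,
                models={}, cv={}, cv_table=pd.DataFrame(), stats_table=pd.DataFrame(),
                agreement={}, ranking=[], pruned=[], error=f"{type(exc).__name__}: {exc}",
            )
    manifest = {
        "package": "morankrig",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_samples": samples.n,
        "analytes": {
            name: ({"error": r.error} if r.error else {
                "distances": r.distances.to_dict(),
                "models": {k: m.to_dict() for k, m in r.models.items()},
                "ranking": r.ranking,
                "pruned": r.pruned,
            })
            for name, r in results.items()
        },
    }
    if config.outdir is not None:
        _write_artifacts(results, manifest, config)
    return {"results": results, "manifest": manifest}


def _write_artifacts(results: dict, manifest: dict, config: WorkflowConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    for name, r in results.items():
        if r.error:
            continue
        adir = out / name
        adir.mkdir(exist_ok=True)
        r.correlogram.to_csv(adir / "correlogram.csv")
        with open(adir / "distances.json", "w") as fh:
            json.dump(r.distances.to_dict(), fh, indent=2)
        with open(adir / "screening.json", "w") as fh:
            json.dump(r.screening.to_dict(), fh, indent=2)
        for label, model in r.models.items():
            model.to_json(adir / f"model_{label}.json")
        r.cv_table.to_csv(adir / "cross_validation.csv", index=False)
        r.stats_table.to_csv(adir / "summary_stats.csv", index=False)
        for label, tab in r.agreement.items():
            tab.to_csv(adir / f"agreement_{label}.csv")
        for label, grid in r.grids.items():
            grid.to_ascii_grid(adir / f"prediction_{label}.asc", "value")
            grid.to_ascii_grid(adir / f"variance_{label}.asc", "variance")
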