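"""Ordinary kriging, lognormal back-transform, cross-validation and metrics.

Ordinary kriging predicts Z*(x0) = sum_i lambda_i Z(x_i) over the samples
in a search neighbourhood, with weights solving the semivariogram system

    [ Gamma  1 ] [ lambda ]   [ gamma0 ]
    [  1^T   0 ] [   mu   ] = [   1    ]

where Gamma_ij = gamma(d(x_i, x_j)), gamma0_i = gamma(d(x_i, x0)) and mu is
the Lagrange multiplier enforcing unbiasedness (sum lambda_i = 1).  The
kriging variance is sigma_k^2 = lambda . gamma0 + mu.

When the analyte was modelled on the natural-log scale, predictions are
mapped back to concentrations either naively (exp(y)) or with the lognormal
ordinary-kriging bias correction exp(y + sigma_k^2 / 2 - mu).

Leave-one-out cross-validation predicts every sample with itself removed
and scores a variogram model by

    ME   = mean(pred - obs)            MAE = mean |pred - obs|
    RMSE = sqrt(mean((pred - obs)^2))  MSE = RMSE^2
    RMSSE = sqrt(mean(((pred - obs) / sigma_k)^2))

with ME/MAE/RMSE/MSE on the concentration scale and RMSSE on the working
scale where the kriging standard deviation is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .samples import SampleSet, ValidationError
from .variogram import VariogramModel


@dataclass(frozen=True)
class KrigingConfig:
    """Search-neighbourhood and back-transform settings.

    ``n_neighbors`` nearest samples are used per target (minimum
    ``min_neighbors``; targets with fewer are masked).  ``back_transform``
    is applied to log-scale predictions: ``"none"``, ``"naive_exp"`` or
    ``"bias_corrected"`` (the default; subtracts the Lagrange multiplier
    and adds half the kriging variance before exponentiating).
    """

    n_neighbors: int = 12
    min_neighbors: int = 4
    search_radius: float | None = None
    back_transform: str = "bias_corrected"

    def __post_init__(self) -> None:
        if self.min_neighbors < 1:
            raise ValidationError("min_neighbors must be >= 1")
        if self.n_neighbors < self.min_neighbors:
            raise ValidationError("n_neighbors must be >= min_neighbors")
        if self.back_transform not in ("none", "naive_exp", "bias_corrected"):
            raise ValidationError(f"unknown back_transform {self.back_transform!r}")


class SingularSystemError(RuntimeError):
    """Kriging system is singular (coincident or degenerate neighbours)."""


def ok_weights(
    target_xy: np.ndarray,
    neighbor_xy: np.ndarray,
    model: VariogramModel,
) -> tuple[np.ndarray, float, float]:
    """Solve the ordinary kriging system for one target.

    Returns ``(weights, mu, kriging_variance)``; weights sum to one within
    solver tolerance.  Negative weights are permitted (no correction).
    """
    neighbor_xy = np.atleast_2d(np.asarray(neighbor_xy, dtype=float))
    target_xy = np.asarray(target_xy, dtype=float).reshape(1, 2)
    k = len(neighbor_xy)
    d_nn = cdist(neighbor_xy, neighbor_xy)
    gamma_nn = np.asarray(model.gamma(d_nn))
    d_t = cdist(neighbor_xy, target_xy)[:, 0]
    gamma_t = np.asarray(model.gamma(d_t))
    A = np.empty((k + 1, k + 1))
    A[:k, :k] = gamma_nn
    A[k, :k] = 1.0
    A[:k, k] = 1.0
    A[k, k] = 0.0
    b = np.concatenate([gamma_t, [1.0]])
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(
            "singular ordinary kriging system: coincident or collinear "
            f"neighbour configuration ({exc})"
        ) from exc
    lam, mu = sol[:k], float(sol[k])
    variance = float(lam @ gamma_t + mu)
    return lam, mu, max(variance, 0.0)


def _neighbourhood(target_xy, coords, config: KrigingConfig, exclude: int | None = None):
    d = np.linalg.norm(coords - np.asarray(target_xy, dtype=float), axis=1)
    idx = np.arange(len(coords))
    if exclude is not None:
        keep = idx != exclude
        d, idx = d[keep], idx[keep]
    if config.search_radius is not None:
        keep = d <= config.search_radius
        d, idx = d[keep], idx[keep]
    order = np.argsort(d, kind="stable")[: config.n_neighbors]
    return idx[order]


def predict_point(
    target_xy,
    samples: SampleSet,
    values,
    model: VariogramModel,
    config: KrigingConfig = KrigingConfig(),
    exclude: int | None = None,
) -> tuple[float, float, float]:
    """Kriged prediction at one location on the working scale.

    Returns ``(prediction, kriging_variance, mu)``.  A target coinciding
    with a retained sample reproduces that sample's value exactly (the
    semivariogram system is an exact interpolator since gamma(0) = 0).
    Raises when fewer than ``min_neighbors`` candidates exist.
    """
    v = np.asarray(values, dtype=float)
    nb = _neighbourhood(target_xy, samples.coords, config, exclude=exclude)
    if len(nb) < config.min_neighbors:
        raise ValidationError(
            f"only {len(nb)} neighbours available (< min_neighbors = {config.min_neighbors})"
        )
    lam, mu, var = ok_weights(target_xy, samples.coords[nb], model)
    return float(lam @ v[nb]), var, mu


def back_transform(
    prediction: float | np.ndarray,
    variance: float | np.ndarray | None = None,
    mu_lagrange: float | np.ndarray | None = None,
    mode: str = "bias_corrected",
):
    """Map a working-scale prediction back to the concentration scale.

    ``none`` returns the prediction unchanged; ``naive_exp`` applies
    exp(y); ``bias_corrected`` applies the lognormal ordinary-kriging
    correction exp(y + sigma_k^2/2 - mu), which removes the downward bias
    of the naive exponential on the mean.
    """
    if mode == "none":
        return prediction
    if mode == "naive_exp":
        return np.exp(prediction)
    if mode == "bias_corrected":
        if variance is None or mu_lagrange is None:
            raise ValidationError("bias_corrected back-transform needs variance and mu")
        return np.exp(prediction + np.asarray(variance) / 2.0 - np.asarray(mu_lagrange))
    raise ValidationError(f"unknown back_transform mode {mode!r}")


@dataclass
class PredictionGrid:
    """Regular grid of kriged values with per-cell variance and mask."""

    x: np.ndarray  # cell-centre x coordinates (ascending)
    y: np.ndarray  # cell-centre y coordinates (ascending)
    value: np.ndarray  # (ny, nx), concentration scale; NaN where masked
    variance: np.ndarray  # (ny, nx), working scale
    mask: np.ndarray  # True where prediction unavailable
    cell_size: float

    def to_ascii_grid(self, path, layer: str = "value") -> None:
        """Write an Esri ASCII grid (text raster) of one layer."""
        arr = getattr(self, layer)
        nodata = -9999.0
        out = np.where(self.mask | ~np.isfinite(arr), nodata, arr)
        header = (
            f"ncols {len(self.x)}\n"
            f"nrows {len(self.y)}\n"
            f"xllcorner {self.x[0] - self.cell_size / 2.0}\n"
            f"yllcorner {self.y[0] - self.cell_size / 2.0}\n"
            f"cellsize {self.cell_size}\n"
            f"NODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in out[::-1]:  # ASCII grids run top-to-bottom
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def predict_grid(
    samples: SampleSet,
    values,
    model: VariogramModel,
    config: KrigingConfig = KrigingConfig(),
    origin: tuple[float, float] | None = None,
    cell_size: float = 1.0,
    shape: tuple[int, int] | None = None,
) -> PredictionGrid:
    """Krige a regular grid of cell centres; deterministic for fixed inputs.

    The grid defaults to the sample bounding box at the given cell size.
    Cells failing the neighbour requirement are masked and counted.
    """
    if origin is None:
        origin = (float(samples.x.min()), float(samples.y.min()))
    if shape is None:
        nx = int(np.ceil((samples.x.max() - origin[0]) / cell_size)) + 1
        ny = int(np.ceil((samples.y.max() - origin[1]) / cell_size)) + 1
    else:
        ny, nx = shape
    gx = origin[0] + cell_size * np.arange(nx)
    gy = origin[1] + cell_size * np.arange(ny)
    value = np.full((ny, nx), np.nan)
    variance = np.full((ny, nx), np.nan)
    mask = np.zeros((ny, nx), dtype=bool)
    n_masked = 0
    for iy, yy in enumerate(gy):
        for ix, xx in enumerate(gx):
            try:
                pred, var, mu = predict_point((xx, yy), samples, values, model, config)
            except (ValidationError, SingularSystemError):
                mask[iy, ix] = True
                n_masked += 1
                continue
            value[iy, ix] = back_transform(pred, var, mu, config.back_transform)
            variance[iy, ix] = var
    if n_masked:
        warnings.warn(f"{n_masked} grid cell(s) masked for insufficient neighbours", UserWarning)
    return PredictionGrid(x=gx, y=gy, value=value, variance=variance, mask=mask,
                          cell_size=float(cell_size))


@dataclass(frozen=True)
class ErrorMetrics:
    ME: float
    MAE: float
    RMSE: float
    MSE: float
    RMSSE: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def error_metrics(observed, predicted, kriging_sd=None) -> ErrorMetrics:
    """ME / MAE / RMSE / MSE (and RMSSE when kriging SDs are supplied)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValidationError("observed and predicted must be equal-length, non-empty")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    rmsse = None
    if kriging_sd is not None:
        sd = np.asarray(kriging_sd, dtype=float)
        if sd.shape != obs.shape:
            raise ValidationError("kriging_sd length mismatch")
        if np.any(sd <= 0):
            raise ValidationError("kriging_sd must be strictly positive for RMSSE")
        rmsse = float(np.sqrt(np.mean((err / sd) ** 2)))
    return ErrorMetrics(
        ME=float(np.mean(err)),
        MAE=float(np.mean(np.abs(err))),
        RMSE=rmse,
        MSE=rmse**2,
        RMSSE=rmsse,
    )


@dataclass
class CrossValidationReport:
    """LOO cross-validation of one variogram model for one analyte."""

    model_label: str
    analyte: str
    metrics: ErrorMetrics
    observed: np.ndarray  # concentration scale
    predicted: np.ndarray  # concentration scale
    kriging_sd: np.ndarray  # working scale
    working_errors: np.ndarray  # pred - obs on the working scale
    n_excluded: int = 0

    def to_row(self) -> dict:
        row = {"model": self.model_label, "analyte": self.analyte}
        row.update(self.metrics.to_dict())
        return row

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"observed": self.observed, "predicted": self.predicted,
             "kriging_sd": self.kriging_sd}
        )


def loo_cross_validate(
    samples: SampleSet,
    values,
    model: VariogramModel,
    config: KrigingConfig = KrigingConfig(),
    log_scale: bool = True,
    model_label: str = "",
    analyte: str = "",
) -> CrossValidationReport:
    """Leave-one-out cross-validation on the concentration scale.

    ``values`` are working-scale values (log concentrations when
    ``log_scale``).  Each sample is predicted from its ``n_neighbors``
    nearest other samples; unpredictable samples (too few neighbours) are
    excluded with a warning.  RMSSE uses working-scale errors and kriging
    SDs; the other metrics use back-transformed concentrations.
    """
    v = np.asarray(values, dtype=float)
    n = samples.n
    preds = np.full(n, np.nan)
    variances = np.full(n, np.nan)
    mus = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        try:
            preds[i], variances[i], mus[i] = predict_point(
                samples.coords[i], samples, v, model, config, exclude=i
            )
            ok[i] = True
        except (ValidationError, SingularSystemError):
            continue
    if not np.all(ok):
        warnings.warn(
            f"{int(np.sum(~ok))} sample(s) unpredictable in LOO and excluded",
            UserWarning,
        )
    if not np.any(ok):
        raise ValidationError("no sample could be cross-validated")
    sd = np.sqrt(variances[ok])
    if log_scale:
        obs_conc = np.exp(v[ok])
        pred_conc = np.asarray(
            back_transform(preds[ok], variances[ok], mus[ok], config.back_transform)
        )
    else:
        obs_conc = v[ok]
        pred_conc = preds[ok]
    metrics = error_metrics(obs_conc, pred_conc)
    work_err = preds[ok] - v[ok]
    if np.all(sd > 0):
        rmsse = float(np.sqrt(np.mean((work_err / sd) ** 2)))
        metrics = ErrorMetrics(metrics.ME, metrics.MAE, metrics.RMSE, metrics.MSE, rmsse)
    return CrossValidationReport(
        model_label=model_label,
        analyte=analyte,
        metrics=metrics,
        observed=obs_conc,
        predicted=pred_conc,
        kriging_sd=sd,
        working_errors=work_err,
        n_excluded=int(np.sum(~ok)),
    )
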