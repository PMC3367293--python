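"""Empirical semivariogram estimation and exponential model fitting.

The semivariance at lag h is half the mean squared difference between the
values of sample pairs separated by (approximately) h:

    gamma(h) = sum_{pairs in bin} (z(x_i) - z(x_j))^2 / (2 N(h))

Only pairs with separation at most the *active lag distance* contribute;
pairs are grouped into equal-width distance bins and each bin is
represented by the mean separation of its pairs.

Fitted models are the exponential

    gamma(h) = C0 + C (1 - exp(-h / a)),   h > 0;  gamma(0) = 0

and the two-structure nested exponential

    gamma(h) = C0 + C1 (1 - exp(-h / a1)) + C2 (1 - exp(-h / a2)),

with nugget C0, partial sills C_k and range parameters a_k (practical
range 3 a_k, the distance at which ~95% of the sill is reached).  The
nugget/sill ratio 100 C0 / (C0 + sum C_k) indexes the strength of spatial
dependence (smaller = stronger).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .samples import SampleSet, ValidationError


class FitError(RuntimeError):
    """Variogram model fit failed to converge or is under-determined."""


@dataclass
class EmpiricalVariogram:
    """Binned empirical semivariogram under a given active lag distance."""

    active_lag: float
    mean_lag: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    scale: str = "log"  # raw | log, informational

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_lag": self.mean_lag, "gamma": self.gamma, "n_pairs": self.n_pairs}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def empirical_variogram(
    samples: SampleSet,
    values,
    active_lag: float,
    n_bins: int = 10,
    scale: str = "log",
) -> EmpiricalVariogram:
    """Bin pair semivariances over (0, active_lag] into equal-width bins.

    Empty bins are dropped; an error is raised when no pair at all falls
    within the active lag.
    """
    if not active_lag > 0:
        raise ValidationError(f"active_lag must be > 0, got {active_lag}")
    v = np.asarray(values, dtype=float)
    d = pdist(samples.coords)
    dv2 = pdist(v[:, None], metric="sqeuclidean")
    keep = d <= active_lag
    if not np.any(keep):
        raise ValidationError(f"no sample pairs within active_lag = {active_lag}")
    d, dv2 = d[keep], dv2[keep]
    edges = np.linspace(0.0, active_lag, n_bins + 1)
    # pairs at exactly zero lag cannot occur (duplicate coords are rejected)
    which = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_bins - 1)
    mean_lag, gamma, counts = [], [], []
    for b in range(n_bins):
        m = which == b
        if not np.any(m):
            continue
        mean_lag.append(d[m].mean())
        gamma.append(dv2[m].sum() / (2.0 * m.sum()))
        counts.append(int(m.sum()))
    return EmpiricalVariogram(
        active_lag=float(active_lag),
        mean_lag=np.asarray(mean_lag),
        gamma=np.asarray(gamma),
        n_pairs=np.asarray(counts),
        scale=scale,
    )


@dataclass
class VariogramModel:
    """Nugget + one or two exponential structures with fit diagnostics.

    ``structures`` holds (partial_sill, range_parameter) tuples ordered by
    increasing range.  The practical range of each structure is three times
    its range parameter.
    """

    kind: str  # "exponential" | "nested_exponential"
    C0: float
    structures: list[tuple[float, float]]
    r_squared: float = np.nan
    rss: float = np.nan
    range_convention: str = "parameter"  # practical range = 3 * parameter

    def __post_init__(self) -> None:
        if self.C0 < 0:
            raise ValidationError("nugget C0 must be >= 0")
        for c, a in self.structures:
            if c < 0 or a <= 0:
                raise ValidationError("partial sills must be >= 0 and ranges > 0")
        self.structures = sorted(self.structures, key=lambda s: s[1])

    @property
    def sill(self) -> float:
        return self.C0 + sum(c for c, _ in self.structures)

    @property
    def practical_ranges(self) -> list[float]:
        return [3.0 * a for _, a in self.structures]

    def gamma(self, h) -> np.ndarray | float:
        """Model semivariance; gamma(0) = 0 exactly (origin discontinuity)."""
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise ValidationError("lag distance h must be >= 0")
        g = np.full(h.shape, self.C0, dtype=float)
        for c, a in self.structures:
            g += c * (1.0 - np.exp(-h / a))
        g = np.where(h == 0, 0.0, g)
        return float(g) if g.ndim == 0 else g

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "C0": self.C0,
            "structures": [{"partial_sill": c, "range_parameter": a, "practical_range": 3 * a}
                           for c, a in self.structures],
            "sill": self.sill,
            "nugget_sill_ratio_percent": nugget_sill_ratio(self),
            "r_squared": self.r_squared,
            "rss": self.rss,
            "range_convention": self.range_convention,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def model_gamma(model: VariogramModel, h) -> np.ndarray | float:
    """Functional alias for :meth:`VariogramModel.gamma`."""
    return model.gamma(h)


def nugget_sill_ratio(model: VariogramModel) -> float:
    """Nugget/sill ratio 100 * C0 / (C0 + sum C_k), in percent."""
    if model.sill <= 0:
        raise ValidationError("sill must be > 0 for the nugget/sill ratio")
    return 100.0 * model.C0 / model.sill


def _fit_stats(gamma_obs: np.ndarray, gamma_fit: np.ndarray) -> tuple[float, float]:
    rss = float(np.sum((gamma_obs - gamma_fit) ** 2))
    tss = float(np.sum((gamma_obs - gamma_obs.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return r2, rss


def fit_exponential(
    ev: EmpiricalVariogram,
    weights: str = "none",
    x0: tuple[float, float, float] | None = None,
) -> VariogramModel:
    """Least-squares fit of gamma(h) = C0 + C (1 - exp(-h/a)) to bin gammas.

    Unweighted by default (matching the R^2/RSS conventions of classic
    variogram-fitting software); pass
    ``weights="npairs"`` to weight residuals by sqrt(N(h)).  Initial values
    default to C0 = first-bin gamma, sill = max bin gamma, a = active_lag/3.
    """
    h, g = ev.mean_lag, ev.gamma
    if len(h) < 4:
        raise FitError(f"need >= 4 variogram bins to fit 3 parameters, got {len(h)}")
    if x0 is None:
        c0_init = max(float(g[0]), 1e-12)
        sill_init = max(float(np.max(g)), c0_init * 1.001)
        x0 = (c0_init, max(sill_init - c0_init, 1e-12), ev.active_lag / 3.0)
    w = np.sqrt(ev.n_pairs) if weights == "npairs" else np.ones_like(g)

    def resid(p):
        c0, c, a = p
        return w * (c0 + c * (1.0 - np.exp(-h / a)) - g)

    sol = least_squares(
        resid, x0=np.asarray(x0, dtype=float),
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
    )
    if not sol.success:
        raise FitError(f"exponential fit did not converge from x0={x0}: {sol.message}")
    c0, c, a = sol.x
    model = VariogramModel(kind="exponential", C0=float(c0), structures=[(float(c), float(a))])
    model.r_squared, model.rss = _fit_stats(g, np.asarray(model.gamma(h)))
    return model


def fit_nested(
    ev_short: EmpiricalVariogram,
    ev_long: EmpiricalVariogram,
    weights: str = "none",
    collapse_rtol: float = 0.05,
) -> VariogramModel:
    """Joint two-structure exponential fit informed by two active lags.

    The short-lag empirical variogram (active lag d1) initialises the
    short-range structure and the long-lag one (active lag d2) the
    long-range structure; the nested model is then fitted jointly to the
    long-lag bins.  If the two fitted ranges collapse onto each other the
    model degrades to a single structure with a warning.
    """
    if not ev_short.active_lag < ev_long.active_lag:
        raise ValidationError("ev_short.active_lag must be < ev_long.active_lag")
    m_short = fit_exponential(ev_short, weights=weights)
    m_long = fit_exponential(ev_long, weights=weights)
    (c1, a1) = m_short.structures[0]
    (c2, a2) = m_long.structures[0]
    h, g = ev_long.mean_lag, ev_long.gamma
    if len(h) < 5:
        raise FitError(f"need >= 5 long-lag bins to fit 5 parameters, got {len(h)}")
    w = np.sqrt(ev_long.n_pairs) if weights == "npairs" else np.ones_like(g)

    def resid(p):
        c0, c1_, a1_, c2_, a2_ = p
        return w * (
            c0
            + c1_ * (1.0 - np.exp(-h / a1_))
            + c2_ * (1.0 - np.exp(-h / a2_))
            - g
        )

    x0 = np.array([
        min(m_short.C0, m_long.C0),
        max(c1, 1e-12), max(a1, 1e-9),
        max(c2, 1e-12), max(a2, a1 * 1.5 + 1e-9),
    ])
    sol = least_squares(
        resid, x0=x0,
        bounds=([0.0, 0.0, 1e-9, 0.0, 1e-9], np.full(5, np.inf)),
    )
    if not sol.success:
        raise FitError(f"nested fit did not converge from x0={x0.tolist()}: {sol.message}")
    c0, c1f, a1f, c2f, a2f = sol.x
    if abs(a1f - a2f) <= collapse_rtol * max(a1f, a2f):
        warnings.warn(
            "nested structures collapsed (a1 ~= a2); degrading to a single "
            "exponential structure",
            UserWarning,
        )
        model = VariogramModel(
            kind="exponential", C0=float(c0),
            structures=[(float(c1f + c2f), float((a1f + a2f) / 2.0))],
        )
    else:
        model = VariogramModel(
            kind="nested_exponential", C0=float(c0),
            structures=[(float(c1f), float(a1f)), (float(c2f), float(a2f))],
        )
    model.r_squared, model.rss = _fit_stats(g, np.asarray(model.gamma(h)))
    return model
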