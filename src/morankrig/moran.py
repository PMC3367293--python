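"""Global and local Moran's I, correlograms, and characteristic distances.

Global Moran's I for an attribute ``x`` under binary spatial weights ``w``:

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x)

Its null moments under the normality assumption (in the raw weight sums
S0, S1, S2) standardise I to Z(I) = (I - E[I]) / sqrt(Var[I]); |Z(I)| > 1.96
flags significance at the 5% level.

A spatial correlogram evaluates I (and Z(I)) over an increasing grid of
distance-band thresholds.  Four characteristic distances summarise its
shape:

- d1: threshold at which I is maximal,
- d2: threshold at which Z(I) is maximal,
- d3: first zero crossing of I (end of the positive correlation range),
- d4: second zero crossing (end of the first negative range), absent when
  no negative range separates two positive ranges.

The local statistic I_i = (z_i / m2) * sum_j w_ij z_j with m2 = sum z^2 / n
decomposes the global statistic (sum_i I_i = S0 * I) and classifies each
site as High-high / Low-low cluster, High-low / Low-high outlier, or
Not-significant, with significance from conditional permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .samples import DistanceBandWeights, SampleSet, ValidationError, build_distance_band_weights

Z_CRITICAL = 1.96

CATEGORY_LABELS = ("Not-significant", "High-high", "Low-low", "Low-high", "High-low")


class DegenerateInputError(ValidationError):
    """Attribute or weight structure admits no autocorrelation statistic."""


def _centered(values: np.ndarray) -> np.ndarray:
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    if np.allclose(z, 0.0):
        raise DegenerateInputError("attribute variance is zero")
    return z


def global_moran(values, weights: DistanceBandWeights) -> float:
    """Global Moran's I for one attribute under binary distance-band weights."""
    z = _centered(values)
    if weights.S0 <= 0:
        raise DegenerateInputError("weights have no neighbour pairs (S0 = 0)")
    num = float(z @ weights.lag(z))
    return weights.n / weights.S0 * num / float(z @ z)


def moran_null_moments(weights: DistanceBandWeights) -> tuple[float, float]:
    """(E[I], Var[I]) under the normality assumption.

    E[I] = -1/(n-1);
    Var[I] = (n^2 S1 - n S2 + 3 S0^2) / (S0^2 (n^2 - 1)) - E[I]^2.
    """
    n = weights.n
    if n < 2:
        raise DegenerateInputError("need n >= 2")
    ei = -1.0 / (n - 1)
    s0, s1, s2 = weights.S0, weights.S1, weights.S2
    var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / (s0 * s0 * (n * n - 1.0)) - ei * ei
    return ei, var


def standardize_moran(I: float, weights: DistanceBandWeights) -> tuple[float, float, float]:
    """Return (E[I], Var[I], Z(I)); raises if the variance degenerates.

    Var[I] is exactly zero under full connectivity (I is then the constant
    -1/(n-1)); that case is reported as degenerate.
    """
    ei, var = moran_null_moments(weights)
    if var <= 1e-14:
        raise DegenerateInputError(f"Var[I] = {var} <= 0 (degenerate weight structure)")
    return ei, var, (I - ei) / np.sqrt(var)


@dataclass(frozen=True)
class CorrelogramPoint:
    threshold: float
    I: float
    EI: float
    VarI: float
    ZI: float
    n_pairs: int

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.ZI)) and abs(self.ZI) > Z_CRITICAL


@dataclass
class Correlogram:
    """Ordered (threshold, I, Z(I)) sequence for one analyte."""

    points: list[CorrelogramPoint]
    analyte: str = ""

    def __post_init__(self) -> None:
        t = self.thresholds
        if np.any(np.diff(t) <= 0):
            raise ValidationError("correlogram thresholds must be strictly increasing")

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p.threshold for p in self.points])

    @property
    def I(self) -> np.ndarray:
        return np.array([p.I for p in self.points])

    @property
    def ZI(self) -> np.ndarray:
        return np.array([p.ZI for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "I": self.I,
                "EI": [p.EI for p in self.points],
                "VarI": [p.VarI for p in self.points],
                "ZI": self.ZI,
                "n_pairs": [p.n_pairs for p in self.points],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_threshold_grid(samples: SampleSet, n_points: int = 30) -> np.ndarray:
    """Threshold sweep from the no-island distance to half the max separation.

    The lower end is the smallest pairwise-distance value at which every
    record has at least one neighbour (so no correlogram point drops
    records); the upper end is half the maximum separation, the customary
    limit beyond which distance classes are dominated by boundary pairs.
    """
    d = samples.pairwise_distances()
    off = d + np.diag(np.full(samples.n, np.inf))
    t_min = float(off.min(axis=1).max())
    t_max = float(d.max() / 2.0)
    if t_max <= t_min:
        t_max = float(d.max())
    return np.linspace(t_min, t_max, n_points)


def build_correlogram(
    values, samples: SampleSet, thresholds, analyte: str = ""
) -> Correlogram:
    """Evaluate I and Z(I) at each threshold; zero-neighbour points dropped."""
    pts = []
    for t in np.asarray(thresholds, dtype=float):
        w = build_distance_band_weights(samples, t, warn_islands=False)
        if w.S0 <= 0:
            warnings.warn(f"threshold {t} has no neighbour pairs; point dropped", UserWarning)
            continue
        I = global_moran(values, w)
        try:
            ei, var, zi = standardize_moran(I, w)
        except DegenerateInputError:
            # full (or near-full) connectivity: I is deterministic, Z(I)
            # undefined; keep the I value, mark Z(I) as missing
            ei, var, zi = -1.0 / (w.n - 1), 0.0, np.nan
        pts.append(CorrelogramPoint(float(t), I, ei, var, zi, w.n_pairs))
    if len(pts) < 3:
        raise ValidationError("correlogram needs at least 3 valid points")
    return Correlogram(points=pts, analyte=analyte)


@dataclass(frozen=True)
class CharacteristicDistances:
    """The four correlogram-derived distances driving variogram active lags."""

    d1: float  # argmax of I
    d2: float  # argmax of Z(I)
    d3: float | None  # first zero crossing of I; None when beyond the grid
    d4: float | None  # second zero crossing; None when no negative range

    def to_dict(self) -> dict:
        return {"d1": self.d1, "d2": self.d2, "d3": self.d3, "d4": self.d4}


def _interp_crossing(t0: float, t1: float, i0: float, i1: float) -> float:
    return t0 + (t1 - t0) * i0 / (i0 - i1)


def extract_characteristic_distances(corr: Correlogram) -> CharacteristicDistances:
    """Locate d1, d2 (argmax of I and Z(I)) and d3, d4 (zero crossings).

    Argmax ties break toward the smaller threshold (closer distance, more
    similarity).  d3 is the linearly interpolated distance of the first sign
    change of I from positive to non-positive; d4 the interpolated return
    from negative to non-negative, reported only when a genuine negative
    range exists.
    """
    t, I, ZI = corr.thresholds, corr.I, corr.ZI
    if len(t) < 3:
        raise ValidationError("need at least 3 correlogram points")
    i1 = int(np.argmax(I))
    if np.all(np.isnan(ZI)):
        raise ValidationError("Z(I) undefined at every threshold: d2 unavailable")
    i2 = int(np.nanargmax(ZI))
    if i1 == len(t) - 1 or i2 == len(t) - 1:
        warnings.warn("correlogram maximum at the largest threshold; extend the grid", UserWarning)
    if I[0] <= 0:
        raise ValidationError("Moran's I not positive at the smallest threshold: d3 undefined")
    # first positive -> <=0 crossing
    d3 = None
    k3 = None
    for k in range(1, len(t)):
        if I[k - 1] > 0 >= I[k]:
            d3 = t[k] if I[k] == 0 else _interp_crossing(t[k - 1], t[k], I[k - 1], I[k])
            k3 = k
            break
    if d3 is None:
        warnings.warn(
            "Moran's I stays positive over the whole threshold grid: the "
            "positive correlation range extends beyond it; d3 (and d4) "
            "unavailable",
            UserWarning,
        )
        return CharacteristicDistances(d1=float(t[i1]), d2=float(t[i2]), d3=None, d4=None)
    # end of the first negative range: next negative -> >=0 crossing
    d4 = None
    for k in range(k3 + 1, len(t)):
        if I[k - 1] < 0 <= I[k]:
            d4 = t[k] if I[k] == 0 else _interp_crossing(t[k - 1], t[k], I[k - 1], I[k])
            break
    return CharacteristicDistances(d1=float(t[i1]), d2=float(t[i2]), d3=float(d3),
                                   d4=None if d4 is None else float(d4))


@dataclass
class LocalMoranResult:
    """Per-site local Moran's I with permutation significance and category."""

    Ii: np.ndarray
    z: np.ndarray
    lag: np.ndarray
    p_value: np.ndarray
    category: np.ndarray  # of CATEGORY_LABELS
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Ii": self.Ii, "z": self.z, "lag": self.lag,
             "p_value": self.p_value, "category": self.category}
        )


def local_moran(
    values,
    weights: DistanceBandWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    method: str = "permutation",
) -> LocalMoranResult:
    """Local Moran's I with cluster/outlier classification.

    I_i = (z_i / m2) * sum_j w_ij z_j with m2 = sum_k z_k^2 / n, so that
    sum_i I_i = S0 * I (the local statistics decompose the global one).

    Significance is assessed by conditional permutation by default: holding
    z_i fixed, the neighbour set is redrawn ``n_permutations`` times from
    the remaining sites and a two-sided pseudo p-value computed.  The
    ``method="analytic"`` alternative uses the conditional normal
    approximation.  Sites with no neighbours are labelled Not-significant
    with a warning.
    """
    z = _centered(values)
    n = weights.n
    m2 = float(z @ z) / n
    lag = weights.lag(z)
    Ii = z * lag / m2
    card = weights.cardinalities
    p = np.ones(n)

    if method == "permutation":
        if seed is None:
            raise ValidationError("seed is required for permutation inference")
        rng = np.random.default_rng(seed)
        # one shared permutation-index matrix over the n-1 "other" sites;
        # per site, its first k columns give the redrawn neighbour sets
        draws = rng.random((n_permutations, n - 1)).argsort(axis=1)
        all_idx = np.arange(n)
        for i in range(n):
            k = card[i]
            if k == 0:
                continue
            others = z[all_idx != i]
            perm_lag = others[draws[:, :k]].sum(axis=1)
            perm_Ii = z[i] * perm_lag / m2
            extreme = np.sum(np.abs(perm_Ii) >= abs(Ii[i]))
            p[i] = (extreme + 1) / (n_permutations + 1)
    elif method == "analytic":
        # conditional moments given z_i (normal approximation)
        for i in range(n):
            k = card[i]
            if k == 0:
                continue
            others = np.delete(z, i)
            mu = others.mean() * k
            var = others.var(ddof=0) * k * (len(others) - k) / max(len(others) - 1, 1)
            if var <= 0:
                continue
            zi_score = (lag[i] - mu) / np.sqrt(var)
            from scipy.stats import norm

            p[i] = 2.0 * norm.sf(abs(zi_score))
    else:
        raise ValidationError(f"unknown method {method!r}")

    if np.any(card == 0):
        warnings.warn(f"{int(np.sum(card == 0))} site(s) have no neighbours; "
                      "labelled Not-significant", UserWarning)

    category = np.full(n, "Not-significant", dtype=object)
    sig = (p < alpha) & (card > 0)
    hi = z > 0
    hilag = lag > 0
    category[sig & hi & hilag] = "High-high"
    category[sig & ~hi & ~hilag] = "Low-low"
    category[sig & ~hi & hilag] = "Low-high"
    category[sig & hi & ~hilag] = "High-low"
    return LocalMoranResult(Ii=Ii, z=z, lag=lag, p_value=p, category=category, alpha=alpha)


def summarize_categories(local: LocalMoranResult) -> pd.DataFrame:
    """Per-category mean I_i, mean z, and percent of samples (sums to 100)."""
    df = local.to_frame()
    rows = []
    n = len(df)
    for cat in CATEGORY_LABELS:
        sub = df[df["category"] == cat]
        rows.append(
            {
                "category": cat,
                "mean_Ii": float(sub["Ii"].mean()) if len(sub) else np.nan,
                "mean_z": float(sub["z"].mean()) if len(sub) else np.nan,
                "percent": 100.0 * len(sub) / n,
            }
        )
    return pd.DataFrame(rows)
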