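"""Point-sample data model, distance-band spatial weights, distribution screening.

The central container is :class:`SampleSet`: georeferenced point samples on a
projected (planar) coordinate system carrying one or more analyte
concentrations in mg/kg.  Distances are Euclidean; the default length unit is
kilometres.  Geographic latitude/longitude input is rejected — project first.

Spatial neighbourhood structure is expressed as binary distance-band weights:
two samples are neighbours iff their separation is positive and at most a
threshold distance.  Weights are *not* row-standardised; the Moran's I
moments used downstream are written in terms of the raw weight sums
S0, S1 and S2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats


class ValidationError(ValueError):
    """Raised when input data violate a documented precondition."""


@dataclass(frozen=True)
class AnalyteConfig:
    """Per-analyte assessment configuration.

    Parameters
    ----------
    name
        Analyte label, e.g. ``"Cr"``.
    critical_value
        Regulatory pollution threshold S in mg/kg; a sample with
        concentration above S counts as polluted.
    background_value
        Background concentration B in mg/kg (uncontaminated reference level).
    log_transform
        Whether the analyte is analysed on the natural-log scale.
    """

    name: str
    critical_value: float
    background_value: float
    log_transform: bool = True

    def __post_init__(self) -> None:
        if not self.critical_value > 0:
            raise ValidationError(f"critical_value must be > 0, got {self.critical_value}")
        if not self.background_value > 0:
            raise ValidationError(f"background_value must be > 0, got {self.background_value}")


class SampleSet:
    """Georeferenced point samples with per-analyte concentrations.

    Parameters
    ----------
    sample_id : sequence of str
        Unique identifier per record.
    x, y : array-like
        Projected planar coordinates (default unit kilometres).
    values : mapping of str to array-like
        Concentration vectors keyed by analyte name (mg/kg).
    distance_unit : str
        Label for the coordinate unit; informational.
    duplicate_policy : {"reject", "jitter"}
        Coincident coordinates either raise or are displaced by
        ``jitter_eps`` with a warning (kriging systems are singular for
        coincident points).
    """

    def __init__(
        self,
        sample_id,
        x,
        y,
        values: dict[str, "np.ndarray"],
        distance_unit: str = "km",
        duplicate_policy: str = "reject",
        jitter_eps: float = 1e-6,
    ) -> None:
        self.sample_id = np.asarray(sample_id, dtype=object)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in values.items()}
        self.distance_unit = distance_unit
        n = len(self.sample_id)
        if n < 3:
            raise ValidationError(f"need at least 3 samples, got {n}")
        if len(self.x) != n or len(self.y) != n:
            raise ValidationError("sample_id, x, y must have equal length")
        for k, v in self.values.items():
            if len(v) != n:
                raise ValidationError(f"analyte {k!r} has {len(v)} values for {n} samples")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError("non-finite coordinates")
        if len(set(self.sample_id)) != n:
            raise ValidationError("sample_id values must be unique")
        self._check_projected()
        self._resolve_duplicates(duplicate_policy, jitter_eps)
        self._dist: np.ndarray | None = None

    def _check_projected(self) -> None:
        # Heuristic lat/lon detection: both axes entirely inside the
        # geographic window is almost surely unprojected input.
        if (
            np.all(np.abs(self.x) <= 180.0)
            and np.all(np.abs(self.y) <= 90.0)
            and (np.ptp(self.x) < 10.0 and np.ptp(self.y) < 10.0)
            and np.any(self.x != np.round(self.x))
        ):
            warnings.warn(
                "coordinates look like geographic lat/lon; distances assume a "
                "planar projection — project to a metric CRS first if so",
                UserWarning,
                stacklevel=3,
            )

    def _resolve_duplicates(self, policy: str, eps: float) -> None:
        coords = np.column_stack([self.x, self.y])
        _, first, counts = np.unique(coords, axis=0, return_index=True, return_counts=True)
        if not np.any(counts > 1):
            return
        if policy == "reject":
            dup = coords[first[counts > 1][0]]
            raise ValidationError(
                f"duplicate coordinates at ({dup[0]}, {dup[1]}); "
                "use duplicate_policy='jitter' to displace them"
            )
        if policy != "jitter":
            raise ValidationError(f"unknown duplicate_policy {policy!r}")
        rng = np.random.default_rng(0)
        seen: set[tuple[float, float]] = set()
        moved = 0
        for i in range(len(self.x)):
            while (self.x[i], self.y[i]) in seen:
                self.x[i] += eps * rng.standard_normal()
                self.y[i] += eps * rng.standard_normal()
                moved += 1
            seen.add((self.x[i], self.y[i]))
        warnings.warn(f"jittered {moved} duplicate coordinate(s) by ~{eps}", UserWarning)

    def __len__(self) -> int:
        return len(self.sample_id)

    @property
    def n(self) -> int:
        return len(self)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def log_values(self, analyte: str) -> np.ndarray:
        """Natural-log concentrations; raises if any value is non-positive."""
        v = self.values[analyte]
        bad = np.flatnonzero(v <= 0)
        if bad.size:
            raise ValidationError(
                f"non-positive {analyte} value at sample_id "
                f"{self.sample_id[bad[0]]!r}: cannot log-transform"
            )
        return np.log(v)

    def working_values(self, analyte: AnalyteConfig) -> np.ndarray:
        """Values on the analysis scale: ln(concentration) if configured."""
        if analyte.log_transform:
            return self.log_values(analyte.name)
        return self.values[analyte.name].copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_id, "x": self.x, "y": self.y})
        for k, v in self.values.items():
            df[k] = v
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_geojson(self, path) -> None:
        feats = []
        for i in range(self.n):
            props = {"sample_id": str(self.sample_id[i])}
            props.update({k: float(v[i]) for k, v in self.values.items()})
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(self.x[i]), float(self.y[i])]},
                    "properties": props,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SampleSet":
        df = pd.read_csv(path)
        required = {"sample_id", "x", "y"}
        if not required.issubset(df.columns):
            raise ValidationError(f"CSV must have columns {sorted(required)}, got {list(df.columns)}")
        analytes = [c for c in df.columns if c not in required]
        return cls(
            df["sample_id"].astype(str).to_numpy(),
            df["x"].to_numpy(),
            df["y"].to_numpy(),
            {a: df[a].to_numpy() for a in analytes},
            **kwargs,
        )

    @classmethod
    def from_geojson(cls, path, **kwargs) -> "SampleSet":
        with open(path) as fh:
            gj = json.load(fh)
        ids, xs, ys = [], [], []
        vals: dict[str, list[float]] = {}
        for feat in gj["features"]:
            geom = feat["geometry"]
            if geom["type"] != "Point":
                raise ValidationError(f"only Point features supported, got {geom['type']}")
            xs.append(geom["coordinates"][0])
            ys.append(geom["coordinates"][1])
            props = dict(feat.get("properties") or {})
            ids.append(str(props.pop("sample_id")))
            for k, v in props.items():
                vals.setdefault(k, []).append(float(v))
        return cls(ids, xs, ys, {k: np.asarray(v) for k, v in vals.items()}, **kwargs)

    def pairwise_distances(self) -> np.ndarray:
        """Full symmetric Euclidean distance matrix (cached)."""
        if self._dist is None:
            self._dist = squareform(pdist(self.coords))
        return self._dist


def pairwise_distances(samples: SampleSet) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    return samples.pairwise_distances()


@dataclass
class DistanceBandWeights:
    """Binary distance-band spatial weights.

    ``w_ij = 1`` iff ``0 < d(i, j) <= threshold``; symmetric, zero diagonal.
    The raw weight sums feed the Moran's I null moments:

    - ``S0 = sum_ij w_ij`` (twice the neighbour-pair count),
    - ``S1 = 1/2 sum_ij (w_ij + w_ji)^2``,
    - ``S2 = sum_i (w_i. + w_.i)^2``.
    """

    threshold: float
    n: int
    neighbors: list[np.ndarray]  # per-site sorted neighbour index arrays
    island_ids: list = field(default_factory=list)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    @property
    def S0(self) -> float:
        return float(self.cardinalities.sum())

    @property
    def n_pairs(self) -> int:
        return int(self.S0 // 2)

    @property
    def S1(self) -> float:
        # binary symmetric: (w_ij + w_ji)^2 = 4 for each linked ordered pair
        return float(2.0 * self.S0)

    @property
    def S2(self) -> float:
        # row sum equals column sum for symmetric weights
        return float(np.sum((2.0 * self.cardinalities) ** 2))

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatial lag: per-site sum of neighbour values (binary weights)."""
        return np.array([z[nb].sum() if len(nb) else 0.0 for nb in self.neighbors])

    def dense(self) -> np.ndarray:
        """Explicit 0/1 matrix; intended for small n (testing, inspection)."""
        w = np.zeros((self.n, self.n))
        for i, nb in enumerate(self.neighbors):
            w[i, nb] = 1.0
        return w


def build_distance_band_weights(
    samples: SampleSet, threshold: float, warn_islands: bool = True
) -> DistanceBandWeights:
    """Build binary weights linking every pair within ``threshold`` distance.

    Records left with zero neighbours ("islands") trigger a warning listing
    their sample ids; downstream statistics treat them as missing
    neighbourhoods.
    """
    if not threshold > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    d = samples.pairwise_distances()
    adj = (d <= threshold) & (d > 0)
    neighbors = [np.flatnonzero(adj[i]) for i in range(samples.n)]
    islands = [samples.sample_id[i] for i, nb in enumerate(neighbors) if len(nb) == 0]
    if islands and warn_islands:
        warnings.warn(
            f"threshold {threshold} leaves {len(islands)} record(s) with no "
            f"neighbors: {islands[:10]}",
            UserWarning,
        )
    return DistanceBandWeights(threshold=float(threshold), n=samples.n,
                               neighbors=neighbors, island_ids=islands)


@dataclass(frozen=True)
class ScreeningReport:
    """Raw-vs-log distribution screening for one analyte."""

    analyte: str
    skew_raw: float
    skew_log: float
    ks_p_raw: float
    ks_p_log: float
    recommend_log: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def screen_distribution(samples: SampleSet, analyte: AnalyteConfig) -> ScreeningReport:
    """Compare raw and natural-log scales by skewness and a KS normality test.

    The log scale is recommended when it brings the sample skewness closer
    to zero — the usual situation for environmental concentrations, which
    tend to be lognormal.  The Kolmogorov–Smirnov p-value (Lilliefors-style,
    against a normal with estimated mean/SD) is reported for both scales.
    """
    raw = samples.values[analyte.name]
    if np.ptp(raw) == 0:
        raise ValidationError(f"constant {analyte.name} values: skewness undefined")
    logv = samples.log_values(analyte.name)

    def _ks_p(v: np.ndarray) -> float:
        sd = v.std(ddof=1)
        if sd == 0:
            return 0.0
        return float(stats.kstest(v, "norm", args=(v.mean(), sd)).pvalue)

    skew_raw = float(stats.skew(raw, bias=False))
    skew_log = float(stats.skew(logv, bias=False))
    return ScreeningReport(
        analyte=analyte.name,
        skew_raw=skew_raw,
        skew_log=skew_log,
        ks_p_raw=_ks_p(raw),
        ks_p_log=_ks_p(logv),
        recommend_log=abs(skew_log) < abs(skew_raw),
    )
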