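"""Single-factor pollution indexing, agreement tables, summary statistics.

The single-factor pollution index of a sample is P_i = C_i / S, the
measured concentration divided by the regulatory critical value; a sample
is *polluted* iff P_i > 1 (strict inequality; configurable).  Agreement
tables cross-classify measured against kriging-predicted pollution status
as percentages of all samples.  Prediction maps are classified into
ordinal bands at multiples of the analyte's background value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from .samples import AnalyteConfig, ValidationError
from .kriging import PredictionGrid

STATUS_LABELS = ("polluted", "unpolluted")


def single_factor_index(values, analyte: AnalyteConfig, strict: bool = True) -> pd.DataFrame:
    """Per-sample pollution index P = C/S and polluted/unpolluted status."""
    c = np.asarray(values, dtype=float)
    if np.any(c < 0):
        raise ValidationError("negative concentration in pollution assessment")
    p = c / analyte.critical_value
    polluted = p > 1.0 if strict else p >= 1.0
    return pd.DataFrame(
        {"index": p, "status": np.where(polluted, "polluted", "unpolluted")}
    )


def agreement_table(measured_status, predicted_status) -> pd.DataFrame:
    """2x2 percent-of-all-samples table, predicted in rows, measured in columns.

    The diagonal holds agreement (status preserved by interpolation); the
    measured-polluted/predicted-unpolluted cell is the *underestimation*
    of pollution, the opposite cell the overestimation.
    """
    m = np.asarray(measured_status, dtype=object)
    p = np.asarray(predicted_status, dtype=object)
    if m.shape != p.shape:
        raise ValidationError("status vectors must have equal length")
    n = m.size
    table = pd.DataFrame(0.0, index=list(STATUS_LABELS), columns=list(STATUS_LABELS))
    for row in STATUS_LABELS:  # predicted
        for col in STATUS_LABELS:  # measured
            table.loc[row, col] = 100.0 * np.sum((p == row) & (m == col)) / n
    table.index.name = "predicted"
    table.columns.name = "measured"
    return table


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    minimum: float
    maximum: float
    range: float
    sd: float
    cv_percent: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summary_stats(values) -> SummaryStats:
    """Mean / min / max / range / SD (n-1 denominator) / CV% of a value list."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values for summary statistics")
    mean = float(v.mean())
    if mean <= 0:
        raise ValidationError("CV undefined for non-positive mean")
    sd = float(v.std(ddof=1))
    return SummaryStats(
        mean=mean,
        minimum=float(v.min()),
        maximum=float(v.max()),
        range=float(v.max() - v.min()),
        sd=sd,
        cv_percent=100.0 * sd / mean,
    )


def classify_by_background(
    grid: PredictionGrid, analyte: AnalyteConfig, multipliers=(1.0, 2.0, 3.0)
) -> np.ndarray:
    """Ordinal class raster at background-value multiples.

    Class 0 is below background (value < m_0 * B); class k covers
    [m_k * B, m_{k+1} * B), the last class is open above.  Masked cells
    propagate as -1.
    """
    mult = np.asarray(multipliers, dtype=float)
    if mult[0] != 1.0 or np.any(np.diff(mult) <= 0):
        raise ValidationError("multipliers must be strictly increasing and start at 1")
    edges = mult * analyte.background_value
    cls = np.searchsorted(edges, grid.value, side="right")
    cls = np.where(grid.mask | ~np.isfinite(grid.value), -1, cls)
    return cls.astype(int)
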