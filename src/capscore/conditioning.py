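"""Post-extraction feature conditioning.

Three stages, applied per feature row and per subject, in fixed order:

1. causal moving-average smoothing (31-tap uniform FIR, "order 30") for
   every feature except the MMSD, TEO and EMD families, which encode the
   fast amplitude/frequency changes the smoother would destroy;
2. outlier replacement: values more than 4 SD from the row mean are set to
   the row median (statistics from the original row, single pass) - the
   usual 3 SD rule would flag the A-phases themselves;
3. min-max normalization to [0, 1] (a constant row maps to all zeros).

Statistics are never shared across subjects, so cross-validation stays
leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from capscore.features import FeatureMatrix, FeatureSeries


@dataclass
class ConditioningConfig:
    smoothing_order: int = 30
    outlier_sd: float = 4.0
    exempt_prefixes: tuple = ("MMSD", "TEO", "EMD")

    def __post_init__(self) -> None:
        if self.smoothing_order < 1:
            raise ValueError("smoothing_order must be >= 1")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")


def causal_moving_average(series: FeatureSeries, order: int = 30) -> FeatureSeries:
    """Mean of the current and previous ``order`` values (growing at the start)."""
    v = series.values
    cs = np.concatenate([[0.0], np.cumsum(v)])
    t = np.arange(len(v))
    starts = np.maximum(0, t - order)
    out = (cs[t + 1] - cs[starts]) / (t + 1 - starts)
    return FeatureSeries(series.name, out, series.band)


def replace_outliers(series: FeatureSeries, sd_threshold: float = 4.0) -> FeatureSeries:
    """Replace values beyond ``sd_threshold`` SDs from the mean with the median."""
    v = series.values.copy()
    sd = v.std()
    if sd == 0:
        return FeatureSeries(series.name, v, series.band)
    mask = np.abs(v - v.mean()) > sd_threshold * sd
    v[mask] = np.median(series.values)
    return FeatureSeries(series.name, v, series.band)


def minmax_normalize(series: FeatureSeries) -> FeatureSeries:
    """Map to [0, 1]; a constant series maps to all zeros."""
    v = series.values
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return FeatureSeries(series.name, np.zeros_like(v), series.band)
    return FeatureSeries(series.name, (v - lo) / (hi - lo), series.band)


def condition(matrix: FeatureMatrix, config: ConditioningConfig | None = None) -> FeatureMatrix:
    """Smooth (non-exempt rows) -> replace outliers -> normalize, row-wise."""
    config = config or ConditioningConfig()
    out = []
    for name in matrix.names:
        s = FeatureSeries(name, matrix.row(name))
        if not name.startswith(config.exempt_prefixes):
            s = causal_moving_average(s, config.smoothing_order)
        s = replace_outliers(s, config.outlier_sd)
        s = minmax_normalize(s)
        out.append(s)
    return FeatureMatrix.from_series(out, subject_id=matrix.subject_id)
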