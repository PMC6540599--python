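"""Signal conditioning and feature normalization.

Raw sensor curves are denoised with a five-point quadratic
Savitzky-Golay filter before feature extraction.  Extracted feature
columns are min-max normalized, x' = (x - x_min) / (x_max - x_min),
because the six characteristic parameters live on very different
scales (an integral over 39 s versus a per-second slope).  Fitted
normalization bounds can be applied to new data, in which case values
may legitimately fall outside [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.signal import savgol_filter
from sklearn.preprocessing import MinMaxScaler

from .samples import SensorTrace

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureMatrix

__all__ = [
    "savgol_smooth",
    "baseline_subtract",
    "NormParams",
    "fit_minmax",
    "apply_minmax",
    "normalize_features",
]

logger = logging.getLogger(__name__)

SAVGOL_WINDOW = 5
SAVGOL_POLYORDER = 2
BASELINE_MODES = ("none", "initial")


def savgol_smooth(trace: SensorTrace) -> SensorTrace:
    """Five-point, degree-2 Savitzky-Golay smoothing with mirror edges.

    Interior points receive the classical quadratic window-5 weights
    (-3, 12, 17, 12, -3)/35; the time axis is unchanged.
    """
    if trace.n < SAVGOL_WINDOW:
        raise ValueError(
            f"trace has {trace.n} points; Savitzky-Golay window is {SAVGOL_WINDOW}"
        )
    smoothed = savgol_filter(trace.values, SAVGOL_WINDOW, SAVGOL_POLYORDER, mode="mirror")
    return trace.with_values(smoothed)


def baseline_subtract(trace: SensorTrace, mode: str = "none") -> SensorTrace:
    """Optional baseline handling: ``none`` (identity) or ``initial`` (x - x[0])."""
    if mode == "none":
        return trace
    if mode == "initial":
        return trace.with_values(trace.values - trace.values[0])
    raise ValueError(f"unknown baseline mode {mode!r}; choose from {BASELINE_MODES}")


@dataclass(frozen=True)
class NormParams:
    """Per-column min-max bounds fitted on a feature matrix."""

    columns: tuple[str, ...]
    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        x_min = np.asarray(self.x_min, dtype=float)
        x_max = np.asarray(self.x_max, dtype=float)
        object.__setattr__(self, "x_min", x_min)
        object.__setattr__(self, "x_max", x_max)
        if not (len(self.columns) == x_min.size == x_max.size):
            raise ValueError("columns, x_min and x_max must have equal length")
        if np.any(x_max < x_min):
            raise ValueError("x_max must be >= x_min in every column")


def fit_minmax(fm: "FeatureMatrix") -> NormParams:
    """Fit per-column min-max bounds; constant columns are flagged."""
    if fm.n_samples == 0:
        raise ValueError("cannot fit normalization on an empty matrix")
    scaler = MinMaxScaler().fit(fm.values)
    constant = scaler.data_max_ == scaler.data_min_
    if np.any(constant):
        names = [c for c, flag in zip(fm.columns, constant) if flag]
        logger.warning(
            "constant feature columns map to 0 under min-max normalization: %s", names
        )
    return NormParams(tuple(fm.columns), scaler.data_min_, scaler.data_max_)


def apply_minmax(fm: "FeatureMatrix", params: NormParams) -> "FeatureMatrix":
    """Apply fitted bounds; new data may land outside [0, 1]."""
    if tuple(fm.columns) != params.columns:
        raise ValueError("normalization parameters were fitted on different columns")
    span = params.x_max - params.x_min
    span = np.where(span == 0, 1.0, span)  # constant columns -> 0
    values = (fm.values - params.x_min) / span
    return replace(fm, values=values)


def normalize_features(fm: "FeatureMatrix") -> "FeatureMatrix":
    """Fit on ``fm`` and transform it (training-matrix convenience)."""
    return apply_minmax(fm, fit_minmax(fm))
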