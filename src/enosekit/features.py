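"""The six characteristic parameters of a sensor response curve.

Each MOS sensor's 39-point response curve is summarized by six scalar
features before classification:

========  ====================================================================
code      definition
========  ====================================================================
``INV``   integral value: sum of the response values times the sampling
          interval — the area under the curve, total exposure response.
``WEV``   wavelet energy value: sum of squared level-4 approximation
          coefficients of a Daubechies-3 discrete wavelet decomposition
          (symmetric boundary extension) — the energy of the coarse trend.
``MGV``   maximum gradient value: slope of the chord from the initial value
          to the (first) maximum — how fast the sensor charges up.
``ADV``   average differential value: mean successive difference over the
          sampling interval; telescopes to (last - first)/((T-1)*dt).
``RSAV``  relation steady-state response average value: mean response over
          the late, stable window t >= t0.
``VARV``  variance value: population variance (denominator n) of the curve.
========  ====================================================================

A dataset of S sensors and the full six features yields an S x 6-column
feature matrix (60 columns for the 10-sensor array), ordered
sensor-major with the fixed feature order above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import pywt

from .errors import SchemaError
from .preprocessing import BASELINE_MODES, baseline_subtract, savgol_smooth
from .samples import SampleSet, SensorTrace

__all__ = [
    "FEATURE_CODES",
    "WaveletSpec",
    "FeatureConfig",
    "FeatureMatrix",
    "integral_value",
    "wavelet_energy",
    "level4_approximation",
    "max_gradient",
    "average_differential",
    "steady_state_mean",
    "variance_value",
    "extract_features",
    "CurveFeaturizer",
]

#: Canonical feature order; feature-matrix columns always follow it.
FEATURE_CODES = ("INV", "WEV", "MGV", "ADV", "RSAV", "VARV")

COLUMN_SEP = "__"


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet decomposition settings for the energy feature."""

    family: str = "db3"
    levels: int = 4
    extension: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings shared by all features.

    ``smooth`` applies Savitzky-Golay denoising before extraction;
    ``baseline`` optionally subtracts the initial response; ``t0`` is
    the start (seconds) of the steady-state window for RSAV.
    """

    smooth: bool = True
    baseline: str = "none"
    t0: float = 29.0
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)

    def __post_init__(self) -> None:
        if self.baseline not in BASELINE_MODES:
            raise ValueError(
                f"unknown baseline mode {self.baseline!r}; choose from {BASELINE_MODES}"
            )
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------


def integral_value(trace: SensorTrace, dt: float | None = None) -> float:
    """Area under the response curve: sum(values) * dt."""
    dt = trace.dt if dt is None else float(dt)
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(np.sum(trace.values) * dt)


def level4_approximation(
    trace: SensorTrace, spec: WaveletSpec | None = None
) -> np.ndarray:
    """Approximation coefficients after the configured multilevel DWT.

    A 39-point trace under a four-level db3 decomposition with symmetric
    extension yields exactly 7 coefficients.
    """
    spec = spec or WaveletSpec()
    wavelet = pywt.Wavelet(spec.family)
    if trace.n < wavelet.dec_len:
        raise ValueError(
            f"trace has {trace.n} points; the {spec.family} filter needs at least "
            f"{wavelet.dec_len}"
        )
    with warnings.catch_warnings():
        # decomposing past dwt_max_level is intentional: the coarse trend of a
        # short trace is boundary-dominated but still well defined
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(trace.values, wavelet, mode=spec.extension, level=spec.levels)
    return np.asarray(coeffs[0])


def wavelet_energy(trace: SensorTrace, spec: WaveletSpec | None = None) -> float:
    """Sum of squared approximation coefficients of the level-4 decomposition."""
    approx = level4_approximation(trace, spec)
    return float(np.sum(approx**2))


def max_gradient(trace: SensorTrace) -> float:
    """Chord slope from the initial value to the first maximum.

    Returns 0 when the maximum sits at t = 0 (non-increasing curve), the
    degenerate convention that avoids dividing by zero.
    """
    imax = int(np.argmax(trace.values))
    if imax == 0:
        return 0.0
    return float((trace.values[imax] - trace.values[0]) / trace.times[imax])


def average_differential(trace: SensorTrace, dt: float | None = None) -> float:
    """Mean successive difference per sampling interval."""
    dt = trace.dt if dt is None else float(dt)
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(np.mean(np.diff(trace.values)) / dt)


def steady_state_mean(trace: SensorTrace, t0: float = 29.0) -> float:
    """Mean response over the stable window t >= t0."""
    if not t0 < trace.times[-1]:
        raise ValueError(
            f"t0={t0} must lie before the last sampling time {trace.times[-1]}"
        )
    window = trace.values[trace.times >= t0]
    return float(np.mean(window))


def variance_value(trace: SensorTrace) -> float:
    """Population variance (denominator n) of the response values."""
    return float(np.var(trace.values))


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Samples x (sensor, feature) value matrix with grade labels.

    Column names are ``<sensor_id>__<feature_code>`` in sensor-major
    order with the canonical feature order.
    """

    sample_ids: list[str]
    grades: np.ndarray
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.columns = list(self.columns)
        self.grades = np.asarray(self.grades, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.sample_ids), len(self.columns)
        if self.values.shape != (n, p):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples x {p} columns"
            )
        if self.grades.shape != (n,):
            raise ValueError("grades must have one entry per sample")
        if len(set(self.columns)) != p:
            raise SchemaError("duplicate feature-matrix column names")
        if n and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def select_feature(self, code: str) -> "FeatureMatrix":
        """Single-feature block: the per-sensor columns of one feature code."""
        if code not in FEATURE_CODES:
            raise ValueError(f"unknown feature code {code!r}")
        keep = [i for i, c in enumerate(self.columns) if c.endswith(COLUMN_SEP + code)]
        if not keep:
            raise ValueError(f"matrix has no columns for feature {code!r}")
        return replace(
            self,
            columns=[self.columns[i] for i in keep],
            values=self.values[:, keep],
        )

    def take(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            grades=self.grades[idx],
            values=self.values[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "grade", self.grades)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        missing = {"sample_id", "grade"} - set(df.columns)
        if missing:
            raise SchemaError(f"feature table is missing columns: {sorted(missing)}")
        feature_cols = [c for c in df.columns if c not in ("sample_id", "grade")]
        for col in feature_cols:
            parts = col.split(COLUMN_SEP)
            if len(parts) != 2 or parts[1] not in FEATURE_CODES:
                raise SchemaError(
                    f"column {col!r} is not of the form <sensor>{COLUMN_SEP}<code> "
                    f"with code in {FEATURE_CODES}"
                )
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            grades=df["grade"].to_numpy(dtype=int),
            columns=feature_cols,
            values=df[feature_cols].to_numpy(dtype=float),
        )


def _feature_value(code: str, trace: SensorTrace, cfg: FeatureConfig) -> float:
    if code == "INV":
        return integral_value(trace)
    if code == "WEV":
        return wavelet_energy(trace, cfg.wavelet)
    if code == "MGV":
        return max_gradient(trace)
    if code == "ADV":
        return average_differential(trace)
    if code == "RSAV":
        return steady_state_mean(trace, cfg.t0)
    if code == "VARV":
        return variance_value(trace)
    raise ValueError(f"unknown feature code {code!r}")


def extract_features(
    sample_set: SampleSet,
    codes: Sequence[str] | None = None,
    cfg: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Extract the requested features from every sensor of every sample.

    Smoothing (and any configured baseline handling) is applied to each
    trace before extraction.  Columns come out sensor-major in the
    canonical feature order, independent of the order of ``codes``.
    """
    cfg = cfg or FeatureConfig()
    if codes is None:
        selected = list(FEATURE_CODES)
    else:
        unknown = [c for c in codes if c not in FEATURE_CODES]
        if unknown:
            raise ValueError(f"unknown feature codes: {unknown}")
        if not codes:
            raise ValueError("codes must be a non-empty subset of the six features")
        selected = [c for c in FEATURE_CODES if c in set(codes)]
    if len(sample_set) == 0:
        raise ValueError("cannot extract features from an empty sample set")

    columns = [
        f"{sid}{COLUMN_SEP}{code}" for sid in sample_set.sensor_ids for code in selected
    ]
    rows = np.empty((len(sample_set), len(columns)))
    for i, record in enumerate(sample_set):
        j = 0
        for trace in record.traces:
            prepared = savgol_smooth(trace) if cfg.smooth else trace
            prepared = baseline_subtract(prepared, cfg.baseline)
            for code in selected:
                rows[i, j] = _feature_value(code, prepared, cfg)
                j += 1
    return FeatureMatrix(
        sample_ids=sample_set.sample_ids,
        grades=sample_set.grades,
        columns=columns,
        values=rows,
    )


class CurveFeaturizer:
    """Transformer-style wrapper around :func:`extract_features`.

    Stateless (``fit`` is a no-op); provided so the extraction step
    composes with estimator-style pipelines.
    """

    def __init__(self, codes: Sequence[str] | None = None, cfg: FeatureConfig | None = None):
        self.codes = codes
        self.cfg = cfg

    def fit(self, X: SampleSet, y=None) -> "CurveFeaturizer":
        return self

    def transform(self, X: SampleSet) -> FeatureMatrix:
        return extract_features(X, codes=self.codes, cfg=self.cfg)

    def fit_transform(self, X: SampleSet, y=None) -> FeatureMatrix:
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"codes": self.codes, "cfg": self.cfg}

    def set_params(self, **params) -> "CurveFeaturizer":
        for key, value in params.items():
            if key not in ("codes", "cfg"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self
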