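"""Synthetic MOS sensor-array response generator.

The fish-meal measurements behind the original freshness study are not
publicly available, so this module generates datasets with the same
statistical structure: 6 storage grades x 30 replicate measurements,
10 sensors sampled at 1 Hz for 39 s, rise-to-plateau response curves
whose plateaus depend on sensor and grade, and replicate noise small
enough that per-sensor repeatability (RSD of the steady-state mean)
stays below 5 %.

The response model is a first-order exponential rise toward a plateau,

    x_s(t) = b_s + A[s, g] * (1 - exp(-t / tau_s)) + eps_t,
    eps_t ~ Normal(0, noise_sd_frac * A[s, g])  (i.i.d. per time point),

which captures the adsorption kinetics of a heated MOS element exposed
to a step change in volatile concentration: a fast initial rise whose
rate constant ``tau_s`` is a sensor property, saturating at a plateau
whose height ``A[s, g]`` encodes how strongly the grade-``g`` volatile
profile excites sensor ``s``.

Two amplitude presets are provided.  ``paper_like`` mimics the observed
grade structure of spoiling fish meal: grades 1-5 have closely spaced
plateaus (fresh samples emit similar volatiles) while grade 6 jumps
strongly, most of all on the ammonia-analog sensor (S9), because rotten
samples release ammonia and amines.  ``separable`` spaces all six
grades widely on every sensor and is used for design-controlled
classifier checks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .samples import SampleRecord, SampleSet, SensorTrace

__all__ = [
    "SyntheticConfig",
    "generate_trace",
    "generate_dataset",
    "paper_like_preset",
    "separable_preset",
    "preset",
    "DEFAULT_ACID_VALUES",
]

#: Acid value (mg KOH / g) attached to each storage grade as metadata.
DEFAULT_ACID_VALUES = {1: 2.99, 2: 3.78, 3: 4.63, 4: 5.40, 5: 6.58, 6: 9.25}

#: Index (0-based) of the ammonia-analog sensor in the default layout.
AMMONIA_SENSOR_INDEX = 8  # "S9": responds to ammonia / amines of spoilage

# Relative sensitivity of each sensor to the fish-meal volatile load.
_BASE_SENSITIVITY = np.array([1.2, 0.8, 1.0, 1.5, 0.7, 0.9, 0.6, 1.1, 0.9, 1.0])


def _default_sensor_ids(n: int) -> tuple[str, ...]:
    return tuple(f"S{i + 1}" for i in range(n))


def _paper_like_amplitudes(n_sensors: int = 10, n_grades: int = 6) -> np.ndarray:
    """Plateau matrix with overlapping grades 1..(G-1) and a rotten jump at G."""
    base = np.resize(_BASE_SENSITIVITY, n_sensors)
    amp = np.empty((n_sensors, n_grades))
    for g in range(1, n_grades):  # small monotone increments for fresh grades
        amp[:, g - 1] = base * (1.0 + 0.03 * (g - 1))
    jump = np.full(n_sensors, 0.35)
    if n_sensors > AMMONIA_SENSOR_INDEX:
        jump[AMMONIA_SENSOR_INDEX] = 4.0
    amp[:, n_grades - 1] = base * (1.0 + 0.03 * (n_grades - 2) + jump)
    return amp


def _separable_amplitudes(n_sensors: int = 10, n_grades: int = 6) -> np.ndarray:
    """Plateau matrix with wide, monotone grade spacing on every sensor."""
    base = np.resize(_BASE_SENSITIVITY, n_sensors)
    grades = np.arange(1, n_grades + 1)
    return base[:, None] * (0.4 + 0.3 * grades[None, :])


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic sensor-array generator.

    Defaults reproduce the study conditions the analysis assumes:
    6 grades x 30 replicates, 10 sensors, 39 samples at 1 Hz, unit
    baseline, 2 % replicate noise, and the ``paper_like`` plateau
    structure.
    """

    n_grades: int = 6
    replicates_per_grade: int = 30
    n_sensors: int = 10
    n_timepoints: int = 39
    dt: float = 1.0
    baseline: float | np.ndarray = 1.0
    amplitude_matrix: np.ndarray | None = None
    tau: float | np.ndarray | None = None
    noise_sd_frac: float = 0.02
    drift_per_s: float = 0.0
    seed: int = 0
    sensor_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_grades, self.replicates_per_grade, self.n_sensors) < 1:
            raise ValueError("counts must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need at least two time points")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be non-negative")
        baseline = np.broadcast_to(
            np.asarray(self.baseline, dtype=float), (self.n_sensors,)
        ).copy()
        self.baseline = baseline
        if self.amplitude_matrix is None:
            self.amplitude_matrix = _paper_like_amplitudes(self.n_sensors, self.n_grades)
        self.amplitude_matrix = np.asarray(self.amplitude_matrix, dtype=float)
        if self.amplitude_matrix.shape != (self.n_sensors, self.n_grades):
            raise ValueError(
                "amplitude_matrix must have shape (n_sensors, n_grades)="
                f"{(self.n_sensors, self.n_grades)}, got {self.amplitude_matrix.shape}"
            )
        if np.any(self.amplitude_matrix < 0):
            raise ValueError("plateau amplitudes must be non-negative")
        if self.tau is None:
            self.tau = np.linspace(3.0, 8.0, self.n_sensors)
        self.tau = np.broadcast_to(
            np.asarray(self.tau, dtype=float), (self.n_sensors,)
        ).copy()
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")
        if not self.sensor_ids:
            self.sensor_ids = _default_sensor_ids(self.n_sensors)
        self.sensor_ids = tuple(self.sensor_ids)
        if len(self.sensor_ids) != self.n_sensors:
            raise ValueError("sensor_ids length must equal n_sensors")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_grades": int(self.n_grades),
            "replicates_per_grade": int(self.replicates_per_grade),
            "n_sensors": int(self.n_sensors),
            "n_timepoints": int(self.n_timepoints),
            "dt": float(self.dt),
            "baseline": np.asarray(self.baseline).tolist(),
            "amplitude_matrix": np.asarray(self.amplitude_matrix).tolist(),
            "tau": np.asarray(self.tau).tolist(),
            "noise_sd_frac": float(self.noise_sd_frac),
            "drift_per_s": float(self.drift_per_s),
            "seed": int(self.seed),
            "sensor_ids": list(self.sensor_ids),
        }

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
        data = dict(data)
        if "sensor_ids" in data:
            data["sensor_ids"] = tuple(data["sensor_ids"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha1(text.encode()).hexdigest()[:12]


def generate_trace(
    cfg: SyntheticConfig, sensor: int, grade: int, rng: np.random.Generator
) -> SensorTrace:
    """One noisy rise-to-plateau curve for ``sensor`` (0-based) and ``grade`` (1-based)."""
    if not 0 <= sensor < cfg.n_sensors:
        raise ValueError(f"sensor index {sensor} out of range 0..{cfg.n_sensors - 1}")
    if not 1 <= grade <= cfg.n_grades:
        raise ValueError(f"grade {grade} out of range 1..{cfg.n_grades}")
    t = np.arange(cfg.n_timepoints) * cfg.dt
    amp = cfg.amplitude_matrix[sensor, grade - 1]
    clean = cfg.baseline[sensor] + amp * (1.0 - np.exp(-t / cfg.tau[sensor]))
    if cfg.drift_per_s:
        clean = clean + cfg.drift_per_s * t
    noise = rng.normal(0.0, cfg.noise_sd_frac * amp, size=t.size)
    return SensorTrace(cfg.sensor_ids[sensor], t, clean + noise)


def generate_dataset(cfg: SyntheticConfig) -> SampleSet:
    """Full synthetic campaign: every grade measured ``replicates_per_grade`` times."""
    rng = np.random.default_rng(cfg.seed)
    records: list[SampleRecord] = []
    for grade in range(1, cfg.n_grades + 1):
        acid = DEFAULT_ACID_VALUES.get(grade) if cfg.n_grades == 6 else None
        for rep in range(1, cfg.replicates_per_grade + 1):
            traces = tuple(
                generate_trace(cfg, s, grade, rng) for s in range(cfg.n_sensors)
            )
            records.append(
                SampleRecord(f"G{grade}R{rep:02d}", grade, traces, acid_value=acid)
            )
    return SampleSet(records, provenance=f"enosekit-synthetic:{cfg.config_hash()}")


def paper_like_preset(seed: int = 0) -> SyntheticConfig:
    """Grades 1-5 closely spaced, grade 6 strongly separated (default preset)."""
    return SyntheticConfig(seed=seed)


def separable_preset(seed: int = 0) -> SyntheticConfig:
    """All six grades widely spaced: pairwise plateau gaps >= 5 noise sd."""
    return SyntheticConfig(amplitude_matrix=_separable_amplitudes(), seed=seed)


def preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Look up a named preset (``paper_like`` or ``separable``)."""
    presets = {"paper_like": paper_like_preset, "separable": separable_preset}
    try:
        return presets[name](seed=seed)
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        ) from None
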