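"""Containers for electronic-nose measurements.

One measurement draws the headspace of a sample over a metal-oxide
(MOS) gas-sensor array and records every sensor's response at a fixed
sampling interval.  :class:`SensorTrace` holds a single sensor's
time-ordered response curve, :class:`SampleRecord` groups the traces of
one measurement together with its storage-grade label, and
:class:`SampleSet` is an ordered collection of records sharing a sensor
layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .errors import SchemaError

__all__ = ["SensorTrace", "SampleRecord", "SampleSet"]


@dataclass(frozen=True)
class SensorTrace:
    """Time-ordered response of one gas sensor during one measurement.

    Parameters
    ----------
    sensor_id : str
        Label of the sensor (e.g. ``"S9"``).
    times : array-like of float
        Sampling times in seconds, strictly increasing, starting at 0.
    values : array-like of float
        Sensor response at each time, in response units (dimensionless
        conductance-derived signal).
    """

    sensor_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if times.size < 2:
            raise ValueError("a trace needs at least two samples")
        if times[0] != 0.0:
            raise ValueError("trace time axis must start at 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("trace times must be strictly increasing")

    @classmethod
    def from_values(
        cls, values: Sequence[float], dt: float = 1.0, sensor_id: str = "S1"
    ) -> "SensorTrace":
        """Build a trace on the uniform axis ``0, dt, 2*dt, ...``."""
        values = np.asarray(values, dtype=float)
        return cls(sensor_id, np.arange(values.size) * float(dt), values)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def dt(self) -> float:
        """Sampling interval of the first step (the axis is assumed uniform)."""
        return float(self.times[1] - self.times[0])

    def with_values(self, values: Sequence[float]) -> "SensorTrace":
        """Same sensor and time axis, new response values."""
        return SensorTrace(self.sensor_id, self.times, np.asarray(values, dtype=float))


@dataclass(frozen=True)
class SampleRecord:
    """One labelled measurement: the traces of every sensor plus metadata.

    ``grade`` is the storage-time grade (1 = freshest).  ``acid_value``
    is the free-fatty-acid titration index (mg KOH per g) used to assign
    the grade; it is pass-through metadata and never drives computation.
    """

    sample_id: str
    grade: int
    traces: tuple[SensorTrace, ...]
    acid_value: float | None = None

    def __post_init__(self) -> None:
        traces = tuple(self.traces)
        object.__setattr__(self, "traces", traces)
        if not traces:
            raise ValueError(f"sample {self.sample_id!r} has no traces")
        if int(self.grade) < 1:
            raise ValueError("grade labels start at 1")
        ref = traces[0].times
        for tr in traces[1:]:
            if tr.times.shape != ref.shape or np.any(tr.times != ref):
                raise SchemaError(
                    f"sample {self.sample_id!r}: sensors disagree on the time axis"
                )
        ids = [tr.sensor_id for tr in traces]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"sample {self.sample_id!r}: duplicate sensor ids")

    @property
    def sensor_ids(self) -> tuple[str, ...]:
        return tuple(tr.sensor_id for tr in self.traces)

    @property
    def times(self) -> np.ndarray:
        return self.traces[0].times

    def trace(self, sensor_id: str) -> SensorTrace:
        for tr in self.traces:
            if tr.sensor_id == sensor_id:
                return tr
        raise KeyError(f"sample {self.sample_id!r} has no sensor {sensor_id!r}")


@dataclass
class SampleSet:
    """Ordered collection of measurements sharing one sensor layout."""

    records: list[SampleRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = list(self.records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise SchemaError(f"duplicate sample id {rec.sample_id!r}")
            seen.add(rec.sample_id)
        if self.records:
            ref = self.records[0].sensor_ids
            for rec in self.records[1:]:
                if rec.sensor_ids != ref:
                    raise SchemaError(
                        f"sample {rec.sample_id!r}: sensor layout differs from "
                        f"the first record"
                    )

    @property
    def sensor_ids(self) -> tuple[str, ...]:
        return self.records[0].sensor_ids if self.records else ()

    @property
    def grades(self) -> np.ndarray:
        return np.array([rec.grade for rec in self.records], dtype=int)

    @property
    def sample_ids(self) -> list[str]:
        return [rec.sample_id for rec in self.records]

    def of_grade(self, grade: int) -> list[SampleRecord]:
        return [rec for rec in self.records if rec.grade == int(grade)]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SampleRecord:
        return self.records[i]

    def with_records(self, records: Sequence[SampleRecord]) -> "SampleSet":
        return replace(self, records=list(records))
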