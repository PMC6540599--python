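"""Kovats retention index against an n-alkane ladder.

Under a linear temperature program the retention index of a compound
eluting between the C_n and C_(n+1) n-alkanes is

    RI = 100 n + 100 (T_Rx - T_Rn) / (T_Rn+1 - T_Rn),

a linear interpolation that is 100 n exactly at every alkane rung.
The ladder (e.g. C7-C40 authentic standards) is read from a
two-column CSV ``carbon_number,retention_time_min``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["AlkaneLadder", "retention_index", "retention_indices"]

LADDER_COLUMNS = ["carbon_number", "retention_time_min"]


@dataclass(frozen=True)
class AlkaneLadder:
    """Reference n-alkane series: carbon numbers and retention times (min)."""

    carbon_numbers: np.ndarray
    retention_times: np.ndarray

    def __post_init__(self) -> None:
        carbons = np.asarray(self.carbon_numbers, dtype=int)
        times = np.asarray(self.retention_times, dtype=float)
        object.__setattr__(self, "carbon_numbers", carbons)
        object.__setattr__(self, "retention_times", times)
        if carbons.size != times.size:
            raise ValueError("carbon numbers and retention times must align")
        if carbons.size < 2:
            raise ValueError("an alkane ladder needs at least two rungs")
        if np.any(np.diff(carbons) <= 0):
            raise ValueError("carbon numbers must be strictly increasing")
        if np.any(np.diff(times) <= 0):
            raise ValueError("retention times must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlkaneLadder":
        table = pd.read_csv(path)
        missing = set(LADDER_COLUMNS) - set(table.columns)
        if missing:
            raise SchemaError(f"alkane ladder is missing columns {sorted(missing)}")
        return cls(
            table["carbon_number"].to_numpy(dtype=int),
            table["retention_time_min"].to_numpy(dtype=float),
        )


def retention_index(t_rx: float, ladder: AlkaneLadder) -> float:
    """Retention index of a compound with retention time ``t_rx`` minutes.

    Brackets are left-closed (T_Rn <= t_rx < T_Rn+1), with the final
    rung included; times outside the ladder range raise.
    """
    times = ladder.retention_times
    carbons = ladder.carbon_numbers
    t_rx = float(t_rx)
    if t_rx < times[0] or t_rx > times[-1]:
        raise ValueError(
            f"retention time {t_rx} min outside the ladder range "
            f"[{times[0]}, {times[-1]}]"
        )
    if t_rx == times[-1]:
        return 100.0 * carbons[-1]
    j = int(np.searchsorted(times, t_rx, side="right")) - 1
    n, n_next = carbons[j], carbons[j + 1]
    frac = (t_rx - times[j]) / (times[j + 1] - times[j])
    return float(100.0 * n + 100.0 * (n_next - n) * frac)


def retention_indices(
    compounds: pd.DataFrame, ladder: AlkaneLadder, time_column: str = "retention_time_min"
) -> pd.DataFrame:
    """Add a ``retention_index`` column to a compound table."""
    if time_column not in compounds.columns:
        raise SchemaError(f"compound table is missing column {time_column!r}")
    out = compounds.copy()
    out["retention_index"] = [
        retention_index(t, ladder) for t in out[time_column].astype(float)
    ]
    return out
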