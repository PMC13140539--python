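"""Measured mass isotopomer distributions.

CSV schema (header required, UTF-8, decimal point)::

    emu_id,time,mass_shift,value,sd

One row per (EMU, time point, mass shift).  Standard deviations must be
strictly positive — a zero sd would weight a record infinitely and is
rejected.  Within each (EMU, time point) the values are expected to sum
to one up to a measurement-error tolerance of +-0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MeasurementSet", "MeasurementError"]

_COLUMNS = ["emu_id", "time", "mass_shift", "value", "sd"]


class MeasurementError(ValueError):
    pass


@dataclass
class MeasurementSet:
    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise MeasurementError(f"measurement table lacks columns {missing}")
        self.frame = self.frame[_COLUMNS].reset_index(drop=True)
        if (self.frame["sd"] <= 0).any():
            bad = self.frame.loc[self.frame["sd"] <= 0].iloc[0]
            raise MeasurementError(
                f"record ({bad.emu_id}, t={bad.time}, M+{int(bad.mass_shift)}) has "
                "non-positive sd; zero-sd records are rejected rather than "
                "infinitely weighted"
            )
        sums = self.frame.groupby(["emu_id", "time"])["value"].sum()
        off = sums[(sums - 1.0).abs() > 0.05]
        if len(off):
            key = off.index[0]
            raise MeasurementError(
                f"MID of {key[0]} at t={key[1]} sums to {off.iloc[0]:.3f}, "
                "outside 1 +- 0.05"
            )

    # -- constructors --------------------------------------------------
    @classmethod
    def from_records(cls, rows, metadata: dict | None = None) -> "MeasurementSet":
        return cls(pd.DataFrame(rows, columns=_COLUMNS), metadata or {})

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "MeasurementSet":
        return cls(pd.read_csv(path), metadata or {})

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False)

    # -- views ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def emu_timepoints(self) -> list[tuple[str, float]]:
        """Distinct (emu_id, time) pairs in deterministic order."""
        pairs = self.frame[["emu_id", "time"]].drop_duplicates()
        return sorted((r.emu_id, float(r.time)) for r in pairs.itertuples())

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.frame["time"].unique().tolist())

    def values_and_sds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.frame["value"].to_numpy(float), self.frame["sd"].to_numpy(float)

    def subset_times(self, times) -> "MeasurementSet":
        keep = self.frame["time"].isin(list(times))
        return MeasurementSet(self.frame[keep].copy(), dict(self.metadata))
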