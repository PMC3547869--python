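"""Timestamped scalar signals.

A :class:`TimeSeries` holds one scalar observable sampled at strictly
increasing time stamps — an impedance magnitude, a total TIRF intensity, or
any per-frame image descriptor. It is the common currency passed between the
simulator, the image-analysis stage and the signal-analysis toolkit, and it
round-trips through a two-column CSV (``time_s,value``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """A scalar signal on explicit time stamps.

    Parameters
    ----------
    time_s : array-like
        Sample times in seconds, strictly increasing.
    value : array-like
        One scalar per time stamp. NaN marks a missing sample (e.g. a frame
        in which no cell was detected); it is never silently treated as 0.
    units : str
        Free-text unit label ("ohm", "a.u.", "um^2", ...).
    label : str
        Source label used in reports ("impedance", "tirf_intensity", ...).
    """

    time_s: np.ndarray
    value: np.ndarray
    units: str = ""
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.ndim != 1 or self.value.ndim != 1:
            raise ValueError("time_s and value must be 1-D")
        if self.time_s.size != self.value.size:
            raise ValueError(
                f"length mismatch: {self.time_s.size} times vs "
                f"{self.value.size} values"
            )
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if not np.all(np.isfinite(self.time_s)):
            raise ValueError("time stamps must be finite")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if len(self) else 0.0

    @property
    def median_dt_s(self) -> float:
        """Typical sampling interval (median of successive differences)."""
        if len(self) < 2:
            raise ValueError("need at least two samples for an interval")
        return float(np.median(np.diff(self.time_s)))

    def with_values(self, value: np.ndarray, **meta_updates) -> "TimeSeries":
        """Copy of this series with new values on the same time base."""
        out = replace(self, value=np.asarray(value, dtype=float))
        out.meta = {**self.meta, **meta_updates}
        return out

    def dropna(self) -> "TimeSeries":
        keep = np.isfinite(self.value)
        return replace(self, time_s=self.time_s[keep], value=self.value[keep])

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time_s, "value": self.value}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, units: str = "", label: str = ""
    ) -> "TimeSeries":
        df = pd.read_csv(path)
        if not {"time_s", "value"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns time_s,value")
        return cls(
            df["time_s"].to_numpy(),
            df["value"].to_numpy(),
            units=units,
            label=label or Path(path).stem,
        )
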