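"""Minimal time-series container shared by the simulation and analysis layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TimeSeries:
    """Sampled multivariate time series.

    ``times`` (min) strictly increasing; ``values`` maps variable name to an
    array of equal length.
    """

    times: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for name, arr in self.values.items():
            if arr.shape != self.times.shape:
                raise ValueError(f"variable {name!r} length does not match times")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"variable {name!r} contains non-finite values")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, **self.values})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time_col: str = "time_min") -> "TimeSeries":
        cols = [c for c in df.columns if c != time_col]
        return cls(df[time_col].to_numpy(), {c: df[c].to_numpy() for c in cols})
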