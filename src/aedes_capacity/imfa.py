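"""The weekly trap index (IMFA) container shared across the package.

IMFA (Mean Female *Aedes* Index) is the weekly ratio of female *Ae. aegypti*
captured to traps inspected in an area — the observable that both the
surveillance program and the model report.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["ImfaSeries"]


@dataclass(frozen=True)
class ImfaSeries:
    """Weekly trap index for one area.

    Parameters
    ----------
    weeks
        Week start dates (7-day grid); strictly increasing.
    values
        Mosquitoes per trap per week; non-negative (NaN marks missing
        surveillance weeks).
    n_traps
        Number of traps the index was formed over.
    smoothed
        Whether a local-polynomial smoother has been applied.
    area_id
        Optional label.
    """

    weeks: pd.DatetimeIndex
    values: np.ndarray
    n_traps: int
    smoothed: bool = False
    area_id: str | None = None

    def __post_init__(self) -> None:
        weeks = pd.DatetimeIndex(self.weeks)
        values = np.asarray(self.values, dtype=float)
        if len(weeks) == 0:
            raise ValueError("ImfaSeries must be non-empty")
        if len(weeks) != len(values):
            raise ValueError("weeks and values must have equal length")
        if len(weeks) > 1 and not (weeks.is_monotonic_increasing and not weeks.has_duplicates):
            raise ValueError("weeks must be strictly increasing")
        finite = values[np.isfinite(values)]
        if np.any(finite < 0):
            raise ValueError("IMFA values must be non-negative")
        object.__setattr__(self, "weeks", weeks)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values, smoothed: bool | None = None) -> "ImfaSeries":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            smoothed=self.smoothed if smoothed is None else smoothed,
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.weeks, name="imfa")

    def dropna(self) -> "ImfaSeries":
        mask = np.isfinite(self.values)
        return replace(self, weeks=self.weeks[mask], values=self.values[mask])
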