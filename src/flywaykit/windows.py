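"""Equal-height latitudinal analysis windows along the projected y-axis."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WindowGrid", "assign_windows"]


@dataclass(frozen=True)
class WindowGrid:
    """``count`` contiguous half-open slabs [y0 + (w-1)h, y0 + w*h), w = 1..count.

    Window 1 is the southernmost.  All units meters.
    """

    y0: float
    height: float
    count: int

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("window height must be positive")
        if self.count < 1:
            raise ValueError("window count must be >= 1")

    @property
    def y_top(self) -> float:
        return self.y0 + self.count * self.height

    @property
    def span(self) -> float:
        return self.count * self.height

    def y_mid(self, window) -> np.ndarray:
        """Vertical midpoint of window(s), meters."""
        w = np.asarray(window, dtype=float)
        return self.y0 + (w - 0.5) * self.height

    def edges(self) -> np.ndarray:
        return self.y0 + self.height * np.arange(self.count + 1)

    @classmethod
    def from_span(cls, ymin: float, ymax: float, height: float) -> "WindowGrid":
        """Grid anchored flush at the data minimum, covering [ymin, ymax]."""
        if ymax < ymin:
            raise ValueError("ymax < ymin")
        count = max(1, math.ceil((ymax - ymin) / height)) if ymax > ymin else 1
        return cls(y0=ymin, height=height, count=count)


def assign_windows(points: pd.DataFrame, grid: WindowGrid) -> pd.DataFrame:
    """Attach a 1-based ``window`` index column (nullable Int64).

    Windows are lower-inclusive / upper-exclusive.  A point exactly on the
    grid's outermost top boundary is assigned to the last window so the
    northernmost point defining a flush grid is not lost; any other point
    outside the grid keeps ``window = <NA>`` (flagged, never dropped).
    """
    y = points["y"].to_numpy(dtype=float)
    w = np.floor((y - grid.y0) / grid.height).astype(np.int64) + 1
    w_ser = pd.Series(w, index=points.index, dtype="Int64")
    at_top = y == grid.y_top
    w_ser[at_top] = grid.count
    outside = (w_ser < 1) | (w_ser > grid.count)
    w_ser[outside] = pd.NA
    out = points.copy()
    out["window"] = w_ser
    return out
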