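"""Column-wise saturation masks.

A saturation artifact in an SD-OCT B-scan corrupts whole A-lines (image
columns), so the natural mask granularity is one boolean per column.  The
mask can be broadcast to a full pixel mask when patch-level bookkeeping
needs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SaturationMask:
    """Per-A-line saturation labels for one B-scan.

    Parameters
    ----------
    columns
        Boolean vector, one entry per A-line; ``True`` marks a saturated
        column.
    """

    columns: np.ndarray = field()

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns)
        if cols.ndim != 1:
            raise ValueError("mask must be a 1-D column vector")
        self.columns = cols.astype(bool)

    @property
    def width(self) -> int:
        return self.columns.size

    @property
    def n_saturated(self) -> int:
        return int(self.columns.sum())

    def runs(self) -> list[tuple[int, int]]:
        """Maximal runs of saturated columns as ``(start, length)`` pairs."""
        padded = np.concatenate(([False], self.columns, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        return [(int(s), int(e - s)) for s, e in zip(starts, ends)]

    def to_pixel_mask(self, height: int) -> np.ndarray:
        """Broadcast to a ``height × width`` boolean matrix."""
        if height <= 0:
            raise ValueError("height must be positive")
        return np.broadcast_to(self.columns, (height, self.width)).copy()

    # -- I/O: single-row CSV of 0/1 ------------------------------------
    def save_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.columns.astype(np.int8)[None, :], fmt="%d",
                   delimiter=",")

    @classmethod
    def load_csv(cls, path: str | Path) -> "SaturationMask":
        row = np.loadtxt(path, delimiter=",", dtype=np.int64)
        return cls(columns=np.atleast_1d(row).astype(bool))

    def render_strip(self, height: int = 16) -> np.ndarray:
        """8-bit strip (black = clean, white = saturated) for visual checks."""
        return np.where(self.to_pixel_mask(height), 255, 0).astype(np.uint8)
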