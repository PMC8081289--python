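"""Row-wise cubic interpolation of missing pixels.

Shared by the spline comparison baseline and by the aggregation fallback
for pixels no recoverable patch covers.  Interpolation runs independently
along each row through that row's known columns; beyond the outermost
known column values are clamped to the nearest support (cubic
extrapolation blows up at image borders).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline, interp1d


def interpolate_columns(image: np.ndarray, missing_cols: np.ndarray
                        ) -> np.ndarray:
    """Replace whole columns by per-row cubic interpolation.

    ``missing_cols`` is a boolean vector over columns; all rows share the
    same support, so a single vectorized spline handles the image.
    """
    image = np.asarray(image, dtype=np.float64)
    missing_cols = np.asarray(missing_cols, dtype=bool)
    if missing_cols.size != image.shape[1]:
        raise ValueError("missing_cols length must equal image width")
    if not missing_cols.any():
        return image.copy()
    known = np.flatnonzero(~missing_cols)
    if known.size < 4:
        raise ValueError("need at least 4 known columns for cubic splines")
    target = np.flatnonzero(missing_cols)
    spline = CubicSpline(known, image[:, known], axis=1)
    out = image.copy()
    vals = spline(np.clip(target, known[0], known[-1]))
    out[:, target] = vals
    return out


def fill_masked_pixels(image: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Fill arbitrary missing pixels row by row (cubic where possible).

    Rows with fewer than 4 known pixels fall back to linear/nearest
    interpolation; a fully missing row is filled with the mean of the
    known pixels of the image.
    """
    image = np.asarray(image, dtype=np.float64)
    missing = np.asarray(missing, dtype=bool)
    if missing.shape != image.shape:
        raise ValueError("mask shape must match image")
    out = image.copy()
    if not missing.any():
        return out
    global_fill = image[~missing].mean() if (~missing).any() else 0.0
    cols = np.arange(image.shape[1])
    for r in np.flatnonzero(missing.any(axis=1)):
        known = cols[~missing[r]]
        target = cols[missing[r]]
        if known.size == 0:
            out[r, target] = global_fill
            continue
        xq = np.clip(target, known[0], known[-1])
        if known.size >= 4:
            out[r, target] = CubicSpline(known, image[r, known])(xq)
        elif known.size >= 2:
            out[r, target] = interp1d(known, image[r, known])(xq)
        else:
            out[r, target] = image[r, known[0]]
    return out
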