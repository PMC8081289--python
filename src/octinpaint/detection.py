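"""Saturated A-line detection in the spectral domain.

An SD-OCT spectrometer pixel can store at most its full well capacity of
charge; a strong specular reflection clips the measured interferogram at
that ceiling and the reconstructed A-line appears as a bright streak.  An
A-line is flagged as saturated when its raw spectrum contains a run of at
least ``min_run`` consecutive points at or above the capacity threshold
(``min_run=1`` reproduces the plain "any point at capacity" rule; larger
values guard against single-sample noise spikes).  Detection is defined
only in the spectral domain — when no raw spectra are available the mask
must be supplied externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masks import SaturationMask
from .phantom import DEFAULT_CAPACITY, SpectralFrame


@dataclass(frozen=True)
class DetectionConfig:
    """Threshold configuration for saturation detection.

    ``capacity`` is the spectrometer full well capacity in charge counts
    (instrument-specific; the default is a measured value for one SD-OCT
    system, not a universal constant).  Comparison uses ``>= capacity``
    since stored charges may be integer-quantized.
    """

    capacity: float = DEFAULT_CAPACITY
    min_run: int = 1

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def _max_run_lengths(above: np.ndarray) -> np.ndarray:
    """Longest run of True per column of a 2-D boolean array."""
    run = np.zeros(above.shape[1], dtype=np.int64)
    best = np.zeros(above.shape[1], dtype=np.int64)
    for row in above:
        run = (run + 1) * row
        np.maximum(best, run, out=best)
    return best


def is_aline_saturated(spectrum: np.ndarray, cfg: DetectionConfig) -> bool:
    """True iff the spectrum has a run of >= ``min_run`` consecutive points
    at or above the capacity threshold."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1 or spectrum.size == 0:
        raise ValueError("spectrum must be a non-empty 1-D vector")
    above = (spectrum >= cfg.capacity)[:, None]
    return bool(_max_run_lengths(above)[0] >= cfg.min_run)


def detect_saturation(frame: SpectralFrame,
                      cfg: DetectionConfig | None = None) -> SaturationMask:
    """Label every A-line of a spectral frame, returning the column-wise
    saturation mask.

    When ``cfg`` is omitted, the frame's own capacity is used with
    ``min_run=1``.
    """
    if frame.n_points == 0 or frame.n_alines == 0:
        raise ValueError("spectral frame must be non-empty")
    if cfg is None:
        cfg = DetectionConfig(capacity=frame.capacity)
    above = frame.charges >= cfg.capacity
    best = _max_run_lengths(above)
    return SaturationMask(columns=best >= cfg.min_run)


def mask_to_pixel_mask(mask: SaturationMask, height: int) -> np.ndarray:
    """Broadcast a column mask to a ``height × width`` pixel mask."""
    return mask.to_pixel_mask(height)
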