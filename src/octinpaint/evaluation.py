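"""Masked-region image-quality metrics and the interpolation baseline.

Inpainting quality is judged only where it matters: PSNR uses the MSE over
saturated-column pixels, and SSIM averages the local SSIM map over the
same region (an 11×11 Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03 —
the standard reference parameterization).  The comparison baseline
replaces each saturated column, row by row, with cubic-spline
interpolation through the row's unsaturated columns.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

from .interp import interpolate_columns
from .masks import SaturationMask
from .phantom import MAX_VAL, MaskPattern


def psnr_masked(reference: np.ndarray, test: np.ndarray,
                pixel_mask: np.ndarray, max_val: float = MAX_VAL) -> float:
    """PSNR in dB with the MSE restricted to masked pixels; +inf if the
    images agree exactly there."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    pixel_mask = np.asarray(pixel_mask, dtype=bool)
    if reference.shape != test.shape or reference.shape != pixel_mask.shape:
        raise ValueError("shapes must match")
    if not pixel_mask.any():
        raise ValueError("mask selects no pixels")
    mse = float(np.mean((reference[pixel_mask] - test[pixel_mask]) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val ** 2 / mse))


def ssim_masked(reference: np.ndarray, test: np.ndarray,
                pixel_mask: np.ndarray | None = None,
                max_val: float = MAX_VAL,
                full_image: bool = False) -> float:
    """Mean of the local SSIM map over masked pixels (or the whole image
    with ``full_image=True``)."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("shapes must match")
    _, smap = structural_similarity(
        reference, test, data_range=max_val, gaussian_weights=True,
        sigma=1.5, use_sample_covariance=False, K1=0.01, K2=0.03, full=True)
    if full_image or pixel_mask is None:
        return float(smap.mean())
    pixel_mask = np.asarray(pixel_mask, dtype=bool)
    if pixel_mask.shape != reference.shape:
        raise ValueError("mask shape must match images")
    if not pixel_mask.any():
        raise ValueError("mask selects no pixels")
    return float(smap[pixel_mask].mean())


def spline_baseline(image: np.ndarray, mask: SaturationMask) -> np.ndarray:
    """Cubic-spline interpolation baseline.

    Each row's saturated columns are re-estimated by a cubic spline
    through that row's unsaturated columns; values beyond the outermost
    support column are clamped to the nearest support.  Unsaturated
    pixels are untouched.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape[1] != mask.width:
        raise ValueError("mask width must match image width")
    return interpolate_columns(image, mask.columns)


@dataclass(frozen=True)
class MetricsReport:
    """One method × mask-pattern × seed evaluation row."""

    method_label: str
    pattern: MaskPattern
    seed: int
    psnr_masked: float
    ssim_masked: float

    def as_row(self) -> dict:
        d = asdict(self)
        d["pattern"] = f"{self.pattern.n_pairs}x{self.pattern.run_length}"
        return d
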