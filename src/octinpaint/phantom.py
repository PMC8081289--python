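"""Synthetic OCT phantoms, saturation masks, and clipped spectral frames.

Real B-scans are not required anywhere in the package: this module builds
layered, speckled phantoms with the statistical structure the inpainting
pipeline assumes (piecewise-constant reflectivity layers under exponential
attenuation, multiplicative gamma speckle), plus the two kinds of corruption
the pipeline consumes — column-wise saturation masks and raw interferogram
spectra hard-clipped at the detector's full well capacity.

A "reference" image emulates the standard frame-averaging protocol: the
pixel-wise mean of ``n_average`` independent speckle realizations of the
same structure, which reduces speckle variance by ``1/n_average``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .masks import SaturationMask

MAX_VAL = 255.0
#: Full well capacity (detector charge counts) used as the default
#: saturation threshold throughout the package.
DEFAULT_CAPACITY = 99_975.6


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model of a layered speckle phantom.

    Attributes
    ----------
    height, width
        Image size in pixels; rows are axial depth, columns are A-lines.
    layer_boundaries
        Strictly increasing row indices of layer tops (first = tissue
        surface); rows above the surface are dark background.
    layer_reflectivities
        Mean display intensity of each layer, in ``[0, max_val]``.
    attenuation_rate
        Per-pixel exponential decay of intensity below the surface.
    speckle_shape
        Shape parameter of the unit-mean gamma multiplicative speckle;
        ``inf`` disables speckle.  Smaller = harsher speckle
        (contrast = shape**-0.5).
    n_average
        Number of independent realizations averaged into the reference.
    boundary_wobble
        Amplitude (pixels) of a fixed low-frequency lateral undulation of
        the layer boundaries, so rows are not exactly constant.
    """

    height: int = 256
    width: int = 256
    layer_boundaries: tuple[int, ...] = (40, 90, 150, 210)
    layer_reflectivities: tuple[float, ...] = (180.0, 110.0, 150.0, 70.0)
    attenuation_rate: float = 0.004
    speckle_shape: float = 4.0
    n_average: int = 5
    seed: int = 0
    max_val: float = MAX_VAL
    background_level: float = 6.0
    boundary_wobble: float = 3.0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        bnd = np.asarray(self.layer_boundaries)
        if bnd.size == 0:
            raise ValueError("at least one layer boundary required")
        if np.any(np.diff(bnd) <= 0):
            raise ValueError("layer_boundaries must be strictly increasing")
        if bnd.min() < 0 or bnd.max() >= self.height:
            raise ValueError("layer_boundaries must lie within [0, height)")
        if len(self.layer_reflectivities) != bnd.size:
            raise ValueError("one reflectivity per layer boundary required")
        if min(self.layer_reflectivities) < 0:
            raise ValueError("reflectivities must be non-negative")
        if max(self.layer_reflectivities) > self.max_val:
            raise ValueError("reflectivities must not exceed max_val")
        if not self.speckle_shape > 0:
            raise ValueError("speckle_shape must be positive (inf allowed)")
        if self.n_average < 1:
            raise ValueError("n_average must be >= 1")
        if self.attenuation_rate < 0:
            raise ValueError("attenuation_rate must be non-negative")


def default_spec_for(height: int, width: int, seed: int = 0) -> PhantomSpec:
    """Default phantom geometry rescaled to an arbitrary image size (layer
    boundaries keep their fractional depths)."""
    base = PhantomSpec()
    bnd = tuple(min(height - 1, int(round(b * height / base.height)))
                for b in base.layer_boundaries)
    return dataclasses.replace(base, height=height, width=width,
                               layer_boundaries=bnd, seed=seed)


def _reflectivity_map(spec: PhantomSpec) -> np.ndarray:
    """Noise-free layered intensity map (height × width)."""
    rows = np.arange(spec.height)[:, None]
    cols = np.arange(spec.width)[None, :]
    # fixed (seed-independent) gentle undulation so structure is identical
    # across realizations of the same spec
    bnd = np.asarray(spec.layer_boundaries, dtype=float)[:, None, None]
    phase = np.arange(len(spec.layer_boundaries), dtype=float)[:, None, None]
    wobble = spec.boundary_wobble * np.sin(
        2.0 * np.pi * 1.5 * cols[None] / max(spec.width, 1) + 0.7 * phase
    )
    bnd_cw = np.clip(bnd + wobble, 0, spec.height - 1)  # (L, 1, W)
    # enforce ordering after the wobble
    bnd_cw = np.maximum.accumulate(bnd_cw, axis=0)

    layer_idx = (rows[None] >= bnd_cw).sum(axis=0)  # (H, W), 0 = background
    refl = np.concatenate(([spec.background_level],
                           np.asarray(spec.layer_reflectivities, float)))
    base = refl[layer_idx]
    surface = bnd_cw[0, 0]  # (W,)
    depth = np.clip(rows - surface[None, :], 0, None)
    base = base * np.exp(-spec.attenuation_rate * depth)
    return np.clip(base, 0.0, spec.max_val)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one noisy speckle realization and its averaged reference.

    Returns
    -------
    noisy, reference
        ``noisy`` is the first speckle realization; ``reference`` is the
        pixel-wise mean of ``spec.n_average`` independent realizations
        (the first of which is ``noisy``, emulating averaging of
        consecutive frames that include the test frame).  Both are float64
        in ``[0, max_val]``.
    """
    base = _reflectivity_map(spec)
    if np.isinf(spec.speckle_shape):   # noise-free limit
        return base.copy(), base.copy()
    rng = np.random.default_rng(spec.seed)
    realizations = []
    for _ in range(spec.n_average):
        speckle = rng.gamma(spec.speckle_shape,
                            1.0 / spec.speckle_shape, size=base.shape)
        realizations.append(np.clip(base * speckle, 0.0, spec.max_val))
    noisy = realizations[0].copy()
    reference = (noisy.copy() if spec.n_average == 1
                 else np.mean(realizations, axis=0))
    return noisy, reference


# ---------------------------------------------------------------------------
# Saturation-mask protocol: x disjoint runs of y consecutive saturated A-lines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskPattern:
    """``n_pairs`` disjoint runs of ``run_length`` consecutive saturated
    A-lines (the x × y synthetic-artifact protocol)."""

    n_pairs: int
    run_length: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.run_length < 1:
            raise ValueError("n_pairs and run_length must be >= 1")

    @property
    def total_saturated(self) -> int:
        return self.n_pairs * self.run_length


#: The five benchmark patterns, all with x·y = 60 saturated A-lines, from
#: sparse (30 runs of 2) to dense (10 runs of 6) saturation.
DEFAULT_PATTERNS: tuple[MaskPattern, ...] = tuple(
    MaskPattern(x, y) for x, y in ((30, 2), (20, 3), (15, 4), (12, 5), (10, 6))
)


def generate_random_mask(n_alines: int, pattern: MaskPattern,
                         seed: int) -> SaturationMask:
    """Place ``pattern.n_pairs`` non-adjacent runs uniformly at random.

    Runs are separated by at least one clean column so each remains a
    maximal run of exactly ``run_length``; placement is uniform over all
    such configurations.  Raises ``ValueError`` if the pattern cannot fit.
    """
    x, y = pattern.n_pairs, pattern.run_length
    # bijection between valid start tuples and x-subsets of a reduced range
    n_slots = n_alines - y - (x - 1) * (y + 1) + 1
    if n_slots < x:
        raise ValueError(
            f"pattern {x}x{y} does not fit in {n_alines} A-lines")
    rng = np.random.default_rng(seed)
    picks = np.sort(rng.choice(n_slots, size=x, replace=False))
    starts = picks + np.arange(x) * (y + 1)
    columns = np.zeros(n_alines, dtype=bool)
    for s in starts:
        columns[s:s + y] = True
    return SaturationMask(columns=columns)


def inject_saturation(image: np.ndarray, mask: SaturationMask,
                      sat_value: float = MAX_VAL) -> np.ndarray:
    """Overlay a saturation streak: every pixel in a saturated column is set
    to ``sat_value``; all other pixels are untouched.  Idempotent."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[1] != mask.width:
        raise ValueError("mask width must match image width")
    out = image.copy()
    out[:, mask.columns] = sat_value
    return out


# ---------------------------------------------------------------------------
# Raw spectral frames with hard clipping at the full well capacity
# ---------------------------------------------------------------------------

@dataclass
class SpectralFrame:
    """Raw spectral interferogram of one B-scan.

    ``charges[k, j]`` is the charge count of spectrum point ``k`` in A-line
    ``j``; clipped entries equal ``capacity`` exactly.
    """

    charges: np.ndarray
    capacity: float = DEFAULT_CAPACITY

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.ndim != 2:
            raise ValueError("charges must be 2-D (spectrum points × A-lines)")
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        if np.any(self.charges < 0):
            raise ValueError("charges must be non-negative")

    @property
    def n_points(self) -> int:
        return self.charges.shape[0]

    @property
    def n_alines(self) -> int:
        return self.charges.shape[1]

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("charges", data=self.charges)
            ds.attrs["capacity"] = self.capacity

    @classmethod
    def load_h5(cls, path: str | Path) -> "SpectralFrame":
        with h5py.File(path, "r") as f:
            ds = f["charges"]
            return cls(charges=ds[()], capacity=float(ds.attrs["capacity"]))


def simulate_spectra(n_points: int, n_alines: int,
                     clip_columns=(), capacity: float = DEFAULT_CAPACITY,
                     seed: int = 0) -> SpectralFrame:
    """Simulate per-A-line interferogram spectra, hard-clipping the listed
    columns at the full well capacity.

    Each spectrum is a positive oscillatory signal (DC offset plus a few
    low-frequency cosines and small noise).  Columns in ``clip_columns``
    are scaled so their unclipped amplitude exceeds ``capacity`` by 50%
    and then clipped, producing runs of consecutive capacity-valued points
    at every peak; all other columns peak at 80% of capacity.
    """
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    if n_points < 32:
        raise ValueError("need at least 32 spectrum points")
    clip_columns = np.asarray(sorted(set(int(c) for c in clip_columns)),
                              dtype=int)
    if clip_columns.size and (clip_columns.min() < 0
                              or clip_columns.max() >= n_alines):
        raise ValueError("clip_columns out of range")

    rng = np.random.default_rng(seed)
    k = np.arange(n_points)[:, None] / n_points  # (P, 1)
    freqs = rng.uniform(1.5, 4.0, size=(3, n_alines))
    phases = rng.uniform(0, 2 * np.pi, size=(3, n_alines))
    amps = np.array([0.45, 0.30, 0.15])[:, None]
    signal = 1.0 + sum(
        amps[i] * np.cos(2 * np.pi * freqs[i] * k + phases[i])
        for i in range(3)
    )
    signal += rng.normal(0.0, 0.01, size=signal.shape)
    signal = np.clip(signal, 1e-3, None)

    scale = 0.8 * capacity / signal.max(axis=0)
    if clip_columns.size:
        scale[clip_columns] = (1.5 * capacity
                               / signal[:, clip_columns].max(axis=0))
    charges = np.minimum(signal * scale, capacity)
    return SpectralFrame(charges=charges, capacity=capacity)
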