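"""Overlapping-patch decomposition with exact coordinate bookkeeping.

Images are decomposed into overlapping ``a × b`` blocks, each flattened in
lexicographic (row-major) order to a vector of length ``ab``.  Patch start
indices are clamped so the final patch in each direction ends exactly at
the image edge — no padding, no partial patches — which guarantees every
pixel is covered by at least one patch for any stride.

Standardization subtracts the per-patch mean intensity; for corrupted
patches the mean is computed over *valid* (unsaturated) pixels only, since
saturated values carry no information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _starts(extent: int, size: int, stride: int) -> np.ndarray:
    if size > extent:
        raise ValueError("patch size larger than image")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    st = np.arange(0, extent - size + 1, stride)
    if st[-1] != extent - size:
        st = np.append(st, extent - size)
    return st


@dataclass(frozen=True)
class PatchGrid:
    """Patch start coordinates for an image / patch-size / stride triple."""

    image_shape: tuple[int, int]
    patch_size: tuple[int, int] = (8, 8)
    stride: tuple[int, int] = (1, 1)

    @cached_property
    def row_starts(self) -> np.ndarray:
        return _starts(self.image_shape[0], self.patch_size[0], self.stride[0])

    @cached_property
    def col_starts(self) -> np.ndarray:
        return _starts(self.image_shape[1], self.patch_size[1], self.stride[1])

    @property
    def n_patches(self) -> int:
        return self.row_starts.size * self.col_starts.size

    def coords(self) -> np.ndarray:
        """All (row, col) top-left coordinates, row-major order, shape (n, 2)."""
        rr, cc = np.meshgrid(self.row_starts, self.col_starts, indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])


@dataclass
class Patch:
    """A single vectorized patch (a view convenience over `PatchSet`)."""

    top_left: tuple[int, int]
    patch_shape: tuple[int, int]
    vector: np.ndarray
    valid: np.ndarray
    mean: float | None = None

    def __post_init__(self) -> None:
        ab = self.patch_shape[0] * self.patch_shape[1]
        if self.vector.size != ab or self.valid.size != ab:
            raise ValueError("vector/valid length must equal a*b")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class PatchSet:
    """All patches of one image in vectorized form.

    ``vectors`` is (n_patches, ab) float64, ``valid`` the matching boolean
    validity flags (False = saturated pixel), ``coords`` the (row, col)
    top-left corners.  ``means`` is set after standardization.
    """

    vectors: np.ndarray
    valid: np.ndarray
    coords: np.ndarray
    patch_shape: tuple[int, int]
    image_shape: tuple[int, int]
    means: np.ndarray | None = field(default=None)

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def __getitem__(self, i: int) -> Patch:
        return Patch(
            top_left=(int(self.coords[i, 0]), int(self.coords[i, 1])),
            patch_shape=self.patch_shape,
            vector=self.vectors[i].copy(),
            valid=self.valid[i].copy(),
            mean=None if self.means is None else float(self.means[i]),
        )


def extract_patches(image: np.ndarray, pixel_mask: np.ndarray | None,
                    grid: PatchGrid) -> PatchSet:
    """Extract every grid patch of ``image`` as row-major vectors.

    ``pixel_mask`` marks saturated pixels (True = saturated); ``None``
    means the whole image is valid.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != tuple(grid.image_shape):
        raise ValueError("grid inconsistent with image shape")
    a, b = grid.patch_size
    if pixel_mask is None:
        pixel_mask = np.zeros(image.shape, dtype=bool)
    pixel_mask = np.asarray(pixel_mask, dtype=bool)
    if pixel_mask.shape != image.shape:
        raise ValueError("pixel_mask shape must match image")

    rs, cs = grid.row_starts, grid.col_starts
    win = sliding_window_view(image, (a, b))
    vectors = win[np.ix_(rs, cs)].reshape(-1, a * b)
    mwin = sliding_window_view(~pixel_mask, (a, b))
    valid = mwin[np.ix_(rs, cs)].reshape(-1, a * b)
    return PatchSet(
        vectors=np.ascontiguousarray(vectors),
        valid=np.ascontiguousarray(valid),
        coords=grid.coords(),
        patch_shape=(a, b),
        image_shape=image.shape,
    )


def standardize_patches(ps: PatchSet) -> PatchSet:
    """Subtract the per-patch mean (over valid pixels only) from every entry.

    Patches with zero valid pixels get mean 0 and are left for downstream
    code to mark unrecoverable.
    """
    counts = ps.valid.sum(axis=1)
    sums = np.where(ps.valid, ps.vectors, 0.0).sum(axis=1)
    means = np.divide(sums, counts, out=np.zeros_like(sums),
                      where=counts > 0)
    return PatchSet(
        vectors=ps.vectors - means[:, None],
        valid=ps.valid,
        coords=ps.coords,
        patch_shape=ps.patch_shape,
        image_shape=ps.image_shape,
        means=means,
    )


def standardize_patch(p: Patch) -> Patch:
    """Single-patch standardization: mean over valid entries, subtracted
    from all entries; the stored mean restores the patch exactly."""
    if p.n_valid == 0:
        raise ValueError("patch has no valid pixels")
    m = float(p.vector[p.valid].mean())
    return Patch(top_left=p.top_left, patch_shape=p.patch_shape,
                 vector=p.vector - m, valid=p.valid.copy(), mean=m)


def restore_patch(p: Patch) -> Patch:
    """Inverse of `standardize_patch`."""
    if p.mean is None:
        raise ValueError("patch has no stored mean")
    return Patch(top_left=p.top_left, patch_shape=p.patch_shape,
                 vector=p.vector + p.mean, valid=p.valid.copy(), mean=None)


def collect_training_patches(images, patch_size=(8, 8), stride=(1, 1),
                             max_patches: int | None = 200_000,
                             seed: int = 0) -> np.ndarray:
    """Extract, standardize and pool training patches from several images.

    Patches are extracted at the given stride from each image (all pixels
    valid), zero-meaned, pooled, and uniformly subsampled without
    replacement down to ``max_patches`` to bound memory.  Returns an
    (n, ab) float64 array of zero-mean training vectors.
    """
    pools = []
    for img in images:
        img = np.asarray(img, dtype=np.float64)
        grid = PatchGrid(img.shape, patch_size, stride)
        ps = standardize_patches(extract_patches(img, None, grid))
        pools.append(ps.vectors)
    allv = np.concatenate(pools, axis=0)
    if max_patches is not None and allv.shape[0] > max_patches:
        rng = np.random.default_rng(seed)
        idx = rng.choice(allv.shape[0], size=max_patches, replace=False)
        allv = allv[np.sort(idx)]
    return allv
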