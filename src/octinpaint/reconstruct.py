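"""Patch inpainting and weighted aggregation — the pipeline core.

For each standardized patch that touches saturation, the saturated entries
are dropped from the patch vector and the matching rows from the
dictionary; sparse coding the surviving pixels against this row-reduced
dictionary (sparsity-constrained OMP, ‖α‖₀ ≤ p) yields coefficients that,
applied to the *full* dictionary, predict the whole patch — including the
dropped pixels — and the stored patch mean is added back:
``Z = X α̂ + m``.

Because patches overlap, every pixel collects several estimates; they are
combined by a weighted average whose per-patch weight map is a separable
triangle, maximal at the patch center and falling off linearly toward the
edges (pixels near a patch border see less of their neighborhood and get
less confidence).  Patches with too few valid pixels are unrecoverable
and contribute nothing; pixels left with zero total weight are filled by
row-wise cubic interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dictionary import Dictionary
from .interp import fill_masked_pixels
from .masks import SaturationMask
from .omp import batch_omp_arrays, omp
from .patches import Patch, PatchGrid, extract_patches, standardize_patches
from .phantom import MAX_VAL

log = logging.getLogger(__name__)


class UnrecoverablePatchError(ValueError):
    """Raised when a patch has too few valid pixels to sparse-code."""


@dataclass(frozen=True)
class InpaintConfig:
    """Tunables of the patch-inpainting stage.

    ``sparsity`` is the number of atoms per patch code; the default
    ``min_valid_pixels = max(3·p, 8)`` requires a comfortable
    overdetermination margin before a patch counts as recoverable.  With
    ``process_all_patches`` (default) clean patches are sparse-coded too,
    which doubles as speckle suppression; otherwise unsaturated pixels
    pass through bit-identical and only saturated pixels are replaced.
    """

    sparsity: int = 2
    patch_size: tuple[int, int] = (8, 8)
    stride: tuple[int, int] = (1, 1)
    min_valid_pixels: int | None = None
    process_all_patches: bool = True
    zero_edge_weights: bool = False
    max_val: float = MAX_VAL

    def __post_init__(self) -> None:
        if self.sparsity < 1:
            raise ValueError("sparsity must be >= 1")
        if (self.min_valid_pixels is not None
                and self.min_valid_pixels < self.sparsity):
            raise ValueError("min_valid_pixels must be >= sparsity")

    @property
    def effective_min_valid(self) -> int:
        if self.min_valid_pixels is not None:
            return self.min_valid_pixels
        return max(3 * self.sparsity, 8)


@dataclass(frozen=True)
class ReducedProblem:
    """A patch's sparse-coding problem restricted to its valid pixels."""

    y_prime: np.ndarray
    X_prime: np.ndarray
    n_removed: int
    kept_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.X_prime.shape[0] != self.y_prime.size:
            raise ValueError("X_prime rows must match y_prime length")


def reduce_problem(p: Patch, X: Dictionary,
                   min_valid: int = 1) -> ReducedProblem:
    """Drop saturated entries from a standardized patch vector and the
    matching dictionary rows, preserving order."""
    kept = np.flatnonzero(p.valid)
    if kept.size < max(min_valid, 1):
        raise UnrecoverablePatchError(
            f"patch at {p.top_left}: only {kept.size} valid pixels")
    return ReducedProblem(
        y_prime=p.vector[kept].copy(),
        X_prime=X.atoms[kept].copy(),
        n_removed=p.vector.size - kept.size,
        kept_indices=kept,
    )


def inpaint_patch(rp: ReducedProblem, X: Dictionary, m_i: float,
                  p: int, max_val: float = MAX_VAL) -> np.ndarray:
    """Sparse-code the valid pixels, reconstruct the full patch.

    The code is fitted on the reduced problem but applied to the full
    dictionary, so removed pixels receive predictions; the patch mean is
    restored and the result clipped to ``[0, max_val]``.
    """
    code = omp(rp.X_prime, rp.y_prime, max_sparsity=min(p, rp.y_prime.size))
    z = X.atoms @ code.coefficients + m_i
    return np.clip(z, 0.0, max_val)


@dataclass(frozen=True)
class WeightMap:
    """Separable per-patch aggregation weights, ``W[i, j] = W_a[i]·W_b[j]``."""

    factor_row: np.ndarray
    factor_col: np.ndarray
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights",
                           np.outer(self.factor_row, self.factor_col))


def _triangle(n: int, zero_edges: bool) -> np.ndarray:
    i = np.arange(n, dtype=float)
    if zero_edges and n > 1:
        w = 1.0 - np.abs(2 * i - (n - 1)) / (n - 1)
    else:
        w = 1.0 - np.abs(2 * i - (n - 1)) / n
    return w


def patch_weight(a: int, b: int, zero_edges: bool = False) -> WeightMap:
    """Triangular weight map: linear fall-off from the patch center.

    The default form ``W_a[i] = 1 − |2i − (a−1)|/a`` stays strictly
    positive at the edges so border pixels covered only by patch edges
    still receive weight; ``zero_edges=True`` selects the strict
    center-to-edge 1→0 variant instead.
    """
    if a < 1 or b < 1:
        raise ValueError("patch dimensions must be >= 1")
    return WeightMap(factor_row=_triangle(a, zero_edges),
                     factor_col=_triangle(b, zero_edges))


def aggregate(coords: np.ndarray, estimates: np.ndarray, weights: WeightMap,
              image_shape: tuple[int, int],
              ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted average of overlapping patch estimates.

    Parameters
    ----------
    coords
        (n, 2) top-left corners; ``estimates`` the matching (n, ab)
        reconstructed patch vectors (row-major).

    Returns
    -------
    image, covered
        ``image[r, c] = Σ w·z / Σ w`` over contributing patches;
        ``covered`` flags pixels with positive total weight (others are
        left 0 and must be filled by the caller).
    """
    coords = np.asarray(coords)
    estimates = np.asarray(estimates, dtype=np.float64)
    if coords.shape[0] == 0:
        raise ValueError("empty estimate set")
    a, b = weights.weights.shape
    if estimates.shape[1] != a * b:
        raise ValueError("estimate length must match weight map size")
    H, W = image_shape
    di, dj = np.divmod(np.arange(a * b), b)
    flat = ((coords[:, 0, None] + di[None, :]) * W
            + (coords[:, 1, None] + dj[None, :])).ravel()
    w = np.broadcast_to(weights.weights.ravel(),
                        estimates.shape).ravel()
    wsum = np.bincount(flat, weights=w, minlength=H * W)
    vsum = np.bincount(flat, weights=w * estimates.ravel(), minlength=H * W)
    covered = wsum > 0
    out = np.zeros(H * W)
    out[covered] = vsum[covered] / wsum[covered]
    return out.reshape(H, W), covered.reshape(H, W)


def process_image(image: np.ndarray, mask: SaturationMask, X: Dictionary,
                  cfg: InpaintConfig | None = None,
                  stats: dict | None = None) -> np.ndarray:
    """Run the full inpainting pipeline on one B-scan.

    Extracts overlapping patches, standardizes them, sparse-codes each
    recoverable patch against the (row-reduced, where saturated)
    dictionary, and aggregates the overlapping reconstructions with the
    triangular weight map.  Pass a dict as ``stats`` to receive patch
    counts (total / saturated / unrecoverable / zero-weight pixels).
    """
    cfg = cfg or InpaintConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if mask.width != image.shape[1]:
        raise ValueError("mask width must match image width")
    if tuple(X.patch_shape) != tuple(cfg.patch_size):
        raise ValueError("dictionary patch_shape mismatch with config")

    H, W = image.shape
    pm = mask.to_pixel_mask(H)
    grid = PatchGrid((H, W), cfg.patch_size, cfg.stride)
    ps = standardize_patches(extract_patches(image, pm, grid))

    touches_sat = ~ps.valid.all(axis=1)
    selected = np.ones(len(ps), dtype=bool) if cfg.process_all_patches \
        else touches_sat
    valid_counts = ps.valid.sum(axis=1)
    recover = selected & (valid_counts >= cfg.effective_min_valid)
    n_unrec = int((selected & ~recover).sum())

    atoms = X.atoms
    idx_rec = np.flatnonzero(recover)
    Z = np.empty((idx_rec.size, atoms.shape[0]))
    if idx_rec.size:
        patterns, inverse = np.unique(ps.valid[idx_rec], axis=0,
                                      return_inverse=True)
        for gi in range(patterns.shape[0]):
            members = np.flatnonzero(inverse == gi)
            kept = np.flatnonzero(patterns[gi])
            rows = idx_rec[members]
            sub = atoms[kept]
            coefs, _, _ = batch_omp_arrays(
                sub, ps.vectors[rows][:, kept],
                max_sparsity=min(cfg.sparsity, kept.size))
            Z[members] = coefs @ atoms.T + ps.means[rows][:, None]
    Z = np.clip(Z, 0.0, cfg.max_val)

    wm = patch_weight(*cfg.patch_size, zero_edges=cfg.zero_edge_weights)
    if idx_rec.size == 0:
        est = np.zeros((H, W))
        covered = np.zeros((H, W), dtype=bool)
    else:
        est, covered = aggregate(ps.coords[idx_rec], Z, wm, (H, W))

    if cfg.process_all_patches:
        out = est
        missing = ~covered
    else:
        out = image.copy()
        replace = pm & covered
        out[replace] = est[replace]
        missing = pm & ~covered
    n_missing = int(missing.sum())
    if n_missing:
        out = fill_masked_pixels(np.where(missing, 0.0, out), missing)
    out = np.clip(out, 0.0, cfg.max_val)

    if stats is not None:
        stats.update(
            n_patches=len(ps),
            n_saturated_patches=int(touches_sat.sum()),
            n_processed=int(idx_rec.size),
            n_unrecoverable=n_unrec,
            n_fallback_pixels=n_missing,
        )
    log.info("inpainted %d/%d patches (%d touching saturation, "
             "%d unrecoverable, %d fallback pixels)",
             idx_rec.size, len(ps), int(touches_sat.sum()),
             n_unrec, n_missing)
    return out
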