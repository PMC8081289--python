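"""Overcomplete patch dictionaries: container, normalization, persistence.

A dictionary is an ``ab × q`` matrix whose unit-norm columns ("atoms") are
vectorized ``a × b`` patches; overcompleteness (``ab < q``) lets short
sparse combinations of atoms represent a rich family of patch structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np


def _apply_sign_convention(atoms: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's largest-magnitude entry is positive."""
    lead = atoms[np.abs(atoms).argmax(axis=0), np.arange(atoms.shape[1])]
    signs = np.where(lead < 0, -1.0, 1.0)
    return atoms * signs


@dataclass
class Dictionary:
    """Patch dictionary with unit-norm atom columns.

    ``atoms`` has shape ``(ab, q)`` where ``(a, b) = patch_shape``.
    ``metadata`` records training provenance (epsilon, iterations, seed,
    per-iteration error history, ...).  Overcompleteness is conventional
    rather than enforced, so square (e.g. identity) dictionaries remain
    usable in controlled experiments.
    """

    atoms: np.ndarray
    patch_shape: tuple[int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a 2-D matrix")
        a, b = self.patch_shape
        if self.atoms.shape[0] != a * b:
            raise ValueError("atom length must equal a*b")

    @property
    def n_features(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def is_overcomplete(self) -> bool:
        return self.n_atoms > self.n_features

    def column_norms(self) -> np.ndarray:
        return np.linalg.norm(self.atoms, axis=0)

    def coherence(self) -> float:
        """Mutual coherence: max |inner product| between distinct atoms
        (after normalization)."""
        A = self.atoms / self.column_norms()
        G = np.abs(A.T @ A)
        np.fill_diagonal(G, 0.0)
        return float(G.max())

    # -- persistence ----------------------------------------------------
    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("atoms", data=self.atoms)
            ds.attrs["patch_height"] = self.patch_shape[0]
            ds.attrs["patch_width"] = self.patch_shape[1]
            for key in ("epsilon", "iterations", "seed"):
                if key in self.metadata and self.metadata[key] is not None:
                    ds.attrs[key] = self.metadata[key]
            if "error_history" in self.metadata:
                f.create_dataset(
                    "error_history",
                    data=np.asarray(self.metadata["error_history"]))

    @classmethod
    def load_h5(cls, path: str | Path) -> "Dictionary":
        with h5py.File(path, "r") as f:
            ds = f["atoms"]
            meta = {k: ds.attrs[k] for k in ("epsilon", "iterations", "seed")
                    if k in ds.attrs}
            if "error_history" in f:
                meta["error_history"] = f["error_history"][()].tolist()
            return cls(
                atoms=ds[()],
                patch_shape=(int(ds.attrs["patch_height"]),
                             int(ds.attrs["patch_width"])),
                metadata=meta,
            )

    def atlas(self, pad: int = 1) -> np.ndarray:
        """Tile the atoms into a single grayscale image for inspection.

        Each atom is min-max stretched to [0, 255] inside its own tile.
        """
        a, b = self.patch_shape
        q = self.n_atoms
        ncols = int(np.ceil(np.sqrt(q)))
        nrows = int(np.ceil(q / ncols))
        canvas = np.zeros((nrows * (a + pad) + pad, ncols * (b + pad) + pad),
                          dtype=np.uint8)
        for j in range(q):
            tile = self.atoms[:, j].reshape(a, b)
            lo, hi = tile.min(), tile.max()
            tile = (tile - lo) / (hi - lo) if hi > lo else np.full_like(tile, .5)
            r, c = divmod(j, ncols)
            canvas[pad + r * (a + pad): pad + r * (a + pad) + a,
                   pad + c * (b + pad): pad + c * (b + pad) + b] = \
                np.round(tile * 255).astype(np.uint8)
        return canvas


def normalize_dictionary(X: Dictionary | np.ndarray,
                         patch_shape: tuple[int, int] | None = None
                         ) -> Dictionary:
    """Return a copy with unit-norm columns and the sign convention that
    each column's largest-magnitude entry is positive.  Idempotent.
    """
    if isinstance(X, Dictionary):
        atoms, shape, meta = X.atoms, X.patch_shape, dict(X.metadata)
    else:
        atoms = np.asarray(X, dtype=np.float64)
        if patch_shape is None:
            raise ValueError("patch_shape required for a bare matrix")
        shape, meta = patch_shape, {}
    norms = np.linalg.norm(atoms, axis=0)
    if np.any(norms < 1e-12):
        raise ValueError("dictionary contains a zero column")
    return Dictionary(atoms=_apply_sign_convention(atoms / norms),
                      patch_shape=shape, metadata=meta)


def low_coherence_frame(n_rows: int, n_atoms: int, seed: int = 0,
                        max_coherence: float = 1 / 3,
                        max_iter: int = 2000) -> np.ndarray:
    """Construct a unit-norm frame with mutual coherence below a target.

    Random Gaussian frames in low dimension are far too coherent for OMP
    recovery guarantees, so this uses the standard alternating projection:
    shrink large off-diagonal Gram entries toward the Welch bound, project
    the Gram matrix back to rank ``n_rows``, re-normalize, repeat.  Raises
    ``RuntimeError`` if the target is not reached (e.g. below the Welch
    bound).
    """
    welch = np.sqrt((n_atoms - n_rows) / (n_rows * (n_atoms - 1)))
    if max_coherence < welch:
        raise RuntimeError("target coherence below the Welch bound")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_rows, n_atoms))
    A /= np.linalg.norm(A, axis=0)
    shrink_to = max(welch, 0.9 * max_coherence)
    for _ in range(max_iter):
        G = A.T @ A
        off = G - np.diag(np.diag(G))
        mu = np.abs(off).max()
        if mu < max_coherence:
            return _apply_sign_convention(A)
        big = np.abs(G) > shrink_to
        np.fill_diagonal(big, False)
        G[big] = np.sign(G[big]) * shrink_to
        w, V = np.linalg.eigh(G)
        keep = w[-n_rows:]
        B = (V[:, -n_rows:] * np.sqrt(np.clip(keep, 0, None))).T
        A = B / np.linalg.norm(B, axis=0)
    raise RuntimeError(
        f"coherence target {max_coherence} not reached in {max_iter} iters")
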