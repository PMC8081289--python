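"""Orthogonal matching pursuit, single-signal and batch variants.

OMP greedily selects the atom most correlated with the current residual
(normalized correlation, lowest index on ties), then re-fits all selected
coefficients by least squares — an orthogonal projection — before
continuing.  Two stopping rules are supported and may be combined:

* sparsity-constrained: stop after ``max_sparsity`` atoms (the inpainting
  form, ``‖α‖₀ ≤ p``);
* error-constrained: stop once the *squared* ℓ2 residual drops to
  ``error_target`` (the dictionary-training form, ``‖y − Xα‖₂² ≤ ε``).

`batch_omp` computes identical codes for many signals at once using the
precomputed Gram matrix ``G = XᵀX`` and progressive Cholesky updates of
the selected sub-Grams; the batching is purely a performance device and
its output matches per-signal `omp` to numerical precision.

Columns need not be unit-norm (row-reduced dictionaries are not): atom
selection normalizes internally while coefficients are solved against the
original, unnormalized columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .dictionary import Dictionary

_ZERO_COL = 1e-12
_REL_ZERO = 1e-12  # relative squared-residual floor treated as exact


@dataclass
class SparseCode:
    """A sparse coefficient vector with its support and residual norm."""

    coefficients: np.ndarray
    support: np.ndarray
    residual_norm: float

    @property
    def n_nonzero(self) -> int:
        return int(self.support.size)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, Dictionary):
        return X.atoms
    A = np.asarray(X, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError("dictionary must be a 2-D matrix")
    return A


def _check_stopping(d: int, q: int, max_sparsity, error_target) -> int:
    """Validate the stopping rules; return the step cap."""
    if max_sparsity is None and error_target is None:
        raise ValueError("need max_sparsity and/or error_target")
    if error_target is not None and error_target < 0:
        raise ValueError("error_target must be non-negative")
    if max_sparsity is None:
        return min(d, q)
    p = int(max_sparsity)
    if p <= 0:
        raise ValueError("max_sparsity must be positive")
    if p > min(d, q):
        raise ValueError(
            f"max_sparsity {p} exceeds min(rows, atoms) = {min(d, q)}")
    return p


def omp(X, y: np.ndarray, max_sparsity: int | None = None,
        error_target: float | None = None) -> SparseCode:
    """Sparse-code one signal against dictionary ``X``.

    ``error_target`` is a threshold on the squared residual ``‖y − Xα‖₂²``.
    Returns a full-length coefficient vector with zeros off-support.
    """
    A = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64).ravel()
    d, q = A.shape
    if y.size != d:
        raise ValueError("signal length must equal dictionary row count")
    cap = _check_stopping(d, q, max_sparsity, error_target)

    norms = np.linalg.norm(A, axis=0)
    usable = norms > _ZERO_COL
    safe = np.where(usable, norms, 1.0)
    ynorm2 = float(y @ y)
    if ynorm2 == 0.0:
        return SparseCode(np.zeros(q), np.empty(0, dtype=int), 0.0)

    support: list[int] = []
    r = y.copy()
    coef_s = np.empty(0)
    res2 = ynorm2
    while len(support) < cap:
        if error_target is not None and res2 <= error_target:
            break
        if res2 <= _REL_ZERO * ynorm2:
            break
        corr = (A.T @ r) / safe
        corr[~usable] = 0.0
        if support:
            corr[support] = 0.0
        k = int(np.argmax(np.abs(corr)))
        if np.abs(corr[k]) <= _ZERO_COL * np.sqrt(ynorm2):
            break  # residual (numerically) orthogonal to every atom
        support.append(k)
        coef_s, *_ = np.linalg.lstsq(A[:, support], y, rcond=None)
        r = y - A[:, support] @ coef_s
        res2 = float(r @ r)

    alpha = np.zeros(q)
    alpha[support] = coef_s
    return SparseCode(alpha, np.asarray(support, dtype=int),
                      float(np.sqrt(max(res2, 0.0))))


# ---------------------------------------------------------------------------
# Batch variant
# ---------------------------------------------------------------------------

def _forward_solve(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized forward substitution: solve ``L x = B`` per signal.

    ``L``: (n, s, s) lower triangular, ``B``: (n, s).
    """
    s = B.shape[1]
    x = np.empty_like(B)
    for i in range(s):
        acc = B[:, i].copy()
        if i:
            acc -= np.einsum("nj,nj->n", L[:, i, :i], x[:, :i])
        x[:, i] = acc / L[:, i, i]
    return x


def _backward_solve(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``Lᵀ x = B`` per signal (L lower triangular)."""
    s = B.shape[1]
    x = np.empty_like(B)
    for i in range(s - 1, -1, -1):
        acc = B[:, i].copy()
        if i < s - 1:
            acc -= np.einsum("nj,nj->n", L[:, i + 1:, i], x[:, i + 1:])
        x[:, i] = acc / L[:, i, i]
    return x


def batch_omp_arrays(X, signals: np.ndarray, max_sparsity: int | None = None,
                     error_target: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Code many signals at once; the performance core behind `batch_omp`.

    Parameters
    ----------
    signals
        (n_signals, d) array, one signal per row.

    Returns
    -------
    coefficients : (n_signals, q)
    residual_sq : (n_signals,) squared residual norms
    supports : (n_signals, cap) int array, selection order, -1 padded
    """
    A = _as_matrix(X)
    Y = np.asarray(signals, dtype=np.float64)
    if Y.ndim != 2:
        raise ValueError("signals must be a 2-D (n_signals, d) array")
    n, d = Y.shape
    if d != A.shape[0]:
        raise ValueError("signal length must equal dictionary row count")
    q = A.shape[1]
    cap = _check_stopping(d, q, max_sparsity, error_target)

    norms = np.linalg.norm(A, axis=0)
    usable = norms > _ZERO_COL
    safe = np.where(usable, norms, 1.0)
    An = np.where(usable, A / safe, 0.0)

    G = An.T @ An
    H = Y @ An                       # h0 per signal
    ynorm2 = np.einsum("ij,ij->i", Y, Y)

    supports = np.full((n, cap), -1, dtype=np.int64)
    L = np.zeros((n, cap, cap))
    Cn = np.zeros((n, q))            # coefficients in the normalized basis
    corr = H.copy()
    residual_sq = ynorm2.copy()
    selected = np.zeros((n, q), dtype=bool)

    active = ynorm2 > 0.0
    if error_target is not None:
        active &= residual_sq > error_target

    for s in range(cap):
        act = np.flatnonzero(active)
        if act.size == 0:
            break
        absc = np.abs(corr[act])
        absc[selected[act]] = -1.0
        absc[:, ~usable] = -1.0
        k = np.argmax(absc, axis=1)
        best = absc[np.arange(act.size), k]
        proceed = best > _ZERO_COL * np.sqrt(ynorm2[act])

        if s > 0:
            g = G[supports[act, :s], k[:, None]]       # (na, s)
            w = _forward_solve(L[act, :s, :s], g)
            d2 = 1.0 - np.einsum("nj,nj->n", w, w)
            ok = d2 > 1e-12
            proceed &= ok
            act2 = act[proceed]
            if act2.size:
                L[act2, s, :s] = w[proceed]
                L[act2, s, s] = np.sqrt(d2[proceed])
        else:
            act2 = act[proceed]
            L[act2, 0, 0] = 1.0

        active[act[~proceed]] = False
        if act2.size == 0:
            continue
        k2 = k[proceed]
        supports[act2, s] = k2
        selected[act2, k2] = True
        ns = s + 1

        hs = np.take_along_axis(H[act2], supports[act2, :ns], axis=1)
        z = _backward_solve(L[act2, :ns, :ns],
                            _forward_solve(L[act2, :ns, :ns], hs))
        tmp = np.zeros((act2.size, q))
        np.put_along_axis(tmp, supports[act2, :ns], z, axis=1)
        Cn[act2] = tmp
        corr[act2] = H[act2] - tmp @ G
        res = ynorm2[act2] - np.einsum("nj,nj->n", hs, z)
        residual_sq[act2] = np.clip(res, 0.0, None)

        done = residual_sq[act2] <= _REL_ZERO * ynorm2[act2]
        if error_target is not None:
            done |= residual_sq[act2] <= error_target
        active[act2[done]] = False

    coefficients = Cn / safe
    return coefficients, residual_sq, supports


def batch_omp(X, signals, max_sparsity: int | None = None,
              error_target: float | None = None) -> list[SparseCode]:
    """Batch sparse coding; output equals ``[omp(X, y, ...) for y in signals]``.

    Accepts an empty signal set (returns an empty list).
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.size == 0:
        return []
    coefs, res_sq, supports = batch_omp_arrays(
        X, signals, max_sparsity=max_sparsity, error_target=error_target)
    out = []
    for i in range(signals.shape[0]):
        sup = supports[i][supports[i] >= 0]
        out.append(SparseCode(coefs[i], sup.copy(),
                              float(np.sqrt(res_sq[i]))))
    return out


def exhaustive_sparse_fit(X, y: np.ndarray, k: int
                          ) -> tuple[tuple[int, ...], np.ndarray, float]:
    """Brute-force best k-sparse least-squares fit over *all* supports.

    Enumerates every k-subset of atoms, solves the least-squares problem
    on each, and returns ``(support, coefficients, residual_norm)`` of the
    global minimizer.  Exponential in ``k`` — a verification oracle for
    small problems, not a production solver.
    """
    A = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64).ravel()
    best = (None, None, np.inf)
    for sup in itertools.combinations(range(A.shape[1]), k):
        c, *_ = np.linalg.lstsq(A[:, sup], y, rcond=None)
        r = y - A[:, sup] @ c
        rn = float(np.linalg.norm(r))
        if rn < best[2]:
            best = (sup, c, rn)
    return best
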